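"""Trend tests on indicator series: Mann-Kendall with Hamed-Rao variance
correction and Benjamini-Hochberg FDR within patient.

Each indicator series is tested for a *rise* over the final two weeks
before the transition (or the final two weeks of a control segment).
Because consecutive moving windows share almost all of their data, the
indicator series is strongly serially dependent and the classical
Mann-Kendall variance badly understates var(S); the Hamed-Rao (1998)
correction inflates it using the significant lag autocorrelations of the
Sen-detrended ranks.  Two-sided p-values are corrected for multiple
testing with the Benjamini-Hochberg step-up across all tests of one
patient, and only positive-tau rejections count as early warning signals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ews import IndicatorSeries

__all__ = [
    "KendallTrend",
    "HamedRaoOptions",
    "EwsTestResult",
    "kendall_trend",
    "hamed_rao_correct",
    "fdr_within_patient",
    "restrict_to_final_fortnight",
    "test_indicator_series",
]

#: Two weeks of scheduled slots at the default 5 beeps/day.
FORTNIGHT_SLOTS = 70

MIN_POINTS_HARD = 3
MIN_POINTS_SOFT = 10


@dataclass(frozen=True)
class KendallTrend:
    """Mann-Kendall statistics for one indicator series."""

    tau: float
    s: float
    var_s: float
    n: int

    @property
    def valid(self) -> bool:
        return not math.isnan(self.tau)


@dataclass(frozen=True)
class HamedRaoOptions:
    """Variance-correction settings.

    ``acf_alpha`` screens rank autocorrelations: only lags whose |acf|
    exceeds the two-sided normal bound at this level enter the correction.
    The factor is floored at 1 by default so the correction can only make
    the test more conservative.

    ``acf_source`` controls where the rank autocorrelation is estimated:

    * ``"segment"`` (default) — from the *full* indicator series of the
      segment.  Overlapping windows make indicator points dependent out
      to roughly one window length, which is as long as the tested
      fortnight itself; the dependence is only measurable on the longer
      series, so this source is far better calibrated.
    * ``"fortnight"`` — from the tested values alone, with lags capped at
      ``max_lag_frac`` of their count (the textbook single-series
      recipe); substantially under-corrects here, kept for sensitivity
      analyses.
    """

    acf_alpha: float = 0.05
    max_lag_frac: float = 0.25
    floor_at_one: bool = True
    acf_source: str = "segment"

    def __post_init__(self) -> None:
        if self.acf_source not in ("segment", "fortnight"):
            raise ValueError("acf_source must be 'segment' or 'fortnight'")


@dataclass
class EwsTestResult:
    """One trend test: (patient, segment, state, indicator)."""

    patient_id: str
    state: str
    indicator: str
    segment_id: str
    segment_kind: str
    transition_kind: Optional[str]
    tau: float = float("nan")
    s: float = float("nan")
    var_s: float = float("nan")
    hr_factor: float = float("nan")
    p_raw: float = float("nan")
    p_corrected: float = float("nan")
    n_points: int = 0
    valid: bool = False
    reason: str = ""
    significant: bool = False  # set by the within-patient FDR step
    significant_uncorrected: bool = False


def _normal_p(s: float, var_s: float) -> float:
    """Two-sided p for S under normal approximation, continuity-corrected."""
    if var_s <= 0:
        return 1.0
    if s > 0:
        z = (s - 1.0) / math.sqrt(var_s)
    elif s < 0:
        z = (s + 1.0) / math.sqrt(var_s)
    else:
        z = 0.0
    return float(2.0 * stats.norm.sf(abs(z)))


def kendall_trend(values: Sequence[float]) -> KendallTrend:
    """Mann-Kendall S, tie-corrected var(S) and Kendall's tau vs time.

    ``S = sum_{i<j} sign(x_j - x_i)``; tau is the tau-b normalization
    (ties in the values are corrected for; time has no ties).  An
    all-tied series has no defined trend direction: tau is NaN.
    Fewer than 10 points triggers a warning; fewer than 3 are refused.
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise ValueError("indicator values must not contain NaN; drop invalid windows first")
    n = x.size
    if n < MIN_POINTS_HARD:
        raise ValueError(f"need >= {MIN_POINTS_HARD} indicator points, got {n}")
    if n < MIN_POINTS_SOFT:
        warnings.warn(
            f"only {n} indicator points; trend test is unstable", stacklevel=2
        )
    diff = np.sign(x[None, :] - x[:, None])
    s = float(np.triu(diff, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (
        n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))
    ) / 18.0
    d = n * (n - 1) / 2.0
    tie_u = np.sum(ties * (ties - 1) / 2.0)
    denom = math.sqrt(d * (d - tie_u))
    tau = s / denom if denom > 0 else float("nan")
    return KendallTrend(tau=float(tau), s=s, var_s=float(var_s), n=n)


def _rank_acf(values: np.ndarray, max_lag: int) -> np.ndarray:
    """Lag 1..max_lag autocorrelation of the Sen-detrended ranks."""
    n = values.size
    t = np.arange(n, dtype=float)
    slope = stats.theilslopes(values, t).slope
    ranks = stats.rankdata(values - slope * t)
    c = ranks - ranks.mean()
    denom = float(c @ c)
    if denom == 0.0:
        return np.zeros(max_lag)
    return np.array(
        [float(c[lag:] @ c[:-lag]) / denom for lag in range(1, max_lag + 1)]
    )


def hamed_rao_correct(
    values: Sequence[float],
    trend: KendallTrend,
    options: HamedRaoOptions = HamedRaoOptions(),
    acf_values: Optional[Sequence[float]] = None,
) -> tuple[float, float, float]:
    """Hamed-Rao variance inflation and corrected p-value.

    The variance of S is multiplied by

        1 + 2 / (n (n-1) (n-2)) * sum_i (n-i)(n-i-1)(n-i-2) rho_s(i)

    with rho_s(i) the lag-i autocorrelation of the ranks of the
    Sen-detrended values, summed over the significant lags only
    (|rho| > z_{1-a/2}/sqrt(m)).  ``acf_values`` optionally supplies a
    longer series from the same process (the segment's full indicator
    series) on which rho_s is estimated; by default the tested values are
    used, with lags capped at ``max_lag_frac * n``.  For very short
    series (n < 10) the estimated autocorrelations are too unstable: the
    uncorrected variance is returned with a warning.

    Returns ``(correction_factor, corrected_var_s, corrected_p)``.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < MIN_POINTS_SOFT:
        warnings.warn(
            f"n = {n} < {MIN_POINTS_SOFT}: Hamed-Rao correction unstable; "
            "returning the uncorrected test",
            stacklevel=2,
        )
        return 1.0, trend.var_s, _normal_p(trend.s, trend.var_s)
    if acf_values is None:
        src = x
        max_lag = max(int(options.max_lag_frac * n), 1)
    else:
        src = np.asarray(acf_values, dtype=float)
        if src.size < MIN_POINTS_SOFT:
            src = x
        max_lag = n - 3  # heavier lags carry zero weight in the sum
    m = src.size
    max_lag = max(min(max_lag, m - 2, n - 3), 1)
    rho = _rank_acf(src, max_lag)
    bound = stats.norm.ppf(1.0 - options.acf_alpha / 2.0) / math.sqrt(m)
    i = np.arange(1, max_lag + 1, dtype=float)
    weights = (n - i) * (n - i - 1) * (n - i - 2)
    keep = np.abs(rho) > bound
    factor = 1.0 + 2.0 / (n * (n - 1) * (n - 2)) * float(
        np.sum(weights[keep] * rho[keep])
    )
    if options.floor_at_one:
        factor = max(factor, 1.0)
    var_corr = trend.var_s * factor
    return factor, var_corr, _normal_p(trend.s, var_corr)


def restrict_to_final_fortnight(
    series: IndicatorSeries,
    anchor_slot: int,
    fortnight_slots: int = FORTNIGHT_SLOTS,
) -> np.ndarray:
    """Valid indicator estimates whose window ends fall in the final
    two weeks before ``anchor_slot``.

    ``anchor_slot`` is the transition's aligned beep, or the (exclusive)
    end of a control segment — the control anchor mirrors the
    pre-transition evaluation window symmetrically.  When the series
    spans fewer than ``fortnight_slots`` slots of estimates, all
    available points are used.
    """
    ends = series.end_slots
    if len(ends) == 0:
        return np.empty(0)
    span = ends[-1] - ends[0] + 1
    if span < fortnight_slots:
        sel = np.ones(len(ends), dtype=bool)
    else:
        sel = (ends >= anchor_slot - fortnight_slots) & (ends < anchor_slot)
    est = series.estimates[sel]
    return est[~np.isnan(est)]


def test_indicator_series(
    series: IndicatorSeries,
    anchor_slot: int,
    segment_kind: str,
    transition_kind: Optional[str] = None,
    fortnight_slots: int = FORTNIGHT_SLOTS,
    hr_options: HamedRaoOptions = HamedRaoOptions(),
) -> EwsTestResult:
    """Run the full trend test for one indicator series."""
    result = EwsTestResult(
        patient_id=series.patient_id,
        state=series.state,
        indicator=series.indicator,
        segment_id=series.segment_id,
        segment_kind=segment_kind,
        transition_kind=transition_kind,
    )
    values = restrict_to_final_fortnight(series, anchor_slot, fortnight_slots)
    result.n_points = len(values)
    if len(values) < MIN_POINTS_HARD:
        result.reason = "too few valid indicator points"
        return result
    acf_values = None
    if hr_options.acf_source == "segment":
        est = series.estimates
        acf_values = est[~np.isnan(est)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        trend = kendall_trend(values)
        if not trend.valid:
            result.reason = "all indicator values tied"
            return result
        factor, var_corr, p_corr = hamed_rao_correct(
            values, trend, hr_options, acf_values=acf_values
        )
    result.tau = trend.tau
    result.s = trend.s
    result.var_s = trend.var_s
    result.hr_factor = factor
    result.p_raw = _normal_p(trend.s, trend.var_s)
    result.p_corrected = p_corr
    result.valid = True
    return result


def fdr_within_patient(
    results: Iterable[EwsTestResult],
    q: float = 0.05,
    use_corrected: bool = True,
    one_sided: bool = False,
) -> list[EwsTestResult]:
    """Benjamini-Hochberg step-up over one patient's full test family.

    The family spans all (state x indicator x segment) tests of the
    patient.  Decisions are attached in place: a test is an early warning
    signal when its (Hamed-Rao corrected) p-value survives BH at level
    ``q`` *and* tau is positive — a significant fall is not a warning
    signal.  ``one_sided`` halves p-values for positive tau (and sets 1
    - p/2 for negative) before BH, for sensitivity analyses.
    """
    results = list(results)
    pids = {r.patient_id for r in results}
    if len(pids) > 1:
        raise ValueError("FDR family must contain a single patient")
    valid = [r for r in results if r.valid]
    if not valid:
        return results

    def family_p(r: EwsTestResult) -> float:
        p = r.p_corrected if use_corrected else r.p_raw
        if one_sided:
            p = p / 2.0 if r.tau > 0 else 1.0 - p / 2.0
        return min(max(p, 0.0), 1.0)

    pvals = np.array([family_p(r) for r in valid])
    reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    # uncorrected comparator: same BH step, raw Mann-Kendall p-values
    p_raw = np.clip([r.p_raw for r in valid], 0.0, 1.0)
    reject_raw, _, _, _ = multipletests(p_raw, alpha=q, method="fdr_bh")
    for r, rej, rej_raw in zip(valid, reject, reject_raw):
        r.significant = bool(rej and r.tau > 0)
        r.significant_uncorrected = bool(rej_raw and r.tau > 0)
    return results
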