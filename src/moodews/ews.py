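"""Moving-window early-warning-signal indicators.

Two indicators of critical slowing down are estimated in sliding windows
over detrended residuals:

* ``ar1`` — the lag-1 autoregressive coefficient, computed as the
  least-squares slope of residual[t] on residual[t-1] over all pairs of
  consecutive scheduled slots in which both values were observed *and*
  both slots fall on the same calendar day (overnight lags are excluded);
* ``sd`` — the sample standard deviation (denominator n-1) of the
  observed residuals in the window.

The default window spans two weeks of the schedule: 14 whole days x 5
beeps/day = 70 scheduled slots, sliding one slot per step.  Because the
window is an integer number of whole weeks, every placement covers the
same number of weekend days (at day granularity); a strict mode with
stride = beeps_per_day keeps weekend composition constant at slot
granularity as well.

Missing data are never imputed: the AR(1) estimator uses pairwise
deletion, the SD listwise per value, and windows with insufficient
coverage are marked invalid rather than silently estimated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .grid import BeepGrid
from .preprocess import detrend_linear_window
from .transitions import AnalysisSegment

__all__ = [
    "WindowSpec",
    "IndicatorSeries",
    "enumerate_windows",
    "ar1_in_window",
    "sd_in_window",
    "indicator_series",
]

INDICATORS = ("ar1", "sd")


@dataclass(frozen=True)
class WindowSpec:
    """Moving-window geometry and coverage thresholds.

    ``length`` counts *scheduled* slots (default 70 = 14 days x 5
    beeps/day), not completed assessments.  ``min_values`` /
    ``min_pairs`` invalidate windows with insufficient observed coverage;
    both default to 50% of the window's capacity for the respective
    statistic — 70 slots for values, and (length - length/beeps_per_day)
    same-day lag pairs for the AR(1) slope, since the overnight pair of
    each day is excluded by design.
    """

    length: int = 70
    stride: int = 1
    min_values: Optional[int] = None
    min_pairs: Optional[int] = None
    min_coverage: float = 0.5
    enforce_whole_days: bool = True

    def __post_init__(self) -> None:
        if self.length < 2 or self.stride < 1:
            raise ValueError("length must be >= 2 and stride >= 1")
        if not 0.0 <= self.min_coverage <= 1.0:
            raise ValueError("min_coverage must be in [0, 1]")

    @classmethod
    def from_days(
        cls, days: int, beeps_per_day: int = 5, **kwargs
    ) -> "WindowSpec":
        """Window spanning whole calendar days (e.g. 14 days -> 70 slots)."""
        return cls(length=days * beeps_per_day, **kwargs)

    def validate_against(self, grid: BeepGrid) -> None:
        if self.enforce_whole_days and self.length % grid.beeps_per_day:
            raise ValueError(
                f"window length {self.length} is not a whole number of days "
                f"({grid.beeps_per_day} beeps/day); weekend-day constancy "
                "would be undefined"
            )

    def resolved_min_values(self) -> int:
        if self.min_values is not None:
            return self.min_values
        return int(np.ceil(self.min_coverage * self.length))

    def resolved_min_pairs(self, beeps_per_day: int) -> int:
        if self.min_pairs is not None:
            return self.min_pairs
        n_days = max(self.length // beeps_per_day, 1)
        capacity = self.length - n_days  # same-day lag pairs available
        return int(np.ceil(self.min_coverage * capacity))


@dataclass
class IndicatorSeries:
    """Per-window estimates of one indicator, anchored at window ends.

    ``end_slots`` holds the exclusive end slot of each window on the
    study grid; ``estimates`` is NaN where the window was invalid.
    ``n_obs``/``n_pairs`` carry per-window coverage for audit.
    """

    patient_id: str
    state: str
    indicator: str
    segment_id: str
    end_slots: np.ndarray
    estimates: np.ndarray
    n_obs: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        if self.indicator not in INDICATORS:
            raise ValueError(f"indicator must be one of {INDICATORS}")
        if np.any(np.diff(self.end_slots) <= 0):
            raise ValueError("window-end slots must be strictly increasing")

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.estimates)

    @property
    def n_windows(self) -> int:
        return len(self.end_slots)


def enumerate_windows(
    segment_length: int, spec: WindowSpec
) -> list[tuple[int, int]]:
    """All half-open window ranges fitting in a segment (segment-local).

    Ranges are ``[s, s + length)`` for ``s = 0, stride, 2*stride, ...``
    with ``s + length <= segment_length``.  A segment shorter than one
    window yields an empty list with a warning.
    """
    if segment_length < spec.length:
        warnings.warn(
            f"segment of {segment_length} slots shorter than one window "
            f"({spec.length}); no windows fitted",
            stacklevel=2,
        )
        return []
    starts = range(0, segment_length - spec.length + 1, spec.stride)
    return [(s, s + spec.length) for s in starts]


def _pair_mask(
    observed: np.ndarray, start_slot: int, beeps_per_day: int
) -> np.ndarray:
    """Valid lag-1 pairs anchored at t: both slots observed, same day.

    ``start_slot`` is the absolute slot index of element 0, so day
    boundaries are computed on the study calendar even for segment
    slices.  Index 0 of the result is always False (no pair before the
    first slot).
    """
    n = len(observed)
    mask = np.zeros(n, dtype=bool)
    if n < 2:
        return mask
    abs_idx = np.arange(start_slot, start_slot + n)
    same_day = (abs_idx[1:] // beeps_per_day) == (abs_idx[:-1] // beeps_per_day)
    mask[1:] = observed[1:] & observed[:-1] & same_day
    return mask


def ar1_in_window(
    residuals: np.ndarray,
    start_slot: int,
    beeps_per_day: int,
    min_pairs: int = 1,
) -> tuple[float, int]:
    """Lag-1 autoregressive coefficient in one window.

    Least-squares slope of residual[t] on residual[t-1] over same-day
    observed pairs.  Returns ``(estimate, n_pairs)``; the estimate is NaN
    when fewer than ``min_pairs`` pairs exist or the lagged values have
    zero variance.
    """
    r = np.asarray(residuals, dtype=float)
    obs = ~np.isnan(r)
    pairs = _pair_mask(obs, start_slot, beeps_per_day)
    t = np.flatnonzero(pairs)
    n = t.size
    if n < max(min_pairs, 2):
        return float("nan"), n
    x = r[t - 1]
    y = r[t]
    vx = x.var()
    if vx == 0.0:
        return float("nan"), n
    slope = ((x * y).mean() - x.mean() * y.mean()) / vx
    return float(slope), n


def sd_in_window(
    residuals: np.ndarray, min_values: int = 2
) -> tuple[float, int]:
    """Sample standard deviation (ddof=1) of observed residuals in a window."""
    r = np.asarray(residuals, dtype=float)
    obs = r[~np.isnan(r)]
    n = obs.size
    if n < max(min_values, 2):
        return float("nan"), n
    return float(np.std(obs, ddof=1)), n


def _csum(a: np.ndarray) -> np.ndarray:
    """Cumulative sum with a leading zero: range sums via C[j] - C[i]."""
    return np.concatenate(([0.0], np.cumsum(a)))


def _rolling_ar1(
    r: np.ndarray,
    obs: np.ndarray,
    starts: np.ndarray,
    length: int,
    start_slot: int,
    beeps_per_day: int,
    min_pairs: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-window AR(1) slope via cumulative pair sums."""
    x = np.where(obs, r, 0.0)
    pair = _pair_mask(obs, start_slot, beeps_per_day)
    a = np.where(pair, np.concatenate(([0.0], x[:-1])), 0.0)  # lagged value
    b = np.where(pair, x, 0.0)  # leading value
    cN = _csum(pair.astype(float))
    cA = _csum(a)
    cB = _csum(b)
    cAA = _csum(a * a)
    cAB = _csum(a * b)
    lo = starts + 1  # pair index t lies in [s+1, s+length)
    hi = starts + length
    n = cN[hi] - cN[lo]
    sa = cA[hi] - cA[lo]
    sb = cB[hi] - cB[lo]
    saa = cAA[hi] - cAA[lo]
    sab = cAB[hi] - cAB[lo]
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = n * saa - sa * sa
        est = (n * sab - sa * sb) / denom
    est = np.where((n >= max(min_pairs, 2)) & (denom > 0), est, np.nan)
    return est, n.astype(int)


def _rolling_sd(
    r: np.ndarray,
    obs: np.ndarray,
    starts: np.ndarray,
    length: int,
    min_values: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-window sample SD via cumulative sums."""
    x = np.where(obs, r, 0.0)
    cN = _csum(obs.astype(float))
    cX = _csum(x)
    cXX = _csum(x * x)
    hi = starts + length
    n = cN[hi] - cN[starts]
    sx = cX[hi] - cX[starts]
    sxx = cXX[hi] - cXX[starts]
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (sxx - sx * sx / n) / (n - 1)
        est = np.sqrt(np.maximum(var, 0.0))
    est = np.where(n >= max(min_values, 2), est, np.nan)
    return est, n.astype(int)


def indicator_series(
    residuals: np.ndarray,
    segment: AnalysisSegment,
    grid: BeepGrid,
    spec: WindowSpec,
    indicator: str,
    patient_id: str | None = None,
    state: str = "",
    detrend: str = "none",
    exclude_final_window: Optional[bool] = None,
) -> IndicatorSeries:
    """Apply a window estimator across a segment.

    ``residuals`` covers the *full study grid*; the segment's slice is
    used.  For a pre-transition segment the window abutting the
    transition beep (the one whose exclusive end equals the segment end)
    is dropped, so a 150-slot pre-transition segment yields 150 - 70 = 80
    windows; it is kept when dropping it would leave no window at all.
    Control segments use every window.

    ``detrend='linear_within_window'`` applies the OLS line removal to
    each window's raw values before estimating (the sensitivity variant);
    the default assumes ``residuals`` were already detrended over the
    whole segment.
    """
    if indicator not in INDICATORS:
        raise ValueError(f"indicator must be one of {INDICATORS}")
    if detrend not in ("none", "linear_within_window"):
        raise ValueError("detrend must be 'none' or 'linear_within_window'")
    spec.validate_against(grid)
    pid = patient_id if patient_id is not None else segment.patient_id
    r = np.asarray(residuals, dtype=float)[segment.start_slot : segment.end_slot]
    obs = ~np.isnan(r)
    ranges = enumerate_windows(segment.length, spec)
    if exclude_final_window is None:
        exclude_final_window = segment.kind == "pre_transition"
    if (
        exclude_final_window
        and len(ranges) > 1
        and ranges[-1][1] == segment.length
    ):
        ranges = ranges[:-1]
    starts = np.array([s for s, _ in ranges], dtype=int)
    ends = np.array([e for _, e in ranges], dtype=int)
    min_values = spec.resolved_min_values()
    min_pairs = spec.resolved_min_pairs(grid.beeps_per_day)

    if len(ranges) == 0:
        est = np.empty(0)
        n_obs = n_pairs = np.empty(0, dtype=int)
    elif detrend == "linear_within_window":
        est = np.empty(len(ranges))
        n_obs = np.empty(len(ranges), dtype=int)
        n_pairs = np.empty(len(ranges), dtype=int)
        for i, (s, e) in enumerate(ranges):
            w = detrend_linear_window(r[s:e])
            n_obs[i] = int((~np.isnan(w)).sum())
            if indicator == "ar1":
                est[i], n_pairs[i] = ar1_in_window(
                    w, segment.start_slot + s, grid.beeps_per_day, min_pairs
                )
            else:
                est[i], _ = sd_in_window(w, min_values)
                n_pairs[i] = 0
    else:
        cN = _csum(obs.astype(float))
        n_obs = (cN[ends] - cN[starts]).astype(int)
        if indicator == "ar1":
            est, n_pairs = _rolling_ar1(
                r, obs, starts, spec.length, segment.start_slot,
                grid.beeps_per_day, min_pairs,
            )
        else:
            est, n_obs = _rolling_sd(r, obs, starts, spec.length, min_values)
            n_pairs = np.zeros(len(ranges), dtype=int)

    return IndicatorSeries(
        patient_id=pid,
        state=state,
        indicator=indicator,
        segment_id=segment.segment_id,
        end_slots=segment.start_slot + ends,
        estimates=np.asarray(est, dtype=float),
        n_obs=np.asarray(n_obs, dtype=int),
        n_pairs=np.asarray(n_pairs, dtype=int),
    )
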