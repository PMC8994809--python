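"""Per-segment preprocessing: winsorization and detrending.

The moving-window indicators assume a (locally) stationary mean.  Each
pre-transition or control segment is therefore winsorized (values below
the 5th / above the 95th percentile of the segment are clipped to those
percentiles) and detrended.  The primary detrender is a Gaussian-kernel
(Nadaraya-Watson) smoother fitted over the whole segment; a linear
within-window detrender is available as a sensitivity variant.  Missing
beeps are never imputed: every operation preserves the missingness
pattern exactly.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
from sklearn.metrics import cohen_kappa_score

__all__ = [
    "winsorize",
    "default_bandwidth",
    "detrend_kernel",
    "detrend_linear_window",
    "method_agreement",
    "KAPPA_BANDS",
]

#: Interpretation bands for Cohen's kappa between detrending variants.
KAPPA_BANDS = (
    (0.40, "low"),
    (0.60, "weak"),
    (0.80, "moderate"),
    (float("inf"), "high"),
)

MIN_WINSOR_OBS = 20


def winsorize(
    values: np.ndarray,
    lower: float = 5.0,
    upper: float = 95.0,
    min_obs: int = MIN_WINSOR_OBS,
    method: str = "linear",
) -> np.ndarray:
    """Clip observed values to the [P5, P95] of *this* segment.

    ``method`` is the quantile convention (any ``np.percentile`` method);
    the default is linear interpolation between order statistics.  Note
    that only order-statistic conventions (e.g. ``"nearest"``) make the
    operation exactly idempotent — under interpolation a second pass can
    tighten the bounds slightly.  Missing entries are untouched.  With
    fewer than ``min_obs`` observed values the percentiles are
    ill-determined: the series is passed through unchanged with a
    warning.  An all-missing series is an error.
    """
    values = np.asarray(values, dtype=float)
    obs = ~np.isnan(values)
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise ValueError("cannot winsorize an all-missing series")
    if n_obs < min_obs:
        warnings.warn(
            f"only {n_obs} observed values (< {min_obs}); "
            "winsorization skipped",
            stacklevel=2,
        )
        return values.copy()
    p_lo, p_hi = np.percentile(values[obs], [lower, upper], method=method)
    out = values.copy()
    out[obs] = np.clip(values[obs], p_lo, p_hi)
    return out


def default_bandwidth(values: np.ndarray, fraction: float = 0.10) -> float:
    """Kernel bandwidth as a fraction of the observed slot-index span."""
    obs = np.flatnonzero(~np.isnan(np.asarray(values, dtype=float)))
    if obs.size < 2:
        raise ValueError("need at least two observed beeps")
    span = float(obs[-1] - obs[0])
    return max(fraction * span, 1.0)


def detrend_kernel(values: np.ndarray, bandwidth: float) -> np.ndarray:
    """Gaussian-kernel (Nadaraya-Watson) detrending over the segment.

    The smoother runs over the scheduled slot index of the observed beeps
    only; gaps therefore do not stretch the kernel.  Residuals are
    centered so they sum to zero over observed beeps — an innocuous
    normalization, since both window indicators (lag-1 slope and SD) are
    shift-invariant.  Returns residuals on the full grid, NaN where the
    source was missing.
    """
    values = np.asarray(values, dtype=float)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    obs_idx = np.flatnonzero(~np.isnan(values))
    if obs_idx.size < 2:
        raise ValueError("need at least two observed beeps to detrend")
    t = obs_idx.astype(float)
    x = values[obs_idx]
    z = (t[None, :] - t[:, None]) / bandwidth
    w = np.exp(-0.5 * z * z)
    total = w.sum(axis=1)
    # each beep carries self-weight 1; without neighbour mass the smoother
    # degenerates to interpolation and residuals vanish identically
    if (total - 1.0).min() < 1e-12:
        raise ValueError(
            "kernel weight underflow at some observed beeps "
            "(no neighbour within reach); increase the bandwidth"
        )
    smooth = (w @ x) / total
    resid = x - smooth
    resid -= resid.mean()
    out = np.full_like(values, np.nan)
    out[obs_idx] = resid
    return out


def detrend_linear_window(window_values: np.ndarray) -> np.ndarray:
    """OLS line over (slot index, value) within one window; residuals out.

    Residuals are returned on the same grid (NaN where missing).  Fewer
    than 3 observed values cannot support a line: the window is invalid
    and all-NaN is returned.
    """
    window_values = np.asarray(window_values, dtype=float)
    obs_idx = np.flatnonzero(~np.isnan(window_values))
    out = np.full_like(window_values, np.nan)
    if obs_idx.size < 3:
        return out
    t = obs_idx.astype(float)
    x = window_values[obs_idx]
    slope, intercept = np.polyfit(t, x, 1)
    out[obs_idx] = x - (slope * t + intercept)
    return out


def kappa_band(kappa: float) -> str:
    if np.isnan(kappa):
        return "undefined"
    for upper, label in KAPPA_BANDS:
        if kappa < upper:
            return label
    return "high"


def method_agreement(
    flags_a: Iterable[bool], flags_b: Iterable[bool]
) -> tuple[float, str]:
    """Cohen's kappa between two sets of significance flags.

    ``flags_a`` and ``flags_b`` are the significant/non-significant labels
    of the same (state, indicator, segment) test grid under the two
    detrending variants.  Returns (kappa, interpretation band).  When the
    marginals are degenerate (a variant assigns a single label throughout)
    kappa is undefined and NaN is returned, flagged as such.
    """
    a = np.asarray(list(flags_a), dtype=bool)
    b = np.asarray(list(flags_b), dtype=bool)
    if a.shape != b.shape:
        raise ValueError("flag sets must cover identical test grids")
    if a.size == 0:
        raise ValueError("empty test grid")
    if len(np.unique(a)) < 2 and len(np.unique(b)) < 2:
        if np.array_equal(a, b):
            # identical constant labels: agreement perfect but chance-corrected
            # kappa is 0/0
            return float("nan"), "undefined"
        return float("nan"), "undefined"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kappa = float(cohen_kappa_score(a, b))
    return kappa, kappa_band(kappa)
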