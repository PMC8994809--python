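"""In-memory containers for EMA and weekly-scale data."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .grid import BeepGrid

#: The 17 momentary affect/symptom items analyzed for early warning
#: signals, each rated on a continuous 0-100 slider.
STATE_NAMES: tuple[str, ...] = (
    "cheerful",
    "content",
    "down",
    "anxious",
    "irritated",
    "worry",
    "agitated",
    "tired",
    "distracted",
    "full_of_ideas",
    "racing_thoughts",
    "full_of_energy",
    "physically_active",
    "extremely_well",
    "socializing",
    "focus_switch",
    "restless",
)

#: Weekly instruments: Altman Self-Rating Mania Scale and Quick Inventory
#: of Depressive Symptomatology (Self-Report), with their sum-score ranges.
INSTRUMENT_RANGES = {"ASRM": (0, 20), "QIDS": (0, 48)}


@dataclass
class EmaSeries:
    """One patient x one momentary state on the scheduled beep grid.

    ``values`` has one entry per scheduled slot; NaN marks a missed beep.
    Observed values lie in [0, 100].
    """

    patient_id: str
    state: str
    values: np.ndarray
    grid: BeepGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_slots,):
            raise ValueError(
                f"values must have one entry per scheduled slot "
                f"({self.grid.n_slots}), got {self.values.shape}"
            )
        obs = self.values[~np.isnan(self.values)]
        if obs.size and (obs.min() < 0 or obs.max() > 100):
            raise ValueError("EMA values must lie in [0, 100]")

    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.sum())


@dataclass
class ResidualSeries:
    """Detrended residuals on the same grid as the source EMA series.

    The missingness pattern is identical to the source series: detrending
    never imputes.
    """

    patient_id: str
    state: str
    residuals: np.ndarray
    grid: BeepGrid
    method: str = "gaussian_kernel"
    bandwidth: Optional[float] = None

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)


@dataclass
class WeeklyScale:
    """Weekly sum scores for one patient on one symptom instrument.

    ``scores`` is indexed by week (0-based); NaN marks a week without a
    completed questionnaire.  ``completion_slots`` optionally records the
    beep-grid slot at which each weekly questionnaire was completed, used
    for week-to-beep alignment when available.
    """

    patient_id: str
    instrument: str
    scores: np.ndarray
    completion_slots: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.instrument not in INSTRUMENT_RANGES:
            raise ValueError(f"unknown instrument {self.instrument!r}")
        self.scores = np.asarray(self.scores, dtype=float)
        lo, hi = INSTRUMENT_RANGES[self.instrument]
        obs = self.scores[~np.isnan(self.scores)]
        if obs.size and (obs.min() < lo or obs.max() > hi):
            raise ValueError(
                f"{self.instrument} scores must lie in [{lo}, {hi}]"
            )

    @property
    def n_weeks(self) -> int:
        return len(self.scores)
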