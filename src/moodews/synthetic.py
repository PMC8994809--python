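"""Synthetic EMA cohorts with programmable early-warning structure.

The generator emulates the two data streams the analysis consumes:

* momentary-state EMA series (5 scheduled beeps/day, 0-100 sliders,
  ~24% missed beeps), produced by a latent AR(1) process whose lag-1
  coefficient and/or innovation SD can ramp up linearly over a
  configurable pre-transition window — the data-level signature of
  critical slowing down; and
* weekly ASRM/QIDS sum scores, stable at low values except for
  programmed abrupt (within one week) jumps of >= 6 points that define
  manic/depressive transitions.

Because every planted feature is recorded in a :class:`GroundTruth`
object, the full detection pipeline can be scored against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import BeepGrid
from .series import INSTRUMENT_RANGES, STATE_NAMES, EmaSeries, WeeklyScale
from .transitions import TransitionEvent

__all__ = [
    "TransitionSpec",
    "EwsSpec",
    "SimConfig",
    "GroundTruth",
    "simulate_ema",
    "simulate_weekly",
    "simulate_cohort",
]

#: Episode persists this many weeks at the elevated level after a jump.
_EPISODE_WEEKS = 2

#: Minimum spacing (weeks) between two transitions of the same patient so
#: that the two stable antecedent weeks of the second do not collide with
#: the first episode.
_MIN_TRANSITION_GAP = _EPISODE_WEEKS + 3


@dataclass(frozen=True)
class TransitionSpec:
    """A programmed abrupt symptom jump on one weekly instrument."""

    patient_id: str
    kind: str  # 'manic' (ASRM) or 'depressive' (QIDS)
    week: int
    magnitude: int = 6

    def __post_init__(self) -> None:
        if self.kind not in ("manic", "depressive"):
            raise ValueError("kind must be 'manic' or 'depressive'")
        if self.week < 3:
            raise ValueError(
                "transition week must be >= 3 (two stable antecedent weeks "
                "plus a computable baseline difference are required)"
            )
        if self.magnitude < 6:
            raise ValueError("transition magnitude must be >= 6")

    @property
    def instrument(self) -> str:
        return "ASRM" if self.kind == "manic" else "QIDS"


@dataclass(frozen=True)
class EwsSpec:
    """A planted pre-transition ramp in AR coefficient and/or innovation SD.

    ``ar_ramp``/``sd_ramp`` give (start, end) values of the latent AR(1)
    coefficient phi and the innovation standard deviation sigma.  The ramp
    is linear over the final ``ramp_days`` days before the anchor
    transition (the patient's first transition unless ``transition_week``
    says otherwise).
    """

    patient_id: str
    state: str
    indicator: str  # 'ar' | 'sd' | 'both'
    ar_ramp: tuple[float, float] | None = None
    sd_ramp: tuple[float, float] | None = None
    ramp_days: int = 14
    transition_week: int | None = None

    def __post_init__(self) -> None:
        if self.indicator not in ("ar", "sd", "both"):
            raise ValueError("indicator must be 'ar', 'sd' or 'both'")
        if self.indicator in ("ar", "both") and self.ar_ramp is None:
            raise ValueError(f"indicator {self.indicator!r} needs ar_ramp")
        if self.indicator in ("sd", "both") and self.sd_ramp is None:
            raise ValueError(f"indicator {self.indicator!r} needs sd_ramp")
        if self.ar_ramp is not None:
            for phi in self.ar_ramp:
                if not -1.0 < phi < 1.0:
                    raise ValueError("AR coefficients must lie in (-1, 1)")
        if self.sd_ramp is not None:
            for s in self.sd_ramp:
                if s <= 0:
                    raise ValueError("innovation SDs must be positive")
        if self.ramp_days < 1:
            raise ValueError("ramp_days must be positive")


@dataclass
class SimConfig:
    """Study-level simulation parameters.

    Defaults mirror the monitoring design the analysis targets: ~17 weeks
    of 5 daily beeps on 17 momentary states with roughly 24% missed
    assessments (76% compliance), a baseline lag-1 coefficient of 0.2 and
    innovation SD of 10 slider points.
    """

    n_patients: int = 1
    days: int = 119
    beeps_per_day: int = 5
    n_states: int = 17
    missing_rate: float = 0.24
    transition_specs: list[TransitionSpec] = field(default_factory=list)
    ews_specs: list[EwsSpec] = field(default_factory=list)
    baseline_ar: float = 0.2
    baseline_sd: float = 10.0
    gain: float = 1.0
    center: float = 50.0
    start_weekday: int = 0  # Monday
    overnight_carryover: bool = False
    post_transition_missing_rate: float | None = None
    unstable_patient_ids: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be a probability")
        if not -1.0 < self.baseline_ar < 1.0:
            raise ValueError("baseline_ar must lie in (-1, 1)")
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be positive")
        self.validate()

    @property
    def grid(self) -> BeepGrid:
        return BeepGrid(self.days, self.beeps_per_day, self.start_weekday)

    @property
    def patient_ids(self) -> list[str]:
        return [f"P{i:02d}" for i in range(self.n_patients)]

    @property
    def state_names(self) -> list[str]:
        base = list(STATE_NAMES[: self.n_states])
        base += [f"state_{i}" for i in range(len(base), self.n_states)]
        return base

    def transitions_for(self, patient_id: str) -> list[TransitionSpec]:
        specs = [t for t in self.transition_specs if t.patient_id == patient_id]
        return sorted(specs, key=lambda t: t.week)

    def validate(self) -> None:
        grid = self.grid
        ids = set(self.patient_ids)
        states = set(self.state_names)
        for t in self.transition_specs:
            if t.patient_id not in ids:
                raise ValueError(f"unknown patient {t.patient_id!r}")
            if t.week >= grid.n_weeks:
                raise ValueError(
                    f"transition week {t.week} outside the {grid.n_weeks}-week study"
                )
        for pid in ids:
            weeks = [t.week for t in self.transitions_for(pid)]
            for a, b in zip(weeks, weeks[1:]):
                if b - a < _MIN_TRANSITION_GAP:
                    raise ValueError(
                        f"transitions of {pid} closer than "
                        f"{_MIN_TRANSITION_GAP} weeks"
                    )
        for e in self.ews_specs:
            if e.patient_id not in ids:
                raise ValueError(f"unknown patient {e.patient_id!r}")
            if e.state not in states:
                raise ValueError(f"unknown state {e.state!r}")
            week = self._anchor_week(e)
            if week is None:
                raise ValueError(
                    f"EWS spec for {e.patient_id} has no anchor transition"
                )
            anchor = grid.week_start_slot(week)
            ramp_start = anchor - e.ramp_days * self.beeps_per_day
            if ramp_start < 0:
                raise ValueError(
                    "ramp duration exceeds the pre-transition period"
                )
            earlier = [
                t for t in self.transitions_for(e.patient_id) if t.week < week
            ]
            if earlier and ramp_start < grid.week_start_slot(earlier[-1].week):
                raise ValueError(
                    "ramp window overlaps an earlier transition of "
                    f"{e.patient_id}"
                )

    def _anchor_week(self, spec: EwsSpec) -> int | None:
        if spec.transition_week is not None:
            return spec.transition_week
        trans = self.transitions_for(spec.patient_id)
        return trans[0].week if trans else None


@dataclass
class GroundTruth:
    """Planted truth: transitions per patient and true-EWS flags.

    ``ews`` holds (patient_id, state, indicator) triples with indicator in
    {'ar1', 'sd'} — the naming used by the estimation engine.
    """

    transitions: dict[str, list[TransitionEvent]]
    ews: set[tuple[str, str, str]]

    def has_ews(self, patient_id: str, state: str, indicator: str) -> bool:
        return (patient_id, state, indicator) in self.ews

    def all_transitions(self) -> list[TransitionEvent]:
        out: list[TransitionEvent] = []
        for pid in sorted(self.transitions):
            out.extend(self.transitions[pid])
        return out


def _build_truth(config: SimConfig) -> GroundTruth:
    grid = config.grid
    transitions: dict[str, list[TransitionEvent]] = {}
    for spec in config.transition_specs:
        ev = TransitionEvent(
            patient_id=spec.patient_id,
            kind=spec.kind,
            week=spec.week,
            jump=spec.magnitude,
            aligned_slot=grid.week_start_slot(spec.week),
        )
        transitions.setdefault(spec.patient_id, []).append(ev)
    for evs in transitions.values():
        evs.sort(key=lambda e: e.week)
    ews: set[tuple[str, str, str]] = set()
    for e in config.ews_specs:
        if e.indicator in ("ar", "both"):
            ews.add((e.patient_id, e.state, "ar1"))
        if e.indicator in ("sd", "both"):
            ews.add((e.patient_id, e.state, "sd"))
    return GroundTruth(transitions=transitions, ews=ews)


def _param_arrays(
    config: SimConfig, patient_id: str, state: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-slot phi and sigma arrays, with any programmed linear ramps."""
    grid = config.grid
    n = grid.n_slots
    phi = np.full(n, config.baseline_ar)
    sigma = np.full(n, config.baseline_sd)
    for e in config.ews_specs:
        if e.patient_id != patient_id or e.state != state:
            continue
        week = config._anchor_week(e)
        anchor = grid.week_start_slot(week)
        start = anchor - e.ramp_days * config.beeps_per_day
        ramp_len = anchor - start
        # the ramp expresses the approach to the tipping point; after the
        # transition the parameters reset to baseline so later segments of
        # the same patient start from a clean state
        if e.ar_ramp is not None and e.indicator in ("ar", "both"):
            phi[start:anchor] = np.linspace(*e.ar_ramp, ramp_len)
        if e.sd_ramp is not None and e.indicator in ("sd", "both"):
            sigma[start:anchor] = np.linspace(*e.sd_ramp, ramp_len)
    return phi, sigma


def _latent_ar1(
    phi: np.ndarray,
    sigma: np.ndarray,
    eps: np.ndarray,
    grid: BeepGrid,
    overnight_carryover: bool,
) -> np.ndarray:
    """Latent AR(1) path with independent overnight innovations.

    The first beep of each day is drawn from the local stationary
    distribution rather than carried over from the previous evening,
    matching the estimator's overnight-lag exclusion.
    """
    n = grid.n_slots
    bpd = grid.beeps_per_day
    x = np.empty(n)
    stat_sd = sigma / np.sqrt(1.0 - phi**2)
    x[0] = stat_sd[0] * eps[0]
    for t in range(1, n):
        if not overnight_carryover and t % bpd == 0:
            x[t] = stat_sd[t] * eps[t]
        else:
            x[t] = phi[t] * x[t - 1] + sigma[t] * eps[t]
    return x


def simulate_ema(config: SimConfig) -> tuple[list[EmaSeries], GroundTruth]:
    """Generate the EMA table for every patient x state, plus ground truth.

    Latent AR(1) values are affine-mapped to the 0-100 slider scale
    (centered at ``config.center`` with slope ``config.gain``) and
    clipped; beeps are deleted completely at random at
    ``config.missing_rate`` (optionally at an elevated rate after the
    first transition).  Output is reproducible under ``config.seed``.
    """
    grid = config.grid
    rng = np.random.default_rng(config.seed)
    truth = _build_truth(config)
    series: list[EmaSeries] = []
    for pid in config.patient_ids:
        trans = truth.transitions.get(pid, [])
        first_slot = trans[0].aligned_slot if trans else None
        for state in config.state_names:
            phi, sigma = _param_arrays(config, pid, state)
            eps = rng.standard_normal(grid.n_slots)
            u = rng.random(grid.n_slots)
            x = _latent_ar1(phi, sigma, eps, grid, config.overnight_carryover)
            y = np.clip(config.center + config.gain * x, 0.0, 100.0)
            rate = np.full(grid.n_slots, config.missing_rate)
            if (
                config.post_transition_missing_rate is not None
                and first_slot is not None
            ):
                rate[first_slot:] = config.post_transition_missing_rate
            y[u < rate] = np.nan
            series.append(EmaSeries(pid, state, y, grid))
    return series, truth


def _stable_weekly(rng: np.random.Generator, n_weeks: int) -> np.ndarray:
    """Low, stable baseline: integer scores < 6 with week-to-week |change| <= 2."""
    base = int(rng.integers(1, 4))
    jitter = rng.integers(-1, 2, size=n_weeks)
    return np.clip(base + jitter, 0, 5).astype(float)


def _oscillating_weekly(rng: np.random.Generator, n_weeks: int) -> np.ndarray:
    """Alternating +/-5 swings: never a >= 6 rise, but no stable run either."""
    base = int(rng.integers(0, 3))
    swing = 5 * (np.arange(n_weeks) % 2)
    return (base + swing).astype(float)


def simulate_weekly(
    config: SimConfig, truth: GroundTruth | None = None
) -> list[WeeklyScale]:
    """Generate weekly ASRM and QIDS series consistent with the config.

    Baseline weeks are small integers (< 6) with week-to-week changes of
    at most 2 points.  At each programmed transition the matching
    instrument jumps by the specified magnitude within one week, after
    two frozen (perfectly stable) antecedent weeks, stays elevated for
    the episode and then returns to baseline.  Patients listed in
    ``config.unstable_patient_ids`` oscillate by 5 points week to week on
    the ASRM, so they never transition yet offer no stable control run.
    """
    grid = config.grid
    n_weeks = grid.n_weeks
    if truth is not None:
        for evs in truth.transitions.values():
            for ev in evs:
                if ev.week >= n_weeks:
                    raise ValueError(
                        f"transition week {ev.week} outside the study window"
                    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    out: list[WeeklyScale] = []
    for pid in config.patient_ids:
        unstable = pid in config.unstable_patient_ids
        for instrument in ("ASRM", "QIDS"):
            if unstable and instrument == "ASRM":
                scores = _oscillating_weekly(rng, n_weeks)
            else:
                scores = _stable_weekly(rng, n_weeks)
            for spec in config.transitions_for(pid):
                if spec.instrument != instrument:
                    continue
                w, m = spec.week, spec.magnitude
                base = scores[max(w - 3, 0)]
                scores[w - 2 : w] = base  # two stable antecedent weeks
                peak = base + m
                lo, hi = INSTRUMENT_RANGES[instrument]
                if peak > hi:
                    raise ValueError(
                        f"jump of {m} from baseline {base:g} exceeds the "
                        f"{instrument} maximum of {hi}"
                    )
                scores[w] = peak
                end = min(w + _EPISODE_WEEKS, n_weeks)
                scores[w + 1 : end] = peak
            out.append(WeeklyScale(pid, instrument, scores))
    return out


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[EmaSeries], list[WeeklyScale], GroundTruth]:
    """Convenience wrapper: EMA series, weekly scales and ground truth."""
    ema, truth = simulate_ema(config)
    weekly = simulate_weekly(config, truth)
    return ema, weekly, truth
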