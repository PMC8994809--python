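"""Transition detection on weekly symptom scales and analysis segments.

A *transition* is an abrupt — i.e. within one week — rise of at least
``jump_threshold`` (default 6) points on the ASRM (manic) or QIDS-SR
(depressive) sum score, with no comparable rise in the two preceding
weeks.  Detected transitions anchor pre-transition analysis segments on
the beep grid; patients without transitions contribute control segments
(stable stretches used to estimate false-positive rates).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .grid import DAYS_PER_WEEK, BeepGrid
from .series import WeeklyScale

logger = logging.getLogger(__name__)

#: Week-to-week rise defining a transition.
DEFAULT_JUMP_THRESHOLD = 6

#: Week-to-week |change| above which a stretch no longer qualifies as a
#: stable control period.
DEFAULT_STABILITY_THRESHOLD = 4

#: Control segments target the mean pre-transition length observed in
#: transitioning patients (~245 scheduled beeps = 49 days at 5 beeps/day).
DEFAULT_CONTROL_LENGTH = 245

_KIND_BY_INSTRUMENT = {"ASRM": "manic", "QIDS": "depressive"}


@dataclass(frozen=True)
class TransitionEvent:
    """One detected (or planted) abrupt symptom transition."""

    patient_id: str
    kind: str  # 'manic' | 'depressive'
    week: int
    jump: float
    aligned_slot: int  # first scheduled beep of the transition week

    def __post_init__(self) -> None:
        if self.kind not in ("manic", "depressive"):
            raise ValueError("kind must be 'manic' or 'depressive'")

    @property
    def segment_id(self) -> str:
        return f"{self.patient_id}:{self.kind}:w{self.week}"


@dataclass(frozen=True)
class AnalysisSegment:
    """Half-open slot range on the scheduled grid feeding one analysis.

    ``kind`` is ``pre_transition`` (ends at the transition's aligned
    beep) or ``control`` (stable stretch of a non-transitioning patient).
    """

    patient_id: str
    kind: str  # 'pre_transition' | 'control'
    start_slot: int
    end_slot: int
    event: Optional[TransitionEvent] = None

    def __post_init__(self) -> None:
        if self.kind not in ("pre_transition", "control"):
            raise ValueError("kind must be 'pre_transition' or 'control'")
        if self.end_slot <= self.start_slot:
            raise ValueError("empty segment")
        if self.kind == "pre_transition" and self.event is None:
            raise ValueError("pre_transition segment needs its event")

    @property
    def length(self) -> int:
        return self.end_slot - self.start_slot

    @property
    def segment_id(self) -> str:
        if self.event is not None:
            return self.event.segment_id
        return f"{self.patient_id}:control:{self.start_slot}"

    @property
    def transition_kind(self) -> Optional[str]:
        return self.event.kind if self.event is not None else None


def _week_to_slot(scale: WeeklyScale, week: int, grid: BeepGrid) -> int:
    """Align a transition week to its first scheduled beep.

    Uses the weekly questionnaire completion slot when recorded,
    otherwise ``week * 7 * beeps_per_day``.
    """
    if scale.completion_slots is not None:
        slot = scale.completion_slots[week]
        if not np.isnan(slot):
            return int(slot)
    return grid.week_start_slot(week)


def detect_transitions(
    weekly: Iterable[WeeklyScale],
    grid: BeepGrid | None = None,
    jump_threshold: float = DEFAULT_JUMP_THRESHOLD,
) -> list[TransitionEvent]:
    """Find every abrupt symptom rise qualifying as a transition.

    Week ``w`` qualifies when ``score[w] - score[w-1] >= jump_threshold``
    and neither of the two preceding week-to-week differences reached the
    threshold.  Antecedent differences falling before the start of the
    recorded series are treated as stable; an antecedent week that is
    *recorded as missing* disqualifies the candidate (logged), since the
    stability requirement cannot be verified.

    Events are returned sorted by patient, then week.
    """
    events: list[TransitionEvent] = []
    for scale in sorted(
        weekly, key=lambda s: (str(s.patient_id), s.instrument)
    ):
        kind = _KIND_BY_INSTRUMENT[scale.instrument]
        s = scale.scores
        n = len(s)
        if n < 4:
            warnings.warn(
                f"{scale.patient_id}/{scale.instrument}: fewer than 4 weeks "
                "of data; transition candidates skipped",
                stacklevel=2,
            )
            continue
        for w in range(1, n):
            if np.isnan(s[w]) or np.isnan(s[w - 1]):
                continue
            jump = s[w] - s[w - 1]
            if jump < jump_threshold:
                continue
            disqualified = False
            for back in (1, 2):  # differences ending at weeks w-1 and w-2
                hi, lo = w - back, w - back - 1
                if lo < 0:
                    continue  # before the recorded series: treated as stable
                if np.isnan(s[hi]) or np.isnan(s[lo]):
                    logger.info(
                        "%s/%s: candidate at week %d disqualified "
                        "(antecedent week missing)",
                        scale.patient_id,
                        scale.instrument,
                        w,
                    )
                    disqualified = True
                    break
                if s[hi] - s[lo] >= jump_threshold:
                    disqualified = True
                    break
            if disqualified:
                continue
            used_grid = grid or BeepGrid(days=n * DAYS_PER_WEEK)
            events.append(
                TransitionEvent(
                    patient_id=scale.patient_id,
                    kind=kind,
                    week=w,
                    jump=float(jump),
                    aligned_slot=_week_to_slot(scale, w, used_grid),
                )
            )
    events.sort(key=lambda e: (str(e.patient_id), e.week, e.kind))
    return events


def extract_pre_transition_segment(
    event: TransitionEvent,
    grid: BeepGrid,
    previous_event: TransitionEvent | None = None,
    min_length: int = 70,
) -> AnalysisSegment:
    """Carve the pre-transition segment ending at the aligned beep.

    The segment runs from the start of the study — or from the aligned
    beep of the patient's previous transition, so successive segments
    never overlap — up to (excluding) the event's aligned beep.
    """
    start = 0
    if previous_event is not None:
        if previous_event.patient_id != event.patient_id:
            raise ValueError("previous_event belongs to a different patient")
        start = previous_event.aligned_slot
    end = event.aligned_slot
    if end - start < min_length:
        raise ValueError(
            f"insufficient pre-transition data for {event.segment_id}: "
            f"{end - start} slots < one window ({min_length})"
        )
    return AnalysisSegment(
        patient_id=event.patient_id,
        kind="pre_transition",
        start_slot=start,
        end_slot=end,
        event=event,
    )


def select_control_segment(
    weekly: Iterable[WeeklyScale],
    grid: BeepGrid,
    target_length: int = DEFAULT_CONTROL_LENGTH,
    stability_threshold: float = DEFAULT_STABILITY_THRESHOLD,
) -> Optional[AnalysisSegment]:
    """Earliest stable stretch of a non-transitioning patient.

    Scans the patient's weeks for the earliest contiguous run in which
    every week-to-week |change| on *both* instruments stays below
    ``stability_threshold`` and which covers at least ``target_length``
    scheduled beeps.  Returns ``None`` when no such run exists — a valid
    outcome (not every stable-looking patient has one).
    """
    scales = list(weekly)
    pids = {s.patient_id for s in scales}
    if len(pids) != 1:
        raise ValueError("select_control_segment expects one patient's scales")
    (pid,) = pids
    n_weeks = min(s.n_weeks for s in scales)
    beeps_per_week = DAYS_PER_WEEK * grid.beeps_per_day
    weeks_needed = math.ceil(target_length / beeps_per_week)

    def stable_diff(w: int) -> bool:
        """True when the change from week w-1 to w is stable on both scales."""
        for s in scales:
            a, b = s.scores[w - 1], s.scores[w]
            if np.isnan(a) or np.isnan(b) or abs(b - a) >= stability_threshold:
                return False
        return True

    run_start = 0
    for w in range(1, n_weeks + 1):
        if w == n_weeks or not stable_diff(w):
            run_weeks = w - run_start
            if run_weeks >= weeks_needed:
                start = grid.week_start_slot(run_start)
                return AnalysisSegment(
                    patient_id=pid,
                    kind="control",
                    start_slot=start,
                    end_slot=start + target_length,
                )
            run_start = w
    return None


def build_segments(
    weekly: Iterable[WeeklyScale],
    grid: BeepGrid,
    jump_threshold: float = DEFAULT_JUMP_THRESHOLD,
    control_length: int = DEFAULT_CONTROL_LENGTH,
    stability_threshold: float = DEFAULT_STABILITY_THRESHOLD,
    min_segment_length: int = 70,
) -> tuple[list[TransitionEvent], list[AnalysisSegment]]:
    """Full segment inventory: pre-transition + control segments.

    Each transition yields one pre-transition segment (skipped with a
    warning when shorter than one window).  Each patient without any
    detected transition contributes at most one control segment.
    """
    scales = list(weekly)
    events = detect_transitions(scales, grid, jump_threshold)
    by_patient: dict[str, list[TransitionEvent]] = {}
    for ev in events:
        by_patient.setdefault(ev.patient_id, []).append(ev)
    segments: list[AnalysisSegment] = []
    for pid in sorted(by_patient):
        prev = None
        for ev in by_patient[pid]:
            try:
                segments.append(
                    extract_pre_transition_segment(
                        ev, grid, prev, min_length=min_segment_length
                    )
                )
            except ValueError as exc:
                warnings.warn(str(exc), stacklevel=2)
            prev = ev
    transitioning = set(by_patient)
    patients = sorted({s.patient_id for s in scales})
    for pid in patients:
        if pid in transitioning:
            continue
        seg = select_control_segment(
            [s for s in scales if s.patient_id == pid],
            grid,
            target_length=control_length,
            stability_threshold=stability_threshold,
        )
        if seg is not None:
            segments.append(seg)
    return events, segments
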