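"""Group-level evaluation: sensitivity, specificity, PPV and NPV.

Transition segments of each type (manic/depressive) provide true
positives/false negatives; control segments from non-transitioning
patients provide false positives/true negatives.  Predictive values
follow the prevalence-based identities

    PPV = sens * prev / (sens * prev + (1 - spec) * (1 - prev))
    NPV = spec * (1 - prev) / ((1 - sens) * prev + spec * (1 - prev))

with prevalence the proportion of segments carrying a transition of that
type.  A useful early warning signal should beat the prevalence.
Degenerate cells (e.g. an indicator that never fires) are rendered
distinctly from a true 0% value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .inference import EwsTestResult
from .transitions import AnalysisSegment

__all__ = [
    "ConfusionCounts",
    "prevalence",
    "confusion",
    "predictive_values",
    "degenerate_label",
    "evaluation_table",
    "summarize",
]

TRANSITION_KINDS = ("manic", "depressive")

#: Label used for the averaged "alarm in at least one state" rows.
ANY_STATE = "__any_state__"


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts for one (state, indicator, transition type) cell.

    TP/FN run over transition segments of the type; FP/TN over control
    segments (shared across types, so specificity has no type subscript).
    """

    state: str
    indicator: str
    kind: str
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.fp + self.tn
        return self.tn / neg if neg else float("nan")


def prevalence(segments: Iterable[AnalysisSegment]) -> dict[str, float]:
    """Per-type transition prevalence over the full segment inventory."""
    segments = list(segments)
    total = len(segments)
    if total == 0:
        raise ValueError("empty segment inventory")
    out = {}
    for kind in TRANSITION_KINDS:
        n_kind = sum(1 for s in segments if s.transition_kind == kind)
        out[kind] = n_kind / total
    return out


def _alarm_lookup(
    results: Iterable[EwsTestResult],
) -> dict[tuple[str, str, str], bool]:
    """(segment_id, state, indicator) -> alarm flag.

    Skipped/invalid tests count as negative (no alarm); they remain in
    the lookup so the inventory check can distinguish "tested, negative"
    from "missing".
    """
    lookup: dict[tuple[str, str, str], bool] = {}
    for r in results:
        lookup[(r.segment_id, r.state, r.indicator)] = bool(
            r.valid and r.significant
        )
    return lookup


def confusion(
    results: Iterable[EwsTestResult],
    segments: Iterable[AnalysisSegment],
    states: Iterable[str],
    indicators: Iterable[str] = ("ar1", "sd"),
) -> list[ConfusionCounts]:
    """Confusion counts per (state, indicator, transition type).

    Raises when the result set does not cover every segment x state x
    indicator cell of the inventory.
    """
    segments = list(segments)
    states = list(states)
    indicators = list(indicators)
    lookup = _alarm_lookup(results)
    missing = [
        (seg.segment_id, st, ind)
        for seg in segments
        for st in states
        for ind in indicators
        if (seg.segment_id, st, ind) not in lookup
    ]
    if missing:
        raise ValueError(
            f"results missing for {len(missing)} inventory cells, e.g. "
            f"{missing[:3]}"
        )
    controls = [s for s in segments if s.kind == "control"]
    out = []
    for st in states:
        for ind in indicators:
            fp = sum(lookup[(s.segment_id, st, ind)] for s in controls)
            tn = len(controls) - fp
            for kind in TRANSITION_KINDS:
                of_kind = [s for s in segments if s.transition_kind == kind]
                tp = sum(lookup[(s.segment_id, st, ind)] for s in of_kind)
                out.append(
                    ConfusionCounts(
                        state=st,
                        indicator=ind,
                        kind=kind,
                        tp=tp,
                        fn=len(of_kind) - tp,
                        fp=fp,
                        tn=tn,
                    )
                )
    return out


def degenerate_label(sensitivity: float, specificity: float) -> str:
    """Classify the degenerate alarm patterns behind undefined/0% cells.

    * ``no_alarms`` — alarms never fire anywhere: PPV is 0/0, which is
      "no alarms", not 0%.
    * ``alarms_only_in_controls`` — alarms fire in controls but never
      before transitions: PPV is genuinely 0%.
    * ``alarms_everywhere`` — alarms fire for every segment: NPV is 0/0.
    * ``misses_only_in_transitions`` — no alarm before any transition but
      some in controls is covered above; the symmetric NPV-0 case (alarms
      for all controls, some transitions missed) is labelled here.
    """
    if np.isnan(sensitivity) or np.isnan(specificity):
        return "undefined_inputs"
    if sensitivity == 0.0 and specificity == 1.0:
        return "no_alarms"
    if sensitivity == 0.0:
        return "alarms_only_in_controls"
    if sensitivity == 1.0 and specificity == 0.0:
        return "alarms_everywhere"
    if specificity == 0.0:
        return "misses_only_in_transitions"
    return "none"


def predictive_values(
    sensitivity: float, specificity: float, prev: float
) -> tuple[float, float]:
    """PPV and NPV from sensitivity, specificity and prevalence.

    Zero denominators yield NaN; use :func:`degenerate_label` to tell a
    silent indicator (PPV undefined) from a genuinely 0% one.
    """
    for name, v in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
    ):
        if not (math.isnan(v) or 0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    if not 0.0 < prev < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    ppv_den = sensitivity * prev + (1.0 - specificity) * (1.0 - prev)
    npv_den = (1.0 - sensitivity) * prev + specificity * (1.0 - prev)
    ppv = sensitivity * prev / ppv_den if ppv_den > 0 else float("nan")
    npv = specificity * (1.0 - prev) / npv_den if npv_den > 0 else float("nan")
    return ppv, npv


def _any_state_counts(
    results: list[EwsTestResult],
    segments: list[AnalysisSegment],
    states: list[str],
    indicator: str,
    kind: str,
) -> ConfusionCounts:
    """Averaged row: a segment is alarm-positive when ANY state fires."""
    lookup = _alarm_lookup(results)

    def any_alarm(seg: AnalysisSegment) -> bool:
        return any(lookup[(seg.segment_id, st, indicator)] for st in states)

    controls = [s for s in segments if s.kind == "control"]
    of_kind = [s for s in segments if s.transition_kind == kind]
    tp = sum(any_alarm(s) for s in of_kind)
    fp = sum(any_alarm(s) for s in controls)
    return ConfusionCounts(
        state=ANY_STATE,
        indicator=indicator,
        kind=kind,
        tp=tp,
        fn=len(of_kind) - tp,
        fp=fp,
        tn=len(controls) - fp,
    )


def evaluation_table(
    results: Iterable[EwsTestResult],
    segments: Iterable[AnalysisSegment],
    states: Iterable[str],
    indicators: Iterable[str] = ("ar1", "sd"),
) -> pd.DataFrame:
    """Per-state and averaged sensitivity/specificity/PPV/NPV table.

    One row per (state, indicator, transition type), plus averaged rows
    (state = ``__any_state__``) in which a segment counts as
    alarm-positive when at least one state shows the indicator's EWS.
    Each row is annotated with whether the PPV beats the type's
    prevalence and with its degenerate-pattern label.
    """
    results = list(results)
    segments = list(segments)
    states = list(states)
    indicators = list(indicators)
    prev = prevalence(segments)
    counts = confusion(results, segments, states, indicators)
    for ind in indicators:
        for kind in TRANSITION_KINDS:
            counts.append(
                _any_state_counts(results, segments, states, ind, kind)
            )
    rows = []
    for c in counts:
        p = prev[c.kind]
        sens, spec = c.sensitivity, c.specificity
        if 0.0 < p < 1.0 and not (math.isnan(sens) or math.isnan(spec)):
            ppv, npv = predictive_values(sens, spec, p)
        else:
            ppv = npv = float("nan")
        rows.append(
            {
                "state": c.state,
                "indicator": c.indicator,
                "transition_kind": c.kind,
                "tp": c.tp,
                "fn": c.fn,
                "fp": c.fp,
                "tn": c.tn,
                "sensitivity": sens,
                "specificity": spec,
                "prevalence": p,
                "ppv": ppv,
                "npv": npv,
                "beats_prevalence": bool(ppv > p) if not math.isnan(ppv) else False,
                "degenerate": degenerate_label(sens, spec),
            }
        )
    return pd.DataFrame(rows)


def _overlap(
    results: list[EwsTestResult],
    segments: list[AnalysisSegment],
    kind: str,
) -> float:
    """Jaccard overlap (%) of ar1 vs sd alarms over one type's segments."""
    lookup = _alarm_lookup(results)
    seg_ids = {s.segment_id for s in segments if s.transition_kind == kind}
    ar = {
        (sid, st)
        for (sid, st, ind), flag in lookup.items()
        if flag and ind == "ar1" and sid in seg_ids
    }
    sd = {
        (sid, st)
        for (sid, st, ind), flag in lookup.items()
        if flag and ind == "sd" and sid in seg_ids
    }
    union = ar | sd
    if not union:
        return float("nan")
    return 100.0 * len(ar & sd) / len(union)


def summarize(
    results: Iterable[EwsTestResult],
    segments: Iterable[AnalysisSegment],
    states: Iterable[str],
    indicators: Iterable[str] = ("ar1", "sd"),
) -> dict:
    """Report bundle: evaluation table, prevalences, EWS counts, overlap.

    ``mean_ews_per_segment`` gives, per indicator and segment class, the
    mean number of momentary states with a significant EWS — the audit
    statistic describing how densely warnings occur.  ``ar_sd_overlap``
    is the percentage overlap between the two indicators' alarm sets per
    transition type.
    """
    results = list(results)
    segments = list(segments)
    states = list(states)
    table = evaluation_table(results, segments, states, indicators)
    lookup = _alarm_lookup(results)
    mean_ews: dict[str, dict[str, float]] = {}
    classes = {
        "manic": [s for s in segments if s.transition_kind == "manic"],
        "depressive": [
            s for s in segments if s.transition_kind == "depressive"
        ],
        "control": [s for s in segments if s.kind == "control"],
    }
    for ind in indicators:
        mean_ews[ind] = {}
        for cls, segs in classes.items():
            if not segs:
                mean_ews[ind][cls] = float("nan")
                continue
            counts = [
                sum(lookup[(s.segment_id, st, ind)] for st in states)
                for s in segs
            ]
            mean_ews[ind][cls] = float(np.mean(counts))
    return {
        "table": table,
        "prevalence": prevalence(segments),
        "mean_ews_per_segment": mean_ews,
        "ar_sd_overlap_pct": {
            kind: _overlap(results, segments, kind)
            for kind in TRANSITION_KINDS
        },
        "n_segments": len(segments),
    }
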