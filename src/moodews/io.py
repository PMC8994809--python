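"""CSV/JSON readers and writers for all pipeline artifacts.

Conventions: all indices are 0-based, all ranges half-open, calendar
fields (day, slot-in-day, weekday) are stored explicitly.  Missing EMA
values are written as empty cells on their scheduled rows, never dropped.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .ews import IndicatorSeries
from .grid import BeepGrid
from .inference import EwsTestResult
from .series import INSTRUMENT_RANGES, EmaSeries, WeeklyScale
from .synthetic import GroundTruth
from .transitions import AnalysisSegment, TransitionEvent

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"

EXPECTED_N_STATES = 17


class SchemaError(ValueError):
    """Input table violates the documented schema."""


def write_ema_csv(series: Iterable[EmaSeries], path: str | Path) -> None:
    frames = []
    for s in series:
        g = s.grid
        slots = np.arange(g.n_slots)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": s.patient_id,
                    "day": slots // g.beeps_per_day,
                    "slot": slots % g.beeps_per_day,
                    "weekday": [(g.start_weekday + d) % 7 for d in slots // g.beeps_per_day],
                    "state": s.state,
                    "value": s.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_ema_csv(
    path: str | Path, expected_states: int = EXPECTED_N_STATES
) -> tuple[list[EmaSeries], BeepGrid]:
    """Read and validate an EMA table; absent rows become missing beeps."""
    df = pd.read_csv(path)
    required = {"patient_id", "day", "slot", "state", "value"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"EMA table must have columns {sorted(required)}; "
            f"got {sorted(df.columns)}"
        )
    dup = df.duplicated(["patient_id", "day", "slot", "state"])
    if dup.any():
        row = df[dup].iloc[0]
        raise SchemaError(
            f"duplicate (patient, beep, state) row: patient "
            f"{row.patient_id}, day {row.day}, slot {row.slot}, "
            f"state {row.state}"
        )
    bad = df["value"].notna() & ((df["value"] < 0) | (df["value"] > 100))
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        row = df.iloc[i]
        raise SchemaError(
            f"value {row.value} out of range [0, 100] at row {i} "
            f"(patient {row.patient_id}, day {row.day}, slot {row.slot}, "
            f"state {row.state})"
        )
    days = int(df["day"].max()) + 1
    bpd = int(df["slot"].max()) + 1
    start_weekday = 0
    if "weekday" in df.columns:
        day0 = df[df["day"] == 0]
        if len(day0):
            start_weekday = int(day0["weekday"].iloc[0])
    grid = BeepGrid(days, bpd, start_weekday)
    states = sorted(df["state"].unique())
    if len(states) != expected_states:
        warnings.warn(
            f"expected {expected_states} momentary states, found "
            f"{len(states)}; proceeding with the provided states",
            stacklevel=2,
        )
    out = []
    for (pid, state), sub in df.groupby(["patient_id", "state"], sort=True):
        values = np.full(grid.n_slots, np.nan)
        idx = sub["day"].to_numpy() * bpd + sub["slot"].to_numpy()
        values[idx] = sub["value"].to_numpy()
        out.append(EmaSeries(str(pid), str(state), values, grid))
    return out, grid


def write_weekly_csv(scales: Iterable[WeeklyScale], path: str | Path) -> None:
    rows = []
    for s in scales:
        for week, score in enumerate(s.scores):
            rows.append(
                {
                    "patient_id": s.patient_id,
                    "week": week,
                    "instrument": s.instrument,
                    "score": score,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_weekly_csv(path: str | Path) -> list[WeeklyScale]:
    df = pd.read_csv(path)
    required = {"patient_id", "week", "instrument", "score"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"weekly table must have columns {sorted(required)}"
        )
    unknown = set(df["instrument"].unique()) - set(INSTRUMENT_RANGES)
    if unknown:
        raise SchemaError(f"unknown instruments: {sorted(unknown)}")
    out = []
    for (pid, inst), sub in df.groupby(["patient_id", "instrument"], sort=True):
        weeks = sub["week"].to_numpy()
        if len(np.unique(weeks)) != len(weeks):
            raise SchemaError(
                f"duplicate weeks for patient {pid} on {inst}"
            )
        n_weeks = int(weeks.max()) + 1
        scores = np.full(n_weeks, np.nan)
        scores[weeks] = sub["score"].to_numpy()
        lo, hi = INSTRUMENT_RANGES[inst]
        obs = scores[~np.isnan(scores)]
        if obs.size and (obs.min() < lo or obs.max() > hi):
            raise SchemaError(
                f"{inst} score out of range [{lo}, {hi}] for patient {pid}"
            )
        out.append(WeeklyScale(str(pid), str(inst), scores))
    return out


def write_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "transitions": {
            pid: [asdict(ev) for ev in evs]
            for pid, evs in sorted(truth.transitions.items())
        },
        "ews": sorted(list(t) for t in truth.ews),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_truth_json(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    transitions = {
        pid: [TransitionEvent(**ev) for ev in evs]
        for pid, evs in payload["transitions"].items()
    }
    ews = {tuple(t) for t in payload["ews"]}
    return GroundTruth(transitions=transitions, ews=ews)


def write_segments_csv(
    segments: Iterable[AnalysisSegment], path: str | Path
) -> None:
    rows = []
    for s in segments:
        rows.append(
            {
                "segment_id": s.segment_id,
                "patient_id": s.patient_id,
                "kind": s.kind,
                "start_slot": s.start_slot,
                "end_slot": s.end_slot,
                "transition_kind": s.transition_kind or "",
                "transition_week": s.event.week if s.event else "",
                "jump": s.event.jump if s.event else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_segments_csv(path: str | Path) -> list[AnalysisSegment]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        event = None
        if row["kind"] == "pre_transition":
            event = TransitionEvent(
                patient_id=str(row["patient_id"]),
                kind=str(row["transition_kind"]),
                week=int(row["transition_week"]),
                jump=float(row["jump"]),
                aligned_slot=int(row["end_slot"]),
            )
        out.append(
            AnalysisSegment(
                patient_id=str(row["patient_id"]),
                kind=str(row["kind"]),
                start_slot=int(row["start_slot"]),
                end_slot=int(row["end_slot"]),
                event=event,
            )
        )
    return out


def write_indicators_csv(
    series: Iterable[IndicatorSeries], path: str | Path
) -> None:
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": s.patient_id,
                    "segment_id": s.segment_id,
                    "state": s.state,
                    "indicator": s.indicator,
                    "window_end_slot": s.end_slots,
                    "estimate": s.estimates,
                    "n_obs": s.n_obs,
                    "n_pairs": s.n_pairs,
                    "valid": s.valid_mask,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def write_results_csv(
    results: Iterable[EwsTestResult], path: str | Path
) -> None:
    pd.DataFrame([asdict(r) for r in results]).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_results_csv(path: str | Path) -> list[EwsTestResult]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    out = []
    for _, row in df.iterrows():
        d = row.to_dict()
        d["transition_kind"] = d["transition_kind"] or None
        if isinstance(d["transition_kind"], float) and np.isnan(
            d["transition_kind"]
        ):
            d["transition_kind"] = None
        for key in ("patient_id", "state", "indicator", "segment_id",
                    "segment_kind", "reason"):
            d[key] = "" if pd.isna(d[key]) else str(d[key])
        d["n_points"] = int(d["n_points"])
        for key in ("valid", "significant", "significant_uncorrected"):
            d[key] = str(d[key]) == "True"
        out.append(EwsTestResult(**d))
    return out
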