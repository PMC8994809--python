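"""Reusable simulation experiments for calibration and validation.

These functions drive the full pipeline on synthetic cohorts with known
ground truth and measure its operating characteristics: false-positive
control of the corrected trend test, detection power for planted
critical-slowing-down ramps, end-to-end predictive value, and exactness
of the transition-rule round trip.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .evaluation import ANY_STATE, summarize
from .pipeline import PipelineConfig, analyze_segments
from .synthetic import (
    EwsSpec,
    SimConfig,
    TransitionSpec,
    simulate_cohort,
    simulate_ema,
    simulate_weekly,
)
from .transitions import AnalysisSegment, build_segments, detect_transitions

__all__ = [
    "type_one_error_experiment",
    "power_experiment",
    "paper_like_cohort_config",
    "cohort_ppv_experiment",
    "transition_roundtrip_experiment",
]

_SEED_MAX = 2**31 - 1


def _rep_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, _SEED_MAX, size=n)


def type_one_error_experiment(
    n_reps: int = 500,
    seed: int = 0,
    n_states: int = 17,
    q: float = 0.05,
    config: PipelineConfig | None = None,
) -> dict:
    """False-positive rate of the pipeline on stationary patients.

    Each replicate is one patient with no planted structure: stationary
    AR(1) momentary states and a stable weekly course, contributing one
    245-slot control segment.  The family of 17 states x 2 indicators is
    tested with the Hamed-Rao-corrected Mann-Kendall test and
    within-patient BH-FDR at ``q``; the same family is also flagged with
    the *uncorrected* test for comparison.  Returns the fraction of
    replicate families with at least one flag under each test, plus
    per-test flag rates.
    """
    if config is None:
        config = PipelineConfig(q=q)
    seeds = _rep_seeds(seed, n_reps)
    fam_corr = fam_raw = 0
    test_corr = test_raw = n_tests = 0
    for rep_seed in seeds:
        sim = SimConfig(
            n_patients=1,
            days=49,
            n_states=n_states,
            seed=int(rep_seed),
        )
        ema, _ = simulate_ema(sim)
        segment = AnalysisSegment(
            patient_id=sim.patient_ids[0],
            kind="control",
            start_slot=0,
            end_slot=245,
        )
        results = analyze_segments(ema, [segment], sim.grid, config)
        valid = [r for r in results if r.valid]
        fam_corr += any(r.significant for r in valid)
        fam_raw += any(r.significant_uncorrected for r in valid)
        test_corr += sum(r.significant for r in valid)
        test_raw += sum(r.significant_uncorrected for r in valid)
        n_tests += len(valid)
    return {
        "n_reps": n_reps,
        "family_rate_corrected": fam_corr / n_reps,
        "family_rate_uncorrected": fam_raw / n_reps,
        "test_rate_corrected": test_corr / max(n_tests, 1),
        "test_rate_uncorrected": test_raw / max(n_tests, 1),
    }


def power_experiment(
    n_reps: int = 100,
    seed: int = 0,
    ar_ramp: tuple[float, float] = (0.2, 0.7),
    ramp_days: int = 14,
    transition_week: int = 7,  # 245-slot pre-transition period, the
    # mean pre-transition length of transitioning patients
    planted_state: str = "full_of_ideas",
    config: PipelineConfig | None = None,
) -> dict:
    """Detection rate for a planted pre-transition autocorrelation ramp.

    Each replicate is one patient with a manic transition and a linear
    AR-coefficient ramp (default 0.2 -> 0.7 over the final fortnight) in
    a single momentary state.  Detection means the planted (state, ar1)
    test survives within-patient FDR with positive tau; false flags are
    counted over the other (state, indicator) tests of the family.
    """
    if config is None:
        config = PipelineConfig()
    seeds = _rep_seeds(seed, n_reps)
    detected = 0
    false_flags = 0
    n_null = 0
    for rep_seed in seeds:
        sim = SimConfig(
            n_patients=1,
            days=119,
            seed=int(rep_seed),
            baseline_ar=ar_ramp[0],
            transition_specs=[
                TransitionSpec("P00", "manic", transition_week, 7)
            ],
            ews_specs=[
                EwsSpec(
                    "P00",
                    planted_state,
                    "ar",
                    ar_ramp=ar_ramp,
                    ramp_days=ramp_days,
                )
            ],
        )
        ema, weekly, truth = simulate_cohort(sim)
        _, segments = build_segments(
            weekly, sim.grid, min_segment_length=config.window.length
        )
        results = analyze_segments(ema, segments, sim.grid, config)
        for r in results:
            if not r.valid:
                continue
            planted = r.state == planted_state and r.indicator == "ar1"
            # the planted AR ramp also raises the marginal variance, so
            # the same state's sd test is not a clean null either
            same_state = r.state == planted_state
            if planted:
                detected += r.significant
            elif not same_state:
                false_flags += r.significant
                n_null += 1
    return {
        "n_reps": n_reps,
        "detection_rate": detected / n_reps,
        "false_flag_rate": false_flags / max(n_null, 1),
    }


def paper_like_cohort_config(
    seed: int,
    ar_ramp: tuple[float, float] = (0.2, 0.7),
    states_per_transition: int = 3,
    ramp_days: int = 14,
) -> SimConfig:
    """A 20-patient cohort mirroring the study's segment accounting.

    Eleven patients transition (four of them twice: 7 manic + 8
    depressive transitions in total) and nine do not, two of whom lack a
    stable control stretch — yielding 15 pre-transition + 7 control = 22
    segments, hence transition prevalences of 7/22 and 8/22.  Every
    transition is preceded by planted AR ramps in
    ``states_per_transition`` randomly drawn momentary states.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    transitions: list[TransitionSpec] = []
    double = [("manic", "depressive"), ("depressive", "manic")]
    for i in range(4):  # P00..P03: two transitions each
        k1, k2 = double[i % 2]
        transitions.append(TransitionSpec(f"P{i:02d}", k1, 5, 7))
        transitions.append(TransitionSpec(f"P{i:02d}", k2, 11, 8))
    singles = ["manic"] * 3 + ["depressive"] * 4  # P04..P10
    for i, kind in enumerate(singles, start=4):
        transitions.append(TransitionSpec(f"P{i:02d}", kind, 8, 7))
    cfg = SimConfig(
        n_patients=20,
        days=119,
        seed=seed,
        baseline_ar=ar_ramp[0],
        transition_specs=transitions,
        unstable_patient_ids=("P18", "P19"),
    )
    ews_specs: list[EwsSpec] = []
    for t in transitions:
        states = rng.choice(
            cfg.state_names, size=states_per_transition, replace=False
        )
        for st in sorted(states):
            ews_specs.append(
                EwsSpec(
                    t.patient_id,
                    str(st),
                    "ar",
                    ar_ramp=ar_ramp,
                    ramp_days=ramp_days,
                    transition_week=t.week,
                )
            )
    return dataclasses.replace(cfg, ews_specs=ews_specs)


def cohort_ppv_experiment(
    n_cohorts: int = 20,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> dict:
    """End-to-end predictive value of the planted indicator.

    Runs the full pipeline on replicate paper-like cohorts and asks, per
    cohort, whether the averaged ("alarm in any state") PPV of the
    planted ar1 indicator exceeds the transition prevalence for both
    transition types.  Also reports the mean averaged PPV by type.
    """
    if config is None:
        config = PipelineConfig()
    seeds = _rep_seeds(seed, n_cohorts)
    beats = 0
    ppvs = {"manic": [], "depressive": []}
    prevs = {"manic": [], "depressive": []}
    for rep_seed in seeds:
        sim = paper_like_cohort_config(int(rep_seed))
        ema, weekly, truth = simulate_cohort(sim)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, segments = build_segments(
                weekly, sim.grid, min_segment_length=config.window.length
            )
            results = analyze_segments(ema, segments, sim.grid, config)
            bundle = summarize(results, segments, sim.state_names)
        table = bundle["table"]
        avg = table[(table.state == ANY_STATE) & (table.indicator == "ar1")]
        ok = True
        for kind in ("manic", "depressive"):
            row = avg[avg.transition_kind == kind].iloc[0]
            ppvs[kind].append(float(row.ppv))
            prevs[kind].append(float(row.prevalence))
            if not (row.ppv > row.prevalence):
                ok = False
        beats += ok
    return {
        "n_cohorts": n_cohorts,
        "fraction_beating_prevalence": beats / n_cohorts,
        "mean_ppv": {k: float(np.nanmean(v)) for k, v in ppvs.items()},
        "mean_prevalence": {k: float(np.mean(v)) for k, v in prevs.items()},
    }


def transition_roundtrip_experiment(
    n_configs: int = 200, seed: int = 0
) -> dict:
    """Exactness of transition detection on generated weekly series.

    Draws random cohort configurations (patients, transition weeks,
    types, magnitudes), generates weekly scales and checks that the
    detector recovers every programmed transition's type and week with no
    false events.
    """
    rng = np.random.default_rng(seed)
    n_exact = 0
    n_false = 0
    n_missed = 0
    for _ in range(n_configs):
        n_patients = int(rng.integers(2, 6))
        cfg_seed = int(rng.integers(0, _SEED_MAX))
        transitions: list[TransitionSpec] = []
        for p in range(n_patients):
            pid = f"P{p:02d}"
            n_trans = int(rng.integers(0, 3))
            if n_trans == 1:
                weeks = [int(rng.integers(3, 16))]
            elif n_trans == 2:
                w1 = int(rng.integers(3, 10))
                weeks = [w1, w1 + 5 + int(rng.integers(0, 16 - w1 - 5 + 1))]
            else:
                weeks = []
            for w in weeks:
                kind = "manic" if rng.random() < 0.5 else "depressive"
                mag = int(rng.integers(6, 13))
                transitions.append(TransitionSpec(pid, kind, w, mag))
        sim = SimConfig(
            n_patients=n_patients,
            days=119,
            seed=cfg_seed,
            transition_specs=transitions,
        )
        weekly = simulate_weekly(sim)
        events = detect_transitions(weekly, sim.grid)
        planted = {
            (t.patient_id, t.kind, t.week) for t in sim.transition_specs
        }
        found = {(e.patient_id, e.kind, e.week) for e in events}
        n_false += len(found - planted)
        n_missed += len(planted - found)
        n_exact += found == planted
    return {
        "n_configs": n_configs,
        "exact_recovery_rate": n_exact / n_configs,
        "false_events": n_false,
        "missed_events": n_missed,
    }
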