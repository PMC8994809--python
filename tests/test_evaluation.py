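"""Prevalence, confusion bookkeeping and predictive values."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import moodews as m
from moodews.evaluation import (
    ANY_STATE,
    confusion,
    degenerate_label,
    evaluation_table,
    predictive_values,
    prevalence,
    summarize,
)
from moodews.inference import EwsTestResult
from moodews.transitions import AnalysisSegment, TransitionEvent


def seg_inventory(n_manic=7, n_dep=8, n_control=7):
    """Segment inventory shaped like the study's accounting (22 total)."""
    segments = []
    slot = 0
    for i in range(n_manic):
        ev = TransitionEvent(f"M{i}", "manic", 7, 7.0, 245)
        segments.append(AnalysisSegment(f"M{i}", "pre_transition", 0, 245, ev))
    for i in range(n_dep):
        ev = TransitionEvent(f"D{i}", "depressive", 7, 8.0, 245)
        segments.append(AnalysisSegment(f"D{i}", "pre_transition", 0, 245, ev))
    for i in range(n_control):
        segments.append(AnalysisSegment(f"C{i}", "control", 0, 245))
    return segments


def result_for(seg, state, indicator, significant):
    r = EwsTestResult(
        patient_id=seg.patient_id,
        state=state,
        indicator=indicator,
        segment_id=seg.segment_id,
        segment_kind=seg.kind,
        transition_kind=seg.transition_kind,
    )
    r.valid = True
    r.tau = 0.5 if significant else 0.1
    r.significant = significant
    return r


def results_from_flags(segments, states, flag_fn):
    out = []
    for seg in segments:
        for st_ in states:
            for ind in ("ar1", "sd"):
                out.append(
                    result_for(seg, st_, ind, flag_fn(seg, st_, ind))
                )
    return out


class TestPrevalence:
    def test_paper_accounting_prints_32_and_36(self):
        prev = prevalence(seg_inventory())
        assert round(100 * prev["manic"]) == 32
        assert round(100 * prev["depressive"]) == 36
        assert prev["manic"] == pytest.approx(7 / 22)
        assert prev["depressive"] == pytest.approx(8 / 22)

    def test_no_transitions_zero_prevalence(self):
        prev = prevalence(seg_inventory(0, 0, 5))
        assert prev == {"manic": 0.0, "depressive": 0.0}

    def test_empty_inventory_errors(self):
        with pytest.raises(ValueError, match="empty"):
            prevalence([])


class TestConfusion:
    def test_counts_match_ground_truth_bookkeeping(self):
        segments = seg_inventory(2, 1, 3)
        states = ["a", "b"]

        def flags(seg, st_, ind):
            # alarm exactly for state 'a'/ar1 on manic segments and on
            # the first control segment
            if (st_, ind) != ("a", "ar1"):
                return False
            return seg.transition_kind == "manic" or seg.patient_id == "C0"

        results = results_from_flags(segments, states, flags)
        counts = {
            (c.state, c.indicator, c.kind): c
            for c in confusion(results, segments, states)
        }
        c = counts[("a", "ar1", "manic")]
        assert (c.tp, c.fn, c.fp, c.tn) == (2, 0, 1, 2)
        c = counts[("a", "ar1", "depressive")]
        assert (c.tp, c.fn, c.fp, c.tn) == (0, 1, 1, 2)
        c = counts[("b", "sd", "manic")]
        assert (c.tp, c.fn, c.fp, c.tn) == (0, 2, 0, 3)

    def test_missing_cells_rejected(self):
        segments = seg_inventory(1, 1, 1)
        results = results_from_flags(
            segments[:2], ["a"], lambda *_: False
        )
        with pytest.raises(ValueError, match="missing"):
            confusion(results, segments, ["a"])

    def test_invalid_results_count_as_negative(self):
        segments = seg_inventory(1, 0, 1)
        results = results_from_flags(segments, ["a"], lambda *_: True)
        for r in results:
            if r.segment_kind == "control":
                r.valid = False
                r.significant = False
        counts = {
            (c.state, c.indicator, c.kind): c
            for c in confusion(results, segments, ["a"])
        }
        c = counts[("a", "ar1", "manic")]
        assert (c.tp, c.fp, c.tn) == (1, 0, 1)


class TestPredictiveValues:
    def test_perfect_test(self):
        assert predictive_values(1.0, 1.0, 0.32) == (1.0, 1.0)

    def test_zero_sensitivity(self):
        ppv, npv = predictive_values(0.0, 0.8, 0.36)
        assert ppv == 0.0
        assert npv == pytest.approx(0.8 * 0.64 / (0.36 + 0.8 * 0.64))

    def test_hand_substitution(self):
        ppv, npv = predictive_values(0.5, 0.8, 0.36)
        assert ppv == pytest.approx(0.18 / (0.18 + 0.2 * 0.64))
        assert npv == pytest.approx(
            0.8 * 0.64 / (0.5 * 0.36 + 0.8 * 0.64)
        )

    def test_count_form_equivalence(self, rng):
        # when the segment classes embody the prevalence, the formula
        # reduces exactly to PPV = TP/(TP+FP) and NPV = TN/(TN+FN)
        for _ in range(100):
            pos = int(rng.integers(2, 30))
            neg = int(rng.integers(2, 30))
            tp = int(rng.integers(1, pos))
            tn = int(rng.integers(1, neg))
            fp = neg - tn
            fn = pos - tp
            sens, spec = tp / pos, tn / neg
            prev = pos / (pos + neg)
            ppv, npv = predictive_values(sens, spec, prev)
            if tp + fp:
                assert ppv == pytest.approx(tp / (tp + fp))
            if tn + fn:
                assert npv == pytest.approx(tn / (tn + fn))

    def test_degenerate_patterns_distinguished(self):
        assert degenerate_label(0.0, 1.0) == "no_alarms"
        assert degenerate_label(0.0, 0.7) == "alarms_only_in_controls"
        assert degenerate_label(1.0, 0.0) == "alarms_everywhere"
        assert degenerate_label(0.4, 0.0) == "misses_only_in_transitions"
        assert degenerate_label(0.5, 0.5) == "none"
        ppv, _ = predictive_values(0.0, 1.0, 0.3)
        assert math.isnan(ppv)  # silent indicator: undefined, not 0%

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="prevalence"):
            predictive_values(0.5, 0.5, 0.0)
        with pytest.raises(ValueError, match="sensitivity"):
            predictive_values(1.5, 0.5, 0.3)

    @given(
        st.floats(min_value=0.01, max_value=0.99),
        st.floats(min_value=0.01, max_value=0.99),
        st.floats(min_value=0.01, max_value=0.99),
        st.floats(min_value=0.001, max_value=0.3),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_ppv_monotone_in_specificity_and_prevalence(
        self, sens, spec, prev, delta
    ):
        ppv, _ = predictive_values(sens, spec, prev)
        ppv_spec, _ = predictive_values(
            sens, min(spec + delta, 1.0), prev
        )
        ppv_prev, _ = predictive_values(
            sens, spec, min(prev + delta, 0.99)
        )
        assert ppv_spec >= ppv - 1e-12
        assert ppv_prev >= ppv - 1e-12


class TestSummarize:
    def test_perfect_detector_gives_unit_ppv(self):
        segments = seg_inventory(2, 2, 3)
        states = ["a", "b"]
        results = results_from_flags(
            segments, states,
            lambda seg, st_, ind: seg.kind == "pre_transition",
        )
        bundle = summarize(results, segments, states)
        t = bundle["table"]
        planted = t[(t.state == "a") & (t.indicator == "ar1")]
        assert (planted.ppv == 1.0).all()
        assert (planted.sensitivity == 1.0).all()

    def test_identical_indicator_flag_sets_full_overlap(self):
        segments = seg_inventory(2, 1, 2)
        states = ["a", "b"]
        results = results_from_flags(
            segments, states,
            lambda seg, st_, ind: seg.kind == "pre_transition"
            and st_ == "a",
        )
        bundle = summarize(results, segments, states)
        assert bundle["ar_sd_overlap_pct"]["manic"] == pytest.approx(100.0)
        assert bundle["mean_ews_per_segment"]["ar1"]["manic"] == 1.0

    def test_random_flags_ppv_near_prevalence(self, rng):
        # independent 5% alarms cannot beat the prevalence on average
        segments = seg_inventory(70, 70, 260)
        states = ["a"]
        results = results_from_flags(
            segments, states, lambda *_: rng.random() < 0.05
        )
        bundle = summarize(results, segments, states)
        t = bundle["table"]
        row = t[
            (t.state == "a")
            & (t.indicator == "ar1")
            & (t.transition_kind == "manic")
        ].iloc[0]
        assert abs(row.ppv - row.prevalence) < 0.12

    def test_any_state_rows_use_union_of_alarms(self):
        segments = seg_inventory(2, 0, 2)
        states = ["a", "b"]
        # each manic segment alarms in a different state
        results = results_from_flags(
            segments, states,
            lambda seg, st_, ind: ind == "ar1"
            and (
                (seg.patient_id == "M0" and st_ == "a")
                or (seg.patient_id == "M1" and st_ == "b")
            ),
        )
        t = evaluation_table(results, segments, states)
        avg = t[
            (t.state == ANY_STATE)
            & (t.indicator == "ar1")
            & (t.transition_kind == "manic")
        ].iloc[0]
        assert avg.sensitivity == 1.0
        per_state = t[
            (t.state == "a")
            & (t.indicator == "ar1")
            & (t.transition_kind == "manic")
        ].iloc[0]
        assert per_state.sensitivity == 0.5
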