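"""Mann-Kendall trend test, Hamed-Rao correction and within-patient FDR."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import moodews as m
from moodews.ews import IndicatorSeries
from moodews.inference import (
    EwsTestResult,
    HamedRaoOptions,
    fdr_within_patient,
    hamed_rao_correct,
    kendall_trend,
    restrict_to_final_fortnight,
)


def brute_force_mk(x):
    """O(n^2) Mann-Kendall S and tie-corrected var(S), explicit loops."""
    n = len(x)
    s = 0
    for i in range(n):
        for j in range(i + 1, n):
            s += np.sign(x[j] - x[i])
    from collections import Counter

    ties = [c for c in Counter(x).values() if c > 1]
    var_s = n * (n - 1) * (2 * n + 5) / 18.0
    for t in ties:
        var_s -= t * (t - 1) * (2 * t + 5) / 18.0
    d = n * (n - 1) / 2.0
    u = sum(t * (t - 1) / 2.0 for t in ties)
    tau = s / np.sqrt(d * (d - u)) if d > u else np.nan
    return s, var_s, tau


def make_result(pid, state, indicator, tau, p, segment="seg0", valid=True):
    r = EwsTestResult(
        patient_id=pid,
        state=state,
        indicator=indicator,
        segment_id=segment,
        segment_kind="pre_transition",
        transition_kind="manic",
    )
    r.tau, r.p_raw, r.p_corrected, r.valid = tau, p, p, valid
    return r


class TestKendallTrend:
    def test_monotone_sequences(self):
        assert kendall_trend(np.arange(15.0)).tau == pytest.approx(1.0)
        assert kendall_trend(np.arange(15.0)[::-1]).tau == pytest.approx(-1.0)

    def test_small_example_pair_enumeration(self):
        with pytest.warns(UserWarning, match="unstable"):
            tr = kendall_trend([1.0, 3.0, 2.0, 4.0])
        assert tr.s == 4  # (+,+,+,-,+,+) by hand

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(300):
            n = int(rng.integers(5, 40))
            x = rng.integers(0, 8, size=n).astype(float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tr = kendall_trend(x)
            s, var_s, tau = brute_force_mk(x)
            assert tr.s == s
            assert tr.var_s == pytest.approx(var_s)
            if not np.isnan(tau):
                assert tr.tau == pytest.approx(tau)

    def test_matches_scipy_tau_b_against_time(self, rng):
        for _ in range(50):
            x = rng.normal(size=25)
            ref = stats.kendalltau(np.arange(25), x).statistic
            assert kendall_trend(x).tau == pytest.approx(ref)

    def test_all_tied_flagged(self):
        tr = kendall_trend(np.full(12, 3.0))
        assert np.isnan(tr.tau) and not tr.valid

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="indicator points"):
            kendall_trend([1.0, 2.0])


class TestHamedRao:
    def test_serially_independent_factor_near_one(self, rng):
        factors = []
        for _ in range(200):
            x = rng.normal(size=60)
            tr = kendall_trend(x)
            f, _, _ = hamed_rao_correct(
                x, tr, HamedRaoOptions(acf_source="fortnight")
            )
            factors.append(f)
        assert np.mean(factors) == pytest.approx(1.0, abs=0.1)

    def test_autocorrelated_series_corrected_p_larger(self, rng):
        # smooth series: cumulative sum has strong positive rank ACF
        x = np.cumsum(rng.normal(size=80))
        tr = kendall_trend(x)
        f, var_c, p_c = hamed_rao_correct(
            x, tr, HamedRaoOptions(acf_source="fortnight")
        )
        assert f > 2.0
        assert var_c == pytest.approx(tr.var_s * f)
        from moodews.inference import _normal_p

        assert p_c >= _normal_p(tr.s, tr.var_s)

    def test_segment_acf_source_corrects_more_than_fortnight(self, rng):
        # indicator-like series: moving average of white noise, tested on
        # its tail while the ACF comes from the longer series
        z = rng.normal(size=300)
        smooth = np.convolve(z, np.ones(60) / 60, mode="valid")
        tail = smooth[-70:]
        tr = kendall_trend(tail)
        f_short, _, _ = hamed_rao_correct(
            tail, tr, HamedRaoOptions(acf_source="fortnight")
        )
        f_long, _, _ = hamed_rao_correct(
            tail, tr, HamedRaoOptions(), acf_values=smooth
        )
        assert f_long > f_short

    def test_short_series_falls_back_uncorrected(self):
        x = np.arange(8.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tr = kendall_trend(x)
        with pytest.warns(UserWarning, match="unstable"):
            f, var_c, _ = hamed_rao_correct(x, tr)
        assert f == 1.0 and var_c == tr.var_s

    def test_floor_keeps_factor_at_least_one(self, rng):
        for _ in range(50):
            x = rng.normal(size=40)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tr = kendall_trend(x)
            f, _, _ = hamed_rao_correct(x, tr)
            assert f >= 1.0


class TestFdrWithinPatient:
    def test_single_small_p_significant(self):
        results = [make_result("P00", "s0", "ar1", 0.5, 0.03)]
        fdr_within_patient(results)
        assert results[0].significant

    def test_bh_step_up_hand_oracle(self):
        # {0.01, 0.02, 0.04, 0.90} at q=.05: thresholds k*q/4 are
        # .0125, .025, .0375, .05 -> largest k with p_(k) <= threshold
        # is 2, so exactly the two smallest are rejected
        ps = [0.01, 0.02, 0.04, 0.90]
        results = [
            make_result("P00", f"s{i}", "ar1", 0.5, p)
            for i, p in enumerate(ps)
        ]
        fdr_within_patient(results)
        assert [r.significant for r in results] == [True, True, False, False]

    def test_all_ones_nothing_significant(self):
        results = [
            make_result("P00", f"s{i}", "ar1", 0.5, 1.0) for i in range(5)
        ]
        fdr_within_patient(results)
        assert not any(r.significant for r in results)

    def test_negative_tau_never_flagged(self):
        results = [make_result("P00", "s0", "ar1", -0.8, 0.001)]
        fdr_within_patient(results)
        assert not results[0].significant

    def test_mixed_patients_rejected(self):
        results = [
            make_result("P00", "s0", "ar1", 0.5, 0.01),
            make_result("P01", "s0", "ar1", 0.5, 0.01),
        ]
        with pytest.raises(ValueError, match="single patient"):
            fdr_within_patient(results)

    @given(
        st.lists(
            st.floats(min_value=0.001, max_value=1.0, allow_nan=False),
            min_size=2,
            max_size=8,
        ),
        st.integers(min_value=0, max_value=7),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bh_monotone_in_pvalues(self, ps, which):
        which = which % len(ps)
        results = [
            make_result("P00", f"s{i}", "ar1", 0.5, p)
            for i, p in enumerate(ps)
        ]
        fdr_within_patient(results)
        before = {r.state for r in results if r.significant}
        lowered = list(ps)
        lowered[which] = lowered[which] / 2.0
        results2 = [
            make_result("P00", f"s{i}", "ar1", 0.5, p)
            for i, p in enumerate(lowered)
        ]
        fdr_within_patient(results2)
        after = {r.state for r in results2 if r.significant}
        assert before - {f"s{which}"} <= after


class TestRestrictToFinalFortnight:
    def _series(self, ends, estimates):
        ends = np.asarray(ends)
        est = np.asarray(estimates, dtype=float)
        return IndicatorSeries(
            "P00", "s", "ar1", "seg", ends, est,
            np.full(len(ends), 50), np.full(len(ends), 40),
        )

    def test_window_ends_in_final_fortnight_kept(self):
        ends = np.arange(70, 150)  # 80 windows before a slot-150 event
        s = self._series(ends, np.arange(80.0))
        vals = restrict_to_final_fortnight(s, 150)
        assert len(vals) == 70
        np.testing.assert_array_equal(vals, np.arange(10.0, 80.0))

    def test_short_series_keeps_everything(self):
        s = self._series(np.arange(70, 100), np.arange(30.0))
        vals = restrict_to_final_fortnight(s, 150)
        assert len(vals) == 30

    def test_control_anchor_at_segment_end(self):
        ends = np.arange(70, 246)
        s = self._series(ends, np.arange(176.0))
        vals = restrict_to_final_fortnight(s, 245)
        np.testing.assert_array_equal(vals, np.arange(105.0, 175.0))

    def test_invalid_estimates_dropped(self):
        est = np.arange(80.0)
        est[20:] = np.nan
        s = self._series(np.arange(70, 150), est)
        vals = restrict_to_final_fortnight(s, 150)
        assert len(vals) == 10  # ends 80..89 valid only
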