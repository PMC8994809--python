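"""Generator contracts: bounds, missingness, determinism, planted structure."""

import warnings

import numpy as np
import pytest

import moodews as m
from moodews.ews import WindowSpec, indicator_series
from moodews.inference import kendall_trend, restrict_to_final_fortnight
from moodews.preprocess import default_bandwidth, detrend_kernel, winsorize


def _within_day_lag1(values, bpd):
    """Sample lag-1 autocorrelation over same-day observed pairs."""
    v = np.asarray(values, float)
    idx = np.arange(1, len(v))
    ok = (
        ~np.isnan(v[idx])
        & ~np.isnan(v[idx - 1])
        & (idx // bpd == (idx - 1) // bpd)
    )
    a, b = v[idx[ok] - 1], v[idx[ok]]
    return np.corrcoef(a, b)[0, 1], ok.sum()


class TestSimulateEma:
    def test_no_missingness_fills_every_slot(self):
        sim = m.SimConfig(n_patients=1, days=14, missing_rate=0.0, seed=1)
        ema, _ = m.simulate_ema(sim)
        assert all(s.n_observed == sim.grid.n_slots for s in ema)

    def test_deterministic_under_seed(self):
        sim = m.SimConfig(n_patients=2, days=21, seed=7)
        a, _ = m.simulate_ema(sim)
        b, _ = m.simulate_ema(sim)
        for sa, sb in zip(a, b):
            assert sa.patient_id == sb.patient_id and sa.state == sb.state
            np.testing.assert_array_equal(sa.values, sb.values)

    def test_values_bounded(self):
        sim = m.SimConfig(n_patients=1, days=49, seed=3, baseline_sd=30.0)
        ema, _ = m.simulate_ema(sim)
        for s in ema:
            obs = s.values[s.observed_mask]
            assert obs.min() >= 0.0 and obs.max() <= 100.0

    def test_missingness_fraction_matches_rate(self):
        # pooled over 17 states x 595 slots, the realized rate has SE ~0.4%
        sim = m.SimConfig(n_patients=1, days=119, missing_rate=0.24, seed=5)
        ema, _ = m.simulate_ema(sim)
        frac = np.mean([np.isnan(s.values).mean() for s in ema])
        assert abs(frac - 0.24) < 0.03

    def test_zero_baseline_ar_gives_near_zero_lag1(self):
        """Monte-Carlo: with phi=0, within-day lag-1 correlation ~ 0."""
        hits = total = 0
        for seed in range(100):
            sim = m.SimConfig(
                n_patients=1, days=49, n_states=1,
                missing_rate=0.0, baseline_ar=0.0, seed=seed,
            )
            ema, _ = m.simulate_ema(sim)
            r, n = _within_day_lag1(ema[0].values, 5)
            hits += abs(r) <= 3.0 / np.sqrt(n)
            total += 1
        assert hits / total >= 0.95

    def test_overnight_innovations_independent(self):
        """Cross-day lag correlation stays ~0 even at high baseline AR."""
        sim = m.SimConfig(
            n_patients=1, days=119, n_states=1,
            missing_rate=0.0, baseline_ar=0.8, seed=11,
        )
        ema, _ = m.simulate_ema(sim)
        v = ema[0].values
        idx = np.arange(1, len(v))
        cross = idx[idx % 5 == 0]  # first beep of each day
        r_cross = np.corrcoef(v[cross - 1], v[cross])[0, 1]
        r_within, _ = _within_day_lag1(v, 5)
        assert abs(r_cross) < 0.2
        assert r_within > 0.6

        carry = m.SimConfig(
            n_patients=1, days=119, n_states=1, missing_rate=0.0,
            baseline_ar=0.8, seed=11, overnight_carryover=True,
        )
        ema_c, _ = m.simulate_ema(carry)
        vc = ema_c[0].values
        r_carry = np.corrcoef(vc[cross - 1], vc[cross])[0, 1]
        assert r_carry > 0.5

    def test_ramp_overlapping_prior_transition_rejected(self):
        with pytest.raises(ValueError, match="overlaps"):
            m.SimConfig(
                n_patients=1,
                days=119,
                transition_specs=[
                    m.TransitionSpec("P00", "manic", 5, 7),
                    m.TransitionSpec("P00", "depressive", 10, 7),
                ],
                ews_specs=[
                    m.EwsSpec(
                        "P00", "cheerful", "ar",
                        ar_ramp=(0.2, 0.7), ramp_days=40,
                        transition_week=10,
                    )
                ],
            )

    def test_ar_ramp_raises_moving_window_estimate(self, grid49):
        """A planted 0.2 -> 0.8 AR ramp makes the ar1 indicator rise.

        The Kendall tau of the indicator over the ramp fortnight is
        positive far more often than the 50% expected without a ramp.
        """
        spec = WindowSpec()
        pos = tot = 0
        for seed in range(200):
            sim = m.SimConfig(
                n_patients=1, days=49, n_states=1, seed=seed,
                baseline_ar=0.2,
                transition_specs=[m.TransitionSpec("P00", "manic", 6, 7)],
                ews_specs=[
                    m.EwsSpec("P00", "cheerful", "ar", ar_ramp=(0.2, 0.8))
                ],
            )
            ema, truth = m.simulate_ema(sim)
            ev = truth.transitions["P00"][0]
            seg = m.extract_pre_transition_segment(ev, grid49)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                w = winsorize(ema[0].values[seg.start_slot : seg.end_slot])
                full = np.full(grid49.n_slots, np.nan)
                full[seg.start_slot : seg.end_slot] = detrend_kernel(
                    w, default_bandwidth(w)
                )
                ind = indicator_series(full, seg, grid49, spec, "ar1")
                vals = restrict_to_final_fortnight(ind, ev.aligned_slot)
                if len(vals) >= 3:
                    tot += 1
                    pos += kendall_trend(vals).tau > 0
        assert tot >= 190
        assert pos / tot >= 0.70


class TestSimulateWeekly:
    def test_transition_jump_by_construction(self):
        sim = m.SimConfig(
            n_patients=1, days=119, seed=2,
            transition_specs=[m.TransitionSpec("P00", "manic", 8, 6)],
        )
        weekly = m.simulate_weekly(sim)
        asrm = next(s for s in weekly if s.instrument == "ASRM")
        assert asrm.scores[8] - asrm.scores[7] == 6

    def test_depressive_magnitude_eleven_on_qids(self):
        # mirrors the typical observed depressive jump magnitude (~11)
        sim = m.SimConfig(
            n_patients=1, days=119, seed=2,
            transition_specs=[m.TransitionSpec("P00", "depressive", 8, 11)],
        )
        weekly = m.simulate_weekly(sim)
        qids = next(s for s in weekly if s.instrument == "QIDS")
        assert qids.scores[8] - qids.scores[7] == 11
        assert qids.scores.max() <= 48

    def test_no_transitions_roundtrip_empty(self):
        sim = m.SimConfig(n_patients=3, days=119, seed=4)
        weekly = m.simulate_weekly(sim)
        assert m.detect_transitions(weekly, sim.grid) == []

    def test_scores_within_instrument_ranges(self):
        sim = m.SimConfig(
            n_patients=4, days=119, seed=6,
            transition_specs=[m.TransitionSpec("P01", "manic", 8, 12)],
            unstable_patient_ids=("P03",),
        )
        weekly = m.simulate_weekly(sim)
        for s in weekly:
            hi = 20 if s.instrument == "ASRM" else 48
            assert s.scores.min() >= 0 and s.scores.max() <= hi

    def test_magnitude_above_instrument_maximum_errors(self):
        sim_kwargs = dict(
            n_patients=1, days=119, seed=2,
            transition_specs=[m.TransitionSpec("P00", "manic", 8, 21)],
        )
        with pytest.raises(ValueError, match="maximum"):
            m.simulate_weekly(m.SimConfig(**sim_kwargs))

    def test_unstable_patients_have_no_control_run(self):
        sim = m.SimConfig(
            n_patients=1, days=119, seed=9,
            unstable_patient_ids=("P00",),
        )
        weekly = m.simulate_weekly(sim)
        assert m.detect_transitions(weekly, sim.grid) == []
        assert m.select_control_segment(weekly, sim.grid) is None
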