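"""Screening statistics: Z', hit calls, 4PL fits, kinetics, group stats."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nethcs import screen_analytics as SA
from nethcs import synthetic_imaging as si


class TestZPrime:
    def test_zero_variance_limit(self):
        res = SA.zprime([70.0, 70.0, 70.0], [1.0, 1.0, 1.0])
        assert res.z_prime == 1.0

    def test_hand_evaluated_closed_form(self):
        # mu_n=1.5 sd_n=0.5, mu_p=70 sd_p=4 -> 1 - 13.5/68.5 = 0.80292
        pos = [70 - 4 / math.sqrt(2) * x for x in (1, -1)] * 2
        neg = [1.5 - 0.5 / math.sqrt(2) * x for x in (1, -1)] * 2
        res = SA.zprime(pos, neg)
        # sample sd of the symmetric pairs: sd = delta * sqrt(n/(n-1)) / ...
        # compute directly against the closed form instead
        expected = 1 - 3 * (np.std(pos, ddof=1) + np.std(neg, ddof=1)) / abs(
            np.mean(pos) - np.mean(neg))
        assert res.z_prime == pytest.approx(expected, rel=1e-12)

    def test_reference_values(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(70, 4, 200)
        neg = rng.normal(1.5, 0.5, 200)
        res = SA.zprime(pos, neg)
        assert res.z_prime == pytest.approx(0.80292, abs=0.02)

    def test_identical_arms_fail(self):
        res = SA.zprime([5.0, 6.0], [5.0, 6.0])
        assert res.failed and res.z_prime is None

    def test_too_few_wells_rejected(self):
        with pytest.raises(ValueError, match="2 wells"):
            SA.zprime([70.0], [1.0, 2.0])

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=10),
           st.lists(st.floats(0, 100), min_size=2, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_matches_direct_arithmetic(self, pos, neg):
        res = SA.zprime(pos, neg)
        mu_p, mu_n = np.mean(pos), np.mean(neg)
        if mu_p == mu_n:
            assert res.failed
        else:
            direct = 1 - 3 * (np.std(pos, ddof=1) + np.std(neg, ddof=1)) / abs(mu_p - mu_n)
            assert res.z_prime == pytest.approx(direct, rel=1e-9)
            assert res.z_prime <= 1.0


class TestCallHits:
    def test_threshold_semantics(self):
        calls = {c.compound_id: c for c in SA.call_hits(
            {"a": 45.0, "b": 8.0, "c": 50.0, "d": 72.0})}
        assert calls["a"].active and not calls["a"].strong
        assert calls["b"].active and calls["b"].strong
        assert not calls["c"].active  # strictly below 50
        assert not calls["d"].active

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SA.call_hits({"x": 140.0})

    def test_strong_implies_active(self):
        rng = np.random.default_rng(0)
        for c in SA.call_hits({f"c{i}": float(v) for i, v in
                               enumerate(rng.uniform(0, 100, 50))}):
            assert c.active or not c.strong

    @given(st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_hit_count_monotone_in_threshold(self, t1, t2):
        pcts = {f"c{i}": float(v) for i, v in enumerate(np.linspace(0, 100, 21))}
        lo, hi = sorted((t1, t2))
        n_lo = sum(c.active for c in SA.call_hits(pcts, active_threshold=lo))
        n_hi = sum(c.active for c in SA.call_hits(pcts, active_threshold=hi))
        assert n_lo <= n_hi

    def test_replicate_aggregation_is_mean(self):
        wells = [
            {"compound_id": "a", "pct_netotic": 40.0},
            {"compound_id": "a", "pct_netotic": 60.0},
            {"compound_id": "b", "pct_netotic": 10.0},
        ]
        agg = SA.aggregate_replicates(wells)
        assert agg == {"a": 50.0, "b": 10.0}


class TestDoseResponse:
    conc = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0])

    def test_exact_data_recovered(self):
        resp = SA.four_pl(self.conc, 1.0, 70.0, 2.0, 2.0)
        fit = SA.fit_dose_response(self.conc, resp)
        assert fit.converged and not fit.degenerate
        assert fit.bottom == pytest.approx(1.0, rel=1e-6, abs=1e-6)
        assert fit.top == pytest.approx(70.0, rel=1e-6)
        assert fit.ec50_um == pytest.approx(2.0, rel=1e-6)
        assert fit.hill_coef == pytest.approx(2.0, rel=1e-6)

    def test_flat_data_degenerate(self):
        fit = SA.fit_dose_response(self.conc, np.full_like(self.conc, 30.0))
        assert fit.degenerate and fit.ec50_um is None

    def test_multi_start_idempotent(self):
        resp = SA.four_pl(self.conc, 2.0, 65.0, 1.5, 1.2)
        fits = [SA.fit_dose_response(self.conc, resp) for _ in range(3)]
        for f in fits[1:]:
            assert f.ec50_um == pytest.approx(fits[0].ec50_um, rel=1e-9)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            SA.fit_dose_response([0, 1, 2], [70, 40, 10])

    def test_seeded_synthetic_screen_recovers_ec50(self):
        # capsaicin-like wells: 6 doses x 3 replicates, well noise sd 3 pct
        law = si.DEFAULT_RESPONSE_LAW
        rng = np.random.default_rng(99)
        doses = np.array([0.0, 0.3, 0.6, 1.2, 2.5, 5.0])
        concs, resps = [], []
        for c in doses:
            induced = law.induced_frac("PMA", 210.0)
            f = law.baseline_frac + (induced - law.baseline_frac) * (
                1 - si.CAPSAICIN_LIKE.inhibition(float(c)))
            for _ in range(3):
                concs.append(c)
                resps.append(100 * f + rng.normal(0, 3.0))
        fit = SA.fit_dose_response(concs, resps)
        assert fit.converged
        assert 1.0 <= fit.ec50_um <= 2.0


class TestKinetics:
    def test_constant_trace(self):
        t = np.arange(0, 30, 5.0)
        tr = si.KineticTrace(t, np.ones_like(t))
        ks = SA.summarize_kinetics(tr)
        assert ks.peak_fold == 1.0
        assert ks.t_steady_min == 0.0

    def test_closed_form_exponential(self):
        t = np.arange(0, 125, 5.0)
        tr = si.KineticTrace(t, 1 + 5 * (1 - np.exp(-t / 20.0)))
        ks = SA.summarize_kinetics(tr)
        assert ks.plateau == pytest.approx(6.0, rel=1e-6)
        assert ks.t_steady_min == 60.0  # first sample >= 5.75 (t95 = 59.91)

    def test_tmrm_depolarization_ratio(self):
        t = np.arange(0, 65, 5.0)
        veh = si.simulate_tmrm_trace(si.TMRM_VEHICLE_PRESET, t, rng=1)
        unc = si.simulate_tmrm_trace(si.TMRM_UNCOUPLED_PRESET, t, rng=2)
        ks = SA.summarize_kinetics(unc, baseline=veh)
        assert ks.final_ratio_vs_baseline < 0.5

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            si.KineticTrace(np.array([0.0, 10.0, 5.0]), np.zeros(3))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="5 timepoints"):
            SA.summarize_kinetics(si.KineticTrace(
                np.array([0.0, 5.0, 10.0]), np.ones(3)))


class TestCompareGroups:
    def test_identical_constant_groups(self):
        res = SA.compare_groups({"a": [1, 1, 1], "b": [1, 1, 1]}, "a")
        assert res.anova_f == 0.0
        assert not any(c.reject for c in res.comparisons)

    def test_equal_lists_f_zero(self):
        res = SA.compare_groups({"a": [1, 2, 3], "b": [1, 2, 3]}, "a")
        assert res.anova_f == pytest.approx(0.0)

    def test_missing_control_rejected(self):
        with pytest.raises(KeyError, match="ctrl"):
            SA.compare_groups({"a": [1, 2], "b": [3, 4]}, "ctrl")

    def test_matches_scipy_dunnett_oracle(self):
        from scipy.stats import dunnett

        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 12)
        b = rng.normal(1.1, 1, 12)
        ctrl = rng.normal(0, 1, 12)
        ours = SA.compare_groups({"ctrl": ctrl, "a": a, "b": b}, "ctrl")
        ref = dunnett(a, b, control=ctrl)
        ours_p = {c.group: c.p_adjusted for c in ours.comparisons}
        assert ours_p["a"] == pytest.approx(ref.pvalue[0], abs=0.01)
        assert ours_p["b"] == pytest.approx(ref.pvalue[1], abs=0.01)

    def test_detects_large_shift(self):
        rng = np.random.default_rng(7)
        res = SA.compare_groups({
            "ctrl": rng.normal(0, 1, 10),
            "same": rng.normal(0, 1, 10),
            "shifted": rng.normal(4, 1, 10),
        }, "ctrl")
        decisions = {c.group: c.reject for c in res.comparisons}
        assert decisions["shifted"]
        assert not decisions["same"]

    def test_normality_warnings_reported(self):
        rng = np.random.default_rng(8)
        res = SA.compare_groups({
            "ctrl": rng.normal(0, 1, 20),
            "skewed": rng.exponential(1, 20) ** 3,
        }, "ctrl")
        assert set(res.normality_warnings) == {"ctrl", "skewed"}
        assert res.normality_warnings["skewed"] < res.normality_warnings["ctrl"]
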