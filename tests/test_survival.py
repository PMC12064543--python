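"""Survival metrics: AUC/DeLong, concordance, Brier, DCA, cutoffs, KM."""

import numpy as np
import pytest

from ithrad.survival import (
    calibration_points,
    decision_curve,
    delong_compare,
    harrell_c,
    integrated_brier,
    km_logrank,
    optimal_cutoff,
    roc_auc,
    time_dependent_auc,
)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_scores_tied(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_hand_enumerated_pairs(self):
        # cases (0.9, 0.4), controls (0.6, 0.1): 3 of 4 pairs concordant
        assert roc_auc([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0]) == 0.75

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_reorder_invariance(self, rng):
        s = rng.random(40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        perm = rng.permutation(40)
        assert roc_auc(s, y) == pytest.approx(roc_auc(s[perm], y[perm]))


class TestDeLong:
    def test_identical_scores_p_one(self):
        s = [0.9, 0.4, 0.6, 0.1]
        d, se, p = delong_compare(s, s, [1, 1, 0, 0])
        assert d == 0.0
        assert p == 1.0

    def test_auc_matches_rank_estimator(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        a, b = rng.random(60), rng.random(60)
        d, _, _ = delong_compare(a, b, y)
        assert d == pytest.approx(roc_auc(a, y) - roc_auc(b, y), abs=1e-12)

    def test_unpaired_lengths_error(self):
        with pytest.raises(ValueError):
            delong_compare([0.1, 0.2], [0.3], [1, 0])

    def test_informative_vs_noise_significant(self, rng):
        n = 200
        y = rng.integers(0, 2, n)
        good = y + 0.5 * rng.standard_normal(n)
        noise = rng.standard_normal(n)
        d, se, p = delong_compare(good, noise, y)
        assert d > 0.2
        assert p < 0.01


class TestHarrellC:
    def test_no_censoring_perfect_ranking(self):
        t = np.array([5.0, 3.0, 9.0, 1.0])
        assert harrell_c(t, np.ones(4, int), -t) == 1.0

    def test_all_risks_tied(self):
        assert harrell_c([1, 2, 3], [1, 1, 1], [0.5, 0.5, 0.5]) == 0.5

    def test_censoring_comparability_rule(self):
        # times (2,4,6), events (1,0,1), risks (3,1,2): comparable pairs are
        # (1,2) and (1,3) only; both concordant
        assert harrell_c([2, 4, 6], [1, 0, 1], [3, 1, 2]) == 1.0

    def test_no_comparable_pairs_errors(self):
        with pytest.raises(ValueError):
            harrell_c([1, 2, 3], [0, 0, 0], [1, 2, 3])

    def test_matches_lifelines(self, rng):
        from lifelines.utils import concordance_index

        n = 80
        t = rng.exponential(10, n)
        e = rng.integers(0, 2, n)
        e[:2] = 1
        r = rng.random(n)
        ours = harrell_c(t, e, r)
        ref = concordance_index(t, -r, e)
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_equals_roc_auc_on_binary_coded_outcomes(self, rng):
        # cases fail at t=1, controls survive to t=2, no censoring
        for _ in range(5):
            y = rng.integers(0, 2, 50)
            y[:2] = [0, 1]
            s = rng.random(50)
            t = np.where(y == 1, 1.0, 2.0)
            assert harrell_c(t, np.ones(50, int), s) == pytest.approx(
                roc_auc(s, y), abs=1e-12
            )


class TestIntegratedBrier:
    def test_oracle_forecasts_score_zero(self, rng):
        n = 30
        t = rng.uniform(1, 20, n)
        e = np.ones(n, int)
        grid = np.sort(rng.choice(t, 10, replace=False))
        S = (t[:, None] > grid[None, :]).astype(float)
        assert integrated_brier(t, e, S, grid) == pytest.approx(0.0, abs=1e-12)

    def test_constant_half_forecast(self, rng):
        n = 50
        t = rng.uniform(1, 10, n)
        e = np.ones(n, int)
        grid = np.linspace(1.0, t.max(), 20)
        S = np.full((n, len(grid)), 0.5)
        assert integrated_brier(t, e, S, grid) == pytest.approx(0.25, abs=1e-9)

    def test_grid_beyond_follow_up_errors(self, rng):
        t = rng.uniform(1, 10, 20)
        with pytest.raises(ValueError):
            integrated_brier(t, np.ones(20, int), np.ones((20, 1)),
                             [t.max() + 1.0])

    def test_matches_sksurv_brier_at_single_time(self, rng):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        from ithrad.survival import brier_score

        n = 60
        t = rng.exponential(10, n) + 0.1
        e = rng.integers(0, 2, n)
        e[:4] = 1
        s = rng.random(n)
        tau = float(np.quantile(t[e == 1], 0.5))
        ours = brier_score(t, e, s, tau)
        y = np.array([(bool(ev), tt) for ev, tt in zip(e, t)],
                     dtype=[("event", "?"), ("time", "<f8")])
        _, ref = sksurv_metrics.brier_score(y, y, s[:, None], [tau])
        assert ours == pytest.approx(float(ref[0]), abs=1e-9)


class TestTimeDependentAuc:
    def test_reduces_to_roc_auc_without_censoring(self, rng):
        n = 100
        t = rng.uniform(1, 10, n)
        e = np.ones(n, int)
        s = rng.random(n)
        tau = 5.0
        labels = (t <= tau).astype(int)
        assert time_dependent_auc(t, e, s, tau) == pytest.approx(
            roc_auc(s, labels), abs=1e-12
        )

    def test_uninformative_score_near_half(self, rng):
        n = 500
        t = rng.exponential(20, n)
        c = rng.uniform(0, 60, n)
        e = (t <= c).astype(int)
        obs = np.minimum(t, c)
        s = rng.random(n)
        assert abs(time_dependent_auc(obs, e, s, 15.0) - 0.5) < 0.05

    def test_monotone_transform_invariance(self, rng):
        n = 80
        t = rng.exponential(10, n)
        e = rng.integers(0, 2, n)
        e[:5] = 1
        s = rng.random(n)
        tau = float(np.median(t))
        a = time_dependent_auc(t, e, s, tau)
        b = time_dependent_auc(t, e, np.exp(3 * s), tau)
        assert a == pytest.approx(b, abs=1e-12)

    def test_no_cases_errors(self, rng):
        t = np.full(10, 20.0)
        with pytest.raises(ValueError):
            time_dependent_auc(t, np.ones(10, int), rng.random(10), 5.0)


class TestDecisionCurve:
    def test_treat_none_is_zero(self, rng):
        out = decision_curve(rng.random(50), rng.integers(0, 2, 50),
                             [0.2, 0.5, 0.8])
        assert (out["treat_none"] == 0.0).all()

    def test_treat_all_closed_form(self, rng):
        y = rng.integers(0, 2, 200)
        prev = y.mean()
        out = decision_curve(rng.random(200), y, [0.3])
        expected = prev - (1 - prev) * 0.3 / 0.7
        assert out["treat_all"].iloc[0] == pytest.approx(expected)

    def test_perfect_classifier_net_benefit_equals_prevalence(self):
        y = np.array([1] * 30 + [0] * 70)
        p = y.astype(float)
        out = decision_curve(p, y, [0.2, 0.5, 0.9])
        assert np.allclose(out["net_benefit"], 0.3)

    def test_threshold_outside_unit_interval_errors(self, rng):
        with pytest.raises(ValueError):
            decision_curve(rng.random(10), rng.integers(0, 2, 10), [0.0, 0.5])


class TestCalibration:
    def test_well_calibrated_simulator(self, rng):
        n = 5000
        p = rng.random(n)
        y = (rng.random(n) < p).astype(int)
        pts = calibration_points(p, y, n_bins=10)
        assert (pts["mean_predicted"] - pts["observed_fraction"]).abs().max() < 0.05

    def test_degenerate_all_ones(self):
        pts = calibration_points(np.ones(20), np.ones(20, int), n_bins=5)
        assert len(pts) == 1
        assert pts.iloc[0]["mean_predicted"] == 1.0
        assert pts.iloc[0]["observed_fraction"] == 1.0

    def test_bin_count_clamped_to_distinct_values(self, rng):
        p = np.repeat([0.2, 0.8], 25)
        y = rng.integers(0, 2, 50)
        pts = calibration_points(p, y, n_bins=10)
        assert len(pts) == 2


class TestCutoffAndKM:
    def _bimodal(self, rng, n=300):
        grp = rng.integers(0, 2, n)
        score = np.where(grp, rng.normal(2.0, 0.4, n), rng.normal(0.0, 0.4, n))
        lam = np.where(grp, 0.09, 0.03)
        t = rng.exponential(1.0 / lam)
        e = (t <= 60).astype(int)
        return score, np.minimum(t, 60.0), e

    def test_cutoff_lands_between_modes(self, rng):
        score, t, e = self._bimodal(rng)
        cut = optimal_cutoff(score, t, e)
        assert 0.5 < cut < 1.5

    def test_identical_scores_error(self, rng):
        t = rng.exponential(10, 30)
        with pytest.raises(ValueError):
            optimal_cutoff(np.ones(30), t, np.ones(30, int))

    def test_sign_reflection_swaps_groups(self, rng):
        score, t, e = self._bimodal(rng, n=120)
        cut = optimal_cutoff(score, t, e)
        cut_neg = optimal_cutoff(-score, t, e)
        high = score > cut
        low_neg = -score <= cut_neg
        assert np.array_equal(high, low_neg)

    def test_min_group_fraction_enforced(self, rng):
        score, t, e = self._bimodal(rng)
        cut = optimal_cutoff(score, t, e, min_group_frac=0.3)
        frac = np.mean(score > cut)
        assert 0.3 <= frac <= 0.7

    def test_km_identical_groups_null(self, rng):
        t = rng.exponential(10, 40)
        e = rng.integers(0, 2, 40)
        e[:2] = 1
        t2 = np.concatenate([t, t])
        e2 = np.concatenate([e, e])
        g = np.array([0] * 40 + [1] * 40)
        res = km_logrank(t2, e2, g)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.99

    def test_km_step_heights_match_empirical_survival(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.ones(6, int)
        res = km_logrank(np.concatenate([t, t]), np.concatenate([e, e]),
                         [0] * 6 + [1] * 6)
        curve = res.curves[0]
        surv_at = curve["survival"]
        for i, u in enumerate(t):
            assert surv_at.loc[u] == pytest.approx(1.0 - (i + 1) / 6)

    def test_logrank_matches_hand_computation(self):
        """O-E/V on a 10-subject fixture, no ties across groups."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        e = np.array([1, 1, 0, 1, 1, 0, 1, 1, 1, 0])
        g = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1])
        # hand computation of the log-rank statistic
        order = np.argsort(t)
        o_minus_e = 0.0
        var = 0.0
        for i in order:
            if e[i] != 1:
                continue
            at_risk = t >= t[i]
            n = at_risk.sum()
            n1 = (at_risk & (g == 1)).sum()
            o = 1.0 if g[i] == 1 else 0.0
            exp = n1 / n
            o_minus_e += o - exp
            var += exp * (1 - exp)
        expected_chi2 = o_minus_e**2 / var
        res = km_logrank(t, e, g)
        assert res.chi2 == pytest.approx(expected_chi2, abs=1e-9)

    def test_single_group_errors(self, rng):
        with pytest.raises(ValueError):
            km_logrank(rng.exponential(5, 10), np.ones(10, int), np.zeros(10))
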