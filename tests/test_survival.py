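"""Survival core: Kaplan-Meier, log-rank, Cox PH, multiplicity, correlation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survscreen.survival import (
    CoxPH,
    _partial_likelihood,
    benjamini_hochberg,
    bonferroni_adjust,
    cox_fit,
    cox_score_test,
    km_estimate,
    logrank_test,
    mean_time_to_event,
    pearson_r,
)

from conftest import random_survival_fixture


# ---------------------------------------------------------------------- KM


class TestKaplanMeier:
    def test_hand_computed_steps(self):
        km = km_estimate([5, 8, 12, 15], [1, 1, 0, 1])
        assert np.allclose(km.survival_at([5, 8, 12, 15]), [0.75, 0.50, 0.50, 0.0])

    def test_no_events_flat_at_one(self):
        km = km_estimate([3, 7, 9], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_single_subject_event(self):
        km = km_estimate([1.0], [1])
        assert km.survival_at(1.0) == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [1, 1])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.1, 100.0), min_size=1, max_size=40))
    def test_no_censoring_equals_empirical_survival(self, times):
        """With every subject an event, KM is the empirical survivor function."""
        t = np.asarray(times)
        km = km_estimate(t, np.ones_like(t))
        grid = np.unique(t)
        expected = [(t > u).mean() for u in grid]
        assert np.allclose(km.survival_at(grid), expected)

    def test_curve_monotone_and_at_risk_decreasing(self, rng):
        _, t, e = random_survival_fixture(rng, 60)
        km = km_estimate(t, e)
        assert np.all(np.diff(km.survival_prob) <= 1e-12)
        assert np.all(np.diff(km.at_risk) <= 0)


# ----------------------------------------------------------------- log-rank


class TestLogrank:
    def test_identical_groups_no_separation(self):
        t = [2, 4, 6, 8.0]
        e = [1, 0, 1, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 < 1e-10 and p > 0.99

    def test_extreme_separation_significant(self):
        ta = np.arange(1.0, 11.0)
        chi2, p = logrank_test(ta, np.ones(10), np.full(10, 20.0), np.zeros(10))
        assert chi2 > 3.84 and p < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1.0], [1])

    def test_against_exact_permutation(self):
        """Chi-square tail p is close to the exact label-permutation p."""
        t = np.array([1.802, 1.204, 13.801, 3.004, 12.002, 2.406,
                      16.001, 12.004, 28.008, 1.004, 24.005, 4.003])
        e = np.array([1, 1, 0, 1, 1, 1, 1, 1, 1, 1, 0, 1])
        obs, p = logrank_test(t[:6], e[:6], t[6:], e[6:])
        stats = []
        for idx in itertools.combinations(range(12), 6):
            a = np.zeros(12, bool)
            a[list(idx)] = True
            stats.append(logrank_test(t[a], e[a], t[~a], e[~a])[0])
        p_perm = np.mean(np.asarray(stats) >= obs - 1e-12)
        assert abs(p - p_perm) <= 0.02


# ---------------------------------------------------------------------- Cox


def grid_search_beta(x, t, e, lo=-5.0, hi=5.0):
    """Brute-force 1-D partial-likelihood maximizer (coarse-to-fine grid)."""
    X = np.asarray(x, float)[:, None]
    t = np.asarray(t, float)
    e = np.asarray(e, float)
    center, width = 0.0, hi - lo
    for _ in range(8):
        grid = np.linspace(center - width / 2, center + width / 2, 201)
        lls = [_partial_likelihood(X, t, e, np.array([b]), "efron")[0] for b in grid]
        center = grid[int(np.argmax(lls))]
        width /= 50
    return center


class TestCox:
    def test_beta_matches_grid_search_on_well_posed_fixture(self):
        """Newton-Raphson equals brute-force maximization when the MLE is finite."""
        t = np.arange(1.0, 7.0)
        e = np.ones(6)
        x = np.array([1, 0, 1, 0, 0, 1.0])
        fit = cox_fit(x[:, None], t, e)
        assert fit.converged
        assert abs(fit.coef[0] - grid_search_beta(x, t, e)) < 1e-4

    def test_monotone_likelihood_flagged_as_separation(self):
        """All events in one group first: no finite MLE; fit warns, not silent."""
        t = np.arange(1.0, 7.0)
        e = np.ones(6)
        x = np.array([1, 1, 1, 0, 0, 0.0])
        with pytest.warns(UserWarning, match="separation|monotone"):
            fit = cox_fit(x[:, None], t, e)
        assert fit.coef[0] > 15
        assert "separation" in " ".join(fit.warnings_)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(np.zeros((5, 1)), np.arange(1.0, 6.0), np.ones(5))

    def test_matches_lifelines_on_random_fixtures(self, rng):
        """Cross-check against an independent reference implementation."""
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        for _ in range(20):
            n = 50
            X = rng.standard_normal((n, 2)) * 0.8
            t = rng.exponential(15.0, n)
            e = (rng.random(n) < 0.7).astype(int)
            if e.sum() < 3:
                continue
            fit = cox_fit(X, t, e)
            df = pd.DataFrame({"x0": X[:, 0], "x1": X[:, 1], "T": t, "E": e})
            ref = lifelines.CoxPHFitter().fit(
                df, "T", "E", fit_options={"precision": 1e-11, "max_steps": 500}
            )
            assert np.allclose(fit.coef, ref.params_.to_numpy(), atol=1e-6)

    def test_score_test_equals_logrank_chi2(self, rng):
        """Score test at beta=0 is the log-rank statistic (untied times)."""
        for _ in range(10):
            x, t, e = random_survival_fixture(rng, 30, unique_times=True)
            g = (x > np.median(x)).astype(float)
            chi2, _ = logrank_test(t[g == 1], e[g == 1], t[g == 0], e[g == 0])
            assert abs(cox_score_test(g, t, e) - chi2) < 1e-6

    def test_ci_coverage_at_true_hazard_ratio(self):
        """Wald 95% CI covers a true HR of 3 in at least 90% of replicates."""
        covered = 0
        reps = 100
        for r in range(reps):
            rg = np.random.default_rng(40_000 + r)
            g = (rg.random(400) < 0.5).astype(int)
            tt = rg.exponential(1.0, 400) / (0.02 * np.where(g == 1, 3.0, 1.0))
            cc = np.minimum(rg.exponential(1 / 0.015, 400), 120.0)
            t = np.minimum(tt, cc)
            e = (tt <= cc).astype(int)
            fit = cox_fit(g[:, None].astype(float), t, e)
            lo, hi = fit.ci95[0]
            covered += lo <= 3.0 <= hi
        assert covered >= 0.90 * reps

    def test_efron_vs_breslow_differ_only_with_ties(self, rng):
        x, t, e = random_survival_fixture(rng, 25, unique_times=True)
        f1 = cox_fit(x[:, None], t, e, ties="efron")
        f2 = cox_fit(x[:, None], t, e, ties="breslow")
        assert np.allclose(f1.coef, f2.coef, atol=1e-8)

    def test_sklearn_estimator_api(self):
        model = CoxPH(ties="breslow")
        assert model.get_params()["ties"] == "breslow"
        model.set_params(ties="efron")
        t = np.arange(1.0, 9.0)
        e = np.ones(8)
        x = np.array([0.5, -1, 2, 0, 1, -0.5, 0.3, -2.0])
        model.fit(x[:, None], (t, e))
        assert model.coef_.shape == (1,)
        assert np.allclose(model.predict(x[:, None]), x * model.coef_[0])


# -------------------------------------------------------- adjustments, means


class TestAdjustments:
    @pytest.mark.parametrize(
        "p, m, expected",
        [(0.01, 3, 0.03), (0.5, 4, 1.0), (0.2, 1, 0.2)],
    )
    def test_bonferroni_definition(self, p, m, expected):
        assert bonferroni_adjust([p], m=m)[0] == pytest.approx(expected)

    def test_bonferroni_rejects_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.2], m=2)
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2], m=1)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20), st.integers(0, 30))
    def test_bonferroni_monotone_order_preserving(self, ps, extra):
        m = len(ps) + extra
        adj = bonferroni_adjust(ps, m=m)
        assert np.all(adj >= np.asarray(ps))
        assert np.all(adj <= 1.0)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_bh_bounded_by_bonferroni(self, rng):
        p = rng.random(30)
        assert np.all(benjamini_hochberg(p) <= bonferroni_adjust(p) + 1e-15)


class TestMeanTimeToEvent:
    def test_mean_over_events_only(self):
        out = mean_time_to_event([10, 14], [1, 1], [0, 0])
        assert out[0] == pytest.approx(12.0)

    def test_censored_only_group_is_nan(self):
        with pytest.warns(UserWarning, match="no events"):
            out = mean_time_to_event([5, 8, 9], [1, 0, 0], [0, 1, 1])
        assert np.isnan(out[1])

    def test_mixed_fixture_hand_computed(self):
        t = [3, 6, 9, 12, 15, 18]
        e = [1, 0, 1, 1, 0, 1]
        g = [0, 0, 0, 1, 1, 1]
        out = mean_time_to_event(t, e, g)
        assert out[0] == pytest.approx((3 + 9) / 2)
        assert out[1] == pytest.approx((12 + 18) / 2)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_anticorrelation(self):
        x = np.arange(5.0)
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_independent_near_zero(self, rng):
        r, _ = pearson_r(rng.standard_normal(1000), rng.standard_normal(1000))
        assert abs(r) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
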