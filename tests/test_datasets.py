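"""Synthetic cohorts: determinism, planted-effect recovery, IHC fields, PSA rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survscreen.datasets import (
    CovariateSpec,
    PlantedEffect,
    SimulationConfig,
    recurrence_from_psa,
    simulate_cohort,
    simulate_hscore_cohort,
    simulate_ihc_fields,
    simulate_survival_for_marker,
)
from survscreen.survival import cox_fit


class TestSimulateCohort:
    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(n_samples=40, n_genes=10, seed=7)
        e1, c1 = simulate_cohort(cfg)
        e2, c2 = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(c1, c2)

    def test_different_seed_differs(self):
        e1, _ = simulate_cohort(SimulationConfig(n_samples=40, n_genes=10, seed=1))
        e2, _ = simulate_cohort(SimulationConfig(n_samples=40, n_genes=10, seed=2))
        assert not np.allclose(e1.to_numpy(), e2.to_numpy())

    def test_zscore_self_consistency(self):
        expr, _ = simulate_cohort(SimulationConfig(n_samples=500, n_genes=50, seed=3))
        assert abs(expr.to_numpy().mean()) < 0.05
        assert abs(expr.to_numpy().std() - 1.0) < 0.05

    def test_clinical_schema_and_covariate_ranges(self):
        _, clin = simulate_cohort(SimulationConfig(n_samples=100, n_genes=5, seed=4))
        assert {"time", "event", "age", "gs", "t_category", "ipsa", "therapy"} <= set(clin.columns)
        assert clin["time"].min() >= 0
        assert set(clin["event"]) <= {0, 1}
        assert clin["gs"].between(8, 10).all()
        assert clin["age"].between(44, 78).all()
        assert clin["t_category"].isin([2, 3, 4]).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_samples": 1},
            {"baseline_hazard": 0.0},
            {"censoring_rate": -0.1},
            {"planted": (PlantedEffect(0, 1.0, 2.0), PlantedEffect(0, 0.5, 2.0))},
            {"planted": (PlantedEffect(99, 1.0, 2.0),), "n_genes": 10},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**{"n_samples": 50, "n_genes": 100, **kwargs})

    def test_invalid_planted_hr_rejected(self):
        with pytest.raises(ValueError):
            PlantedEffect(0, 1.0, -2.0)

    def test_planted_hr_recovered_by_cox_on_true_split(self):
        """Monte-Carlo: Cox on the known true dichotomy recovers HR 3 within 15%."""
        hrs = []
        for r in range(100):
            rg = np.random.default_rng(50_000 + r)
            x = rg.standard_normal(400)
            t, e = simulate_survival_for_marker(x, 1.0, 3.0, seed=60_000 + r)
            fit = cox_fit((x > 1.0).astype(float)[:, None], t, e)
            hrs.append(fit.hr[0])
        assert abs(np.median(hrs) - 3.0) <= 0.45

    def test_correlated_block_induces_correlation(self):
        cfg = SimulationConfig(n_samples=400, n_genes=6, seed=9,
                               correlated_block=((0, 1, 2), 0.8))
        expr, _ = simulate_cohort(cfg)
        r = np.corrcoef(expr.iloc[0], expr.iloc[1])[0, 1]
        assert r > 0.4

    def test_confounder_couples_gene_and_covariate(self):
        cfg = SimulationConfig(n_samples=400, n_genes=4, seed=10,
                               confounder=(0, "gs", 0.7))
        expr, clin = simulate_cohort(cfg)
        r = np.corrcoef(expr.iloc[0], clin["gs"].astype(float))[0, 1]
        assert r > 0.4

    def test_hscore_cohort_in_range(self):
        h, t, e = simulate_hscore_cohort(n_samples=107, seed=5)
        assert h.shape == (107,)
        assert (h >= 0).all() and (h <= 300).all()
        assert set(np.unique(e)) <= {0, 1}


class TestIhcFields:
    def test_counts_conserved_exactly(self):
        fields = simulate_ihc_fields(3, 200, (0.25, 0.25, 0.25, 0.25), seed=1)
        assert fields.shape == (3, 4)
        assert (fields.sum(axis=1) == 200).all()

    def test_degenerate_probs_all_negative(self):
        fields = simulate_ihc_fields(5, 150, (1, 0, 0, 0), seed=2)
        assert (fields[:, 0] == 150).all()
        assert (fields[:, 1:] == 0).all()

    def test_multinomial_expectation(self):
        fields = simulate_ihc_fields(1000, 200, (0.25, 0.25, 0.25, 0.25), seed=3)
        assert np.all(np.abs(fields.mean(axis=0) - 50.0) <= 3.0)

    def test_bad_probs_rejected(self):
        with pytest.raises(ValueError):
            simulate_ihc_fields(3, 200, (0.5, 0.5, 0.5, 0.5), seed=0)
        with pytest.raises(ValueError):
            simulate_ihc_fields(3, 0, (0.25, 0.25, 0.25, 0.25), seed=0)


class TestRecurrenceFromPsa:
    def test_rp_rule_first_rising_above_threshold(self):
        assert recurrence_from_psa([(3, 0.10), (6, 0.25), (9, 0.30)], "RP") == (6, 1)

    def test_rt_rule_nadir_plus_two(self):
        assert recurrence_from_psa([(6, 1.0), (12, 2.0), (18, 3.1)], "RT", nadir=0.5) == (18, 1)

    def test_censored_when_criterion_never_met(self):
        assert recurrence_from_psa([(3, 0.05), (6, 0.04)], "RP") == (6, 0)

    def test_ht_requires_castrate_testosterone(self):
        series = [(3, 1.0), (6, 2.0)]
        assert recurrence_from_psa(series, "HT", testosterone=30.0) == (6, 1)
        assert recurrence_from_psa(series, "HT", testosterone=120.0) == (6, 0)

    def test_first_measurement_cannot_be_rising(self):
        # PSA already above 0.2 at first visit but never rising afterwards
        assert recurrence_from_psa([(3, 5.0), (6, 4.0)], "RP") == (6, 0)

    def test_validation_errors(self):
        with pytest.raises(ValueError, match="ordered"):
            recurrence_from_psa([(6, 0.1), (3, 0.2)], "RP")
        with pytest.raises(ValueError, match="nadir"):
            recurrence_from_psa([(3, 1.0)], "RT")
        with pytest.raises(ValueError, match="testosterone"):
            recurrence_from_psa([(3, 1.0)], "HT")
        with pytest.raises(ValueError):
            recurrence_from_psa([], "RP")

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 30.0), min_size=1, max_size=8, unique=True),
           st.data())
    def test_event_time_is_an_observed_visit(self, times, data):
        times = sorted(times)
        psa = [(t, data.draw(st.floats(0.0, 10.0))) for t in times]
        t, ev = recurrence_from_psa(psa, "RP")
        assert t in times
        if ev == 0:
            assert t == times[-1]


def test_covariate_spec_therapy_mix():
    spec = CovariateSpec(therapy_probs=(0.2, 0.4, 0.4))
    df = spec.sample(500, np.random.default_rng(0))
    assert set(df["therapy"]) == {"RP", "RT", "HT"}
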