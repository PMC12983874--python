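import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vacalib import (
    AccuracyPull,
    PairedCauseCounts,
    ScenarioConfig,
    ValidationError,
    accuracy_pull_to_matrix,
    cause_map_preset,
    fit_country_specific,
    fit_homogeneous,
    sample_other_country,
    simulate_scenario,
)
from .conftest import fast_fit_settings


class TestAccuracyPullMechanism:
    def test_perfect_accuracy_gives_identity(self):
        ap = AccuracyPull(np.ones(4), np.full(4, 0.25))
        np.testing.assert_allclose(accuracy_pull_to_matrix(ap).values,
                                   np.eye(4))

    def test_no_accuracy_uniform_pull_gives_one_sixth_everywhere(self):
        # an algorithm with no cause preference has a uniform pull of 1/6
        # over the six neonatal causes
        cm = cause_map_preset("neonate6")
        ap = AccuracyPull(np.zeros(6), np.full(6, 1 / 6))
        np.testing.assert_allclose(accuracy_pull_to_matrix(ap, cm).values,
                                   np.full((6, 6), 1 / 6))

    def test_symmetric_half_half_case(self):
        ap = AccuracyPull([0.5, 0.5], [0.5, 0.5])
        np.testing.assert_allclose(accuracy_pull_to_matrix(ap).values,
                                   [[0.75, 0.25], [0.25, 0.75]])

    @given(raw_a=st.lists(st.floats(0, 1), min_size=3, max_size=3),
           raw_b=st.lists(st.floats(0.01, 10), min_size=3, max_size=3))
    @settings(max_examples=60, derandomize=True)
    def test_rows_sum_to_one_for_any_mechanism(self, raw_a, raw_b):
        b = np.asarray(raw_b) / np.sum(raw_b)
        b = b / b.sum()  # exact simplex
        for param in ("pull_on_true", "pull_off_diagonal"):
            m = accuracy_pull_to_matrix(AccuracyPull(raw_a, b),
                                        parameterization=param)
            np.testing.assert_allclose(m.values.sum(axis=1), 1.0, atol=1e-9)

    def test_increasing_accuracy_raises_sensitivity_lowers_off_diagonal(self):
        b = np.array([0.5, 0.3, 0.2])
        lo = accuracy_pull_to_matrix(AccuracyPull([0.3, 0.5, 0.5], b)).values
        hi = accuracy_pull_to_matrix(AccuracyPull([0.7, 0.5, 0.5], b)).values
        assert hi[0, 0] > lo[0, 0]
        assert (hi[0, 1:] <= lo[0, 1:]).all()
        np.testing.assert_allclose(hi[1:], lo[1:])  # other rows untouched

    def test_pull_on_true_sensitivity_exceeds_intrinsic_accuracy(self):
        ap = AccuracyPull([0.4, 0.4], [0.6, 0.4])
        m = accuracy_pull_to_matrix(ap)
        assert m.values[0, 0] == pytest.approx(0.4 + 0.6 * 0.6)

    def test_invalid_mechanism_rejected(self):
        with pytest.raises(ValidationError):
            AccuracyPull([1.2, 0.5], [0.5, 0.5])
        with pytest.raises(ValidationError):
            AccuracyPull([0.5, 0.5], [0.7, 0.7])


class TestHomogeneousFit:
    @pytest.fixture(scope="class")
    def fit(self, paired_2x2):
        return fit_homogeneous(paired_2x2, fast_fit_settings(3))

    def test_posterior_mean_matches_row_proportion_oracle(self, fit):
        # with 1000 deaths per row the posterior concentrates on the
        # observed row proportions
        np.testing.assert_allclose(fit.pooled_mean().values,
                                   [[0.9, 0.1], [0.3, 0.7]], atol=0.02)

    def test_same_seed_reproduces_draws(self, paired_2x2, fit):
        again = fit_homogeneous(paired_2x2, fast_fit_settings(3))
        np.testing.assert_array_equal(fit.pooled_draws, again.pooled_draws)

    def test_country_draws_replicate_pooled(self, fit):
        np.testing.assert_array_equal(fit.country_draws[:, 0],
                                      fit.pooled_draws)

    def test_diagnostics_populated(self, fit):
        assert fit.diagnostics["max_rhat"] > 0
        assert fit.diagnostics["min_ess"] > 0

    def test_diagonal_counts_give_high_sensitivities(self, cm3):
        data = PairedCauseCounts(cm3, ("x",), (np.eye(3, dtype=int) * 500)[None])
        post = fit_homogeneous(data, fast_fit_settings(4))
        assert (post.pooled_mean().sensitivities >= 0.95).all()

    def test_empty_data_rejected(self, cm2):
        data = PairedCauseCounts(cm2, ("x",), np.zeros((1, 2, 2), dtype=int))
        with pytest.raises(ValidationError):
            fit_homogeneous(data, fast_fit_settings(5))


@pytest.fixture(scope="module")
def null_fit():
    """Fit on data simulated with zero cross-country heterogeneity."""
    cfg = ScenarioConfig(cause_map="custom3", n_countries=3,
                         n_per_row=500, heterogeneity=0.0, seed=21)
    truth = simulate_scenario(cfg)
    post = fit_country_specific(truth.paired[0], fast_fit_settings(7))
    return truth, post


class TestCountrySpecificFit:
    def test_null_heterogeneity_shrinks_countries_to_pooled(self, null_fit):
        _, post = null_fit
        diff = np.abs(post.means_by_country()
                      - post.pooled_mean().values[None])
        assert diff.max() <= 0.05

    def test_recovers_heterogeneous_truth(self):
        cfg = ScenarioConfig(cause_map="custom3", n_countries=3,
                             n_per_row=500, heterogeneity=1.0, seed=31)
        truth = simulate_scenario(cfg)
        post = fit_country_specific(truth.paired[0], fast_fit_settings(8))
        mae = np.abs(post.means_by_country() - truth.matrices[0]).mean()
        assert mae <= 0.05

    def test_zero_data_country_equals_other_country_predictive(self):
        n = np.array([[400] * 3, [400] * 3, [0] * 3])
        cfg = ScenarioConfig(cause_map="custom3", n_countries=3, n_per_row=n,
                             heterogeneity=0.3, seed=32)
        truth = simulate_scenario(cfg)
        post = fit_country_specific(truth.paired[0], fast_fit_settings(9))
        zero_mean = post.means_by_country()[2]
        other = np.mean([m.values for m in
                         sample_other_country(post, 4000, seed=1)], axis=0)
        assert np.abs(zero_mean - other).max() <= 0.05

    def test_same_seed_reproduces_draws(self, null_fit):
        truth, post = null_fit
        again = fit_country_specific(truth.paired[0], fast_fit_settings(7))
        np.testing.assert_array_equal(post.country_draws, again.country_draws)


class TestOtherCountryPredictive:
    def test_mean_centred_on_pooled(self, null_fit):
        _, post = null_fit
        other = np.mean([m.values for m in
                         sample_other_country(post, 3000, seed=2)], axis=0)
        assert np.abs(other - post.pooled_mean().values).max() <= 0.03

    def test_fixed_seed_gives_identical_sequences(self, null_fit):
        _, post = null_fit
        a = sample_other_country(post, 50, seed=5)
        b = sample_other_country(post, 50, seed=5)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.values, mb.values)

    def test_spread_nondecreasing_in_heterogeneity(self, null_fit):
        _, post = null_fit
        cfg = ScenarioConfig(cause_map="custom3", n_countries=3,
                             n_per_row=500, heterogeneity=1.5, seed=21)
        truth = simulate_scenario(cfg)
        het = fit_country_specific(truth.paired[0], fast_fit_settings(7))
        sd_null = post.other_draws.std(axis=0).mean()
        sd_het = het.other_draws.std(axis=0).mean()
        assert sd_het >= sd_null

    def test_homogeneous_fit_falls_back_to_pooled_with_warning(
            self, paired_2x2):
        post = fit_homogeneous(paired_2x2, fast_fit_settings(3))
        with pytest.warns(UserWarning, match="homogeneous"):
            draws = sample_other_country(post, 20, seed=3)
        assert len(draws) == 20
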