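import numpy as np
import pytest

from vacalib import (
    CalibrationSettings,
    MisclassPrior,
    ScenarioConfig,
    ValidationError,
    VAOnlyCounts,
    build_informative_prior,
    calibrate_ensemble,
    calibrate_single,
    make_cause_map,
    simulate_scenario,
)
from vacalib.core import MisclassMatrix


def quick(seed, **kw):
    defaults = dict(n_iter=3000, n_burn=1000)
    defaults.update(kw)
    return CalibrationSettings(seed=seed, **defaults)


class TestBuildInformativePrior:
    def test_moment_matching_recovers_known_dirichlet(self, cm3):
        rng = np.random.default_rng(0)
        draws = rng.dirichlet([2, 3, 5], size=(5000, 3))
        prior = build_informative_prior(draws, "dirichlet_rows",
                                        cause_map=cm3)
        a0 = prior.alphas.sum(axis=1)
        np.testing.assert_allclose(a0, 10.0, rtol=0.15)
        np.testing.assert_allclose(prior.mean_matrix(),
                                   np.tile([0.2, 0.3, 0.5], (3, 1)),
                                   atol=0.02)

    def test_identical_draws_cap_concentration_with_warning(self, cm2):
        m = np.array([[0.7, 0.3], [0.4, 0.6]])
        with pytest.warns(UserWarning, match="zero-variance"):
            prior = build_informative_prior(np.stack([m, m]),
                                            "dirichlet_rows", cause_map=cm2)
        np.testing.assert_allclose(prior.alphas.sum(axis=1), 1e6, rtol=1e-3)
        np.testing.assert_allclose(prior.mean_matrix(), m, atol=1e-3)

    def test_point_mass_from_single_draw_is_that_matrix(self, cm2):
        m = MisclassMatrix(cm2, [[0.8, 0.2], [0.3, 0.7]])
        prior = build_informative_prior([m], "point_mass")
        np.testing.assert_array_equal(prior.matrix, m.values)

    def test_other_category_removed_before_packaging(self, cm3_other):
        m = MisclassMatrix(cm3_other, [[0.5, 0.3, 0.2],
                                       [0.1, 0.7, 0.2],
                                       [0.3, 0.3, 0.4]])
        prior = build_informative_prior([m], "point_mass")
        assert prior.cause_map.labels == ("a", "b")
        np.testing.assert_allclose(prior.matrix[0], [0.625, 0.375])

    def test_moment_matching_needs_two_draws(self, cm2):
        with pytest.raises(ValidationError):
            build_informative_prior(np.eye(2)[None], "dirichlet_rows",
                                    cause_map=cm2)


class TestCalibrateSingle:
    def test_identity_matrix_reduces_to_conjugate_posterior(self, cm2):
        # with perfect classification the model is Dirichlet-multinomial:
        # posterior mean (1+30, 1+70)/102
        prior = MisclassPrior(cm2, "point_mass", matrix=np.eye(2))
        res = calibrate_single(VAOnlyCounts(cm2, "a", [30, 70]), prior,
                               quick(1, n_iter=6000, n_burn=1000))
        np.testing.assert_allclose(res.calibrated.mean, [31 / 102, 71 / 102],
                                   atol=0.01)

    def test_point_mass_inversion_recovers_linear_solve(self, cm2):
        phi = np.array([[0.8, 0.2], [0.3, 0.7]])
        prior = MisclassPrior(cm2, "point_mass", matrix=phi)
        res = calibrate_single(VAOnlyCounts(cm2, "a", [7000, 3000]), prior,
                               quick(2))
        # oracle: p = (Phi^T)^-1 q with q = (0.7, 0.3)
        oracle = np.linalg.solve(phi.T, [0.7, 0.3])
        np.testing.assert_allclose(res.calibrated.mean, oracle, atol=0.02)

    def test_symmetric_problem_gives_symmetric_posterior(self, cm2):
        phi = np.array([[0.7, 0.3], [0.3, 0.7]])
        prior = MisclassPrior(cm2, "point_mass", matrix=phi)
        res = calibrate_single(VAOnlyCounts(cm2, "a", [4000, 4000]), prior,
                               quick(3))
        assert abs(res.calibrated.mean[0] - 0.5) < 0.02

    def test_self_consistency_recovers_true_csmf(self, cm3):
        phi = np.array([[0.7, 0.2, 0.1], [0.15, 0.7, 0.15], [0.1, 0.25, 0.65]])
        p_true = np.array([0.5, 0.3, 0.2])
        rng = np.random.default_rng(7)
        x = rng.multinomial(5000, phi.T @ p_true)
        prior = MisclassPrior(cm3, "point_mass", matrix=phi)
        res = calibrate_single(VAOnlyCounts(cm3, "a", x), prior, quick(4))
        assert np.abs(res.calibrated.mean - p_true).mean() <= 0.03

    def test_widening_with_nondegenerate_prior(self):
        cfg = ScenarioConfig(seed=42)  # default synthetic scenario
        truth = simulate_scenario(cfg)
        rng = np.random.default_rng(11)
        draws = np.stack([
            np.stack([rng.dirichlet(80 * truth.matrices[0, 0, i])
                      for i in range(4)])
            for _ in range(500)])
        prior = build_informative_prior(draws, "dirichlet_rows",
                                        cause_map=cfg.cause_map)
        res = calibrate_single(truth.va_only[0], prior, quick(5))
        w_cal = res.calibrated.upper95 - res.calibrated.lower95
        w_unc = res.uncalibrated.upper95 - res.uncalibrated.lower95
        assert (w_cal >= w_unc).all()

    def test_draw_resampling_prior_targets_same_truth(self, cm2):
        phi = np.array([[0.75, 0.25], [0.2, 0.8]])
        rng = np.random.default_rng(3)
        draws = np.stack([np.stack([rng.dirichlet(300 * phi[i])
                                    for i in range(2)]) for _ in range(400)])
        p_true = np.array([0.6, 0.4])
        x = rng.multinomial(4000, phi.T @ p_true)
        prior = build_informative_prior(draws, "draw_resampling",
                                        cause_map=cm2)
        res = calibrate_single(VAOnlyCounts(cm2, "a", x), prior,
                               quick(6, n_iter=6000, n_burn=1500))
        assert np.abs(res.calibrated.mean - p_true).max() <= 0.05

    def test_permutation_equivariance(self, cm2):
        phi = np.array([[0.8, 0.2], [0.3, 0.7]])
        x = np.array([600, 400])
        res = calibrate_single(
            VAOnlyCounts(cm2, "a", x),
            MisclassPrior(cm2, "point_mass", matrix=phi), quick(8))
        cm_rev = make_cause_map(["cause_2", "cause_1"])
        res_rev = calibrate_single(
            VAOnlyCounts(cm_rev, "a", x[::-1]),
            MisclassPrior(cm_rev, "point_mass", matrix=phi[::-1, ::-1]),
            quick(8))
        np.testing.assert_allclose(res.calibrated.mean,
                                   res_rev.calibrated.mean[::-1], atol=0.02)

    def test_singular_point_mass_rejected(self, cm2):
        singular = np.array([[0.5, 0.5], [0.5, 0.5]])
        with pytest.raises(ValidationError, match="singular"):
            calibrate_single(VAOnlyCounts(cm2, "a", [10, 10]),
                             MisclassPrior(cm2, "point_mass",
                                           matrix=singular), quick(9))

    def test_zero_counts_rejected(self, cm2):
        prior = MisclassPrior(cm2, "point_mass", matrix=np.eye(2))
        with pytest.raises(ValidationError):
            calibrate_single(VAOnlyCounts(cm2, "a", [0, 0]), prior, quick(10))

    def test_cause_map_mismatch_rejected(self, cm2, cm3):
        prior = MisclassPrior(cm3, "point_mass", matrix=np.eye(3))
        with pytest.raises(ValidationError, match="align"):
            calibrate_single(VAOnlyCounts(cm2, "a", [5, 5]), prior, quick(11))

    def test_va_other_deaths_excluded_before_calibration(self, cm3_other):
        reduced = cm3_other.without_other()
        prior = MisclassPrior(reduced, "point_mass", matrix=np.eye(2))
        res = calibrate_single(VAOnlyCounts(cm3_other, "a", [30, 50, 20]),
                               prior, quick(12))
        assert res.cause_map.labels == ("a", "b")
        np.testing.assert_allclose(res.uncalibrated.mean, [30 / 80, 50 / 80])


class TestCalibrateEnsemble:
    def test_single_algorithm_reduces_to_calibrate_single(self, cm2):
        phi = np.array([[0.8, 0.2], [0.3, 0.7]])
        prior = MisclassPrior(cm2, "point_mass", matrix=phi)
        va = VAOnlyCounts(cm2, "a", [650, 350])
        one = calibrate_single(va, prior, quick(13))
        ens = calibrate_ensemble([va], [prior], quick(13))
        np.testing.assert_allclose(one.calibrated.mean, ens.calibrated.mean,
                                   atol=1e-12)

    def test_replicated_algorithms_tighten_the_interval(self, cm2):
        phi = np.array([[0.8, 0.2], [0.3, 0.7]])
        prior = MisclassPrior(cm2, "point_mass", matrix=phi)
        va = VAOnlyCounts(cm2, "a", [650, 350])
        one = calibrate_single(va, prior, quick(14))
        three = calibrate_ensemble([va] * 3, [prior] * 3, quick(14))
        np.testing.assert_allclose(three.calibrated.mean, one.calibrated.mean,
                                   atol=0.02)
        w1 = one.calibrated.upper95 - one.calibrated.lower95
        w3 = three.calibrated.upper95 - three.calibrated.lower95
        assert (w3 <= w1 + 0.005).all()

    def test_ensemble_mean_between_disagreeing_algorithms(self, cm2):
        # two point-mass priors whose separate inversions give p = (0.8, 0.2)
        # and p = (0.6, 0.4); the joint posterior must land in between
        phi1 = np.array([[0.8, 0.2], [0.3, 0.7]])
        phi2 = np.array([[0.9, 0.1], [0.2, 0.8]])
        q1 = phi1.T @ np.array([0.8, 0.2])
        q2 = phi2.T @ np.array([0.6, 0.4])
        n = 4000
        va1 = VAOnlyCounts(cm2, "a1", np.round(q1 * n).astype(int))
        va2 = VAOnlyCounts(cm2, "a2", np.round(q2 * n).astype(int))
        res = calibrate_ensemble(
            [va1, va2],
            [MisclassPrior(cm2, "point_mass", matrix=phi1),
             MisclassPrior(cm2, "point_mass", matrix=phi2)], quick(15))
        assert 0.6 < res.calibrated.mean[0] < 0.8

    def test_mismatched_cause_maps_rejected(self, cm2, cm3):
        with pytest.raises(ValidationError):
            calibrate_ensemble(
                [VAOnlyCounts(cm2, "a", [5, 5]),
                 VAOnlyCounts(cm3, "b", [5, 5, 5])],
                [MisclassPrior(cm2, "point_mass", matrix=np.eye(2)),
                 MisclassPrior(cm3, "point_mass", matrix=np.eye(3))],
                quick(16))
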