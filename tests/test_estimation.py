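"""Likelihood, MAP-Bayesian estimation, population fit, and diagnostics."""

import math

import numpy as np
import pytest

from meropk import datasets, pk_core
from meropk.estimation import (
    ErrorModel,
    Observation,
    PopulationModel,
    SubjectData,
    _em_weights,
    bias_imprecision,
    map_estimate,
    npag_fit,
    npde,
    obs_pred_regression,
    subject_loglik,
    vpc,
)
from meropk.exceptions import InputError


@pytest.fixture()
def toy_subject(median_params, ci_1g):
    """Three plasma observations exactly on the model's predictions."""
    times = np.array([49.5, 51.0, 54.0])
    prof = pk_core.solve_profile(median_params, ci_1g, times)
    return SubjectData(
        "toy", ci_1g, times, np.array(["plasma"] * 3, dtype=object), prof.c_plasma
    )


class TestSubjectLoglik:
    def test_zero_residuals_equal_normalization_term(self, median_params, toy_subject):
        error = ErrorModel()
        ll = subject_loglik(median_params, toy_subject, error=error)
        sds = error.sd("plasma", toy_subject.values)
        expected = -sum(math.log(math.sqrt(2 * math.pi) * sd) for sd in sds)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_doubling_gamma_lowers_zero_residual_loglik(self, median_params, toy_subject):
        ll1 = subject_loglik(median_params, toy_subject, error=ErrorModel(gamma=1.0))
        ll2 = subject_loglik(median_params, toy_subject, error=ErrorModel(gamma=2.0))
        assert ll2 < ll1

    def test_matches_brute_force_density_sum(self, median_params, ci_1g):
        # independent oracle: per-observation normal log-density, hand-summed
        times = np.array([49.5, 51.0, 54.0])
        prof = pk_core.solve_profile(median_params, ci_1g, times)
        obs_values = prof.c_plasma + np.array([0.5, -0.3, 1.1])
        subject = SubjectData(
            "x", ci_1g, times, np.array(["plasma"] * 3, dtype=object), obs_values
        )
        gamma = 1.7
        ll = subject_loglik(median_params, subject, error=ErrorModel(gamma=gamma))
        expected = 0.0
        for pred, obs in zip(prof.c_plasma, obs_values):
            sd = gamma * (0.25 + 0.15 * pred)
            expected += (
                -0.5 * math.log(2 * math.pi)
                - math.log(sd)
                - (obs - pred) ** 2 / (2 * sd**2)
            )
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_censored_observations_rejected(self, median_params, ci_1g):
        obs = [Observation("s", 49.5, "plasma", 10.0, bloq=True)]
        with pytest.raises(InputError):
            subject_loglik(median_params, obs, ci_1g)


class TestMapEstimate:
    def test_single_support_point(self, median_params, toy_subject):
        prior = PopulationModel(median_params.as_array()[None, :], np.array([1.0]))
        best, weights = map_estimate(prior, toy_subject)
        assert weights == pytest.approx([1.0])
        assert best.CL == median_params.CL

    def test_posterior_matches_hand_bayes_arithmetic(self, median_params, toy_subject):
        other = median_params.as_array() * 1.5
        prior = PopulationModel(
            np.vstack([median_params.as_array(), other]), np.array([0.3, 0.7])
        )
        _, weights = map_estimate(prior, toy_subject)
        ll0 = subject_loglik(median_params, toy_subject)
        ll1 = subject_loglik(pk_core.StructuralParams.from_array(other), toy_subject)
        post = np.array([0.3 * math.exp(ll0 - ll0), 0.7 * math.exp(ll1 - ll0)])
        post /= post.sum()
        assert weights == pytest.approx(post, abs=1e-12)

    def test_implausible_point_gets_no_weight(self, median_params, toy_subject):
        absurd = median_params.as_array() * 40.0
        prior = PopulationModel(
            np.vstack([median_params.as_array(), absurd]), np.array([0.5, 0.5])
        )
        best, weights = map_estimate(prior, toy_subject)
        assert weights[0] == pytest.approx(1.0, abs=1e-9)
        assert best.CL == pytest.approx(median_params.CL)


class TestDiagnosticsFormulas:
    def test_identical_vectors(self):
        assert bias_imprecision(np.arange(5.0), np.arange(5.0)) == (0.0, 0.0)

    def test_constant_shift_is_pure_bias(self):
        bias, imprecision = bias_imprecision(np.array([1.0, 2, 3]), np.array([2.0, 3, 4]))
        assert bias == pytest.approx(1.0)
        assert imprecision == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        obs, pred = rng.normal(10, 2, 50), rng.normal(10, 2, 50)
        bias, imprecision = bias_imprecision(obs, pred)
        e = pred - obs
        assert bias == pytest.approx(e.mean(), abs=1e-12)
        assert imprecision == pytest.approx((e**2).mean() - e.mean() ** 2, abs=1e-12)

    def test_regression_identity_and_scaling(self):
        x = np.array([1.0, 2, 3, 4])
        assert obs_pred_regression(x, x) == pytest.approx((0.0, 1.0, 1.0))
        intercept, slope, r2 = obs_pred_regression(2 * x, x)
        assert (intercept, slope, r2) == pytest.approx((0.0, 2.0, 1.0))

    def test_regression_matches_normal_equations(self):
        rng = np.random.default_rng(1)
        pred = rng.uniform(1, 20, 30)
        obs = 0.4 + 1.1 * pred + rng.normal(0, 0.5, 30)
        intercept, slope, r2 = obs_pred_regression(obs, pred)
        X = np.column_stack([np.ones_like(pred), pred])
        beta = np.linalg.solve(X.T @ X, X.T @ obs)
        resid = obs - X @ beta
        r2_direct = 1 - (resid**2).sum() / ((obs - obs.mean()) ** 2).sum()
        assert intercept == pytest.approx(beta[0], abs=1e-12)
        assert slope == pytest.approx(beta[1], abs=1e-12)
        assert r2 == pytest.approx(r2_direct, abs=1e-12)

    def test_degenerate_predictions_rejected(self):
        with pytest.raises(InputError):
            obs_pred_regression(np.array([1.0, 2, 3]), np.array([2.0, 2, 2]))


class TestEmWeights:
    def test_em_is_monotone_in_loglik(self):
        rng = np.random.default_rng(3)
        logL = rng.normal(-20, 4, size=(12, 30))
        w0 = np.full(30, 1 / 30)
        _, _, trace = _em_weights(logL, w0)
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))


class TestNpagFit:
    def test_collapsed_bounds_reproduce_subject_loglik(self, median_params, rich_subjects):
        point = median_params.as_array()
        bounds = np.column_stack([point, point])
        model = npag_fit(
            rich_subjects, bounds=bounds, seed=1, n_init=4, max_cycles=2,
            optimize_gamma=False,
        )
        direct = sum(subject_loglik(median_params, s) for s in rich_subjects)
        assert len(model.weights) == 1
        assert model.loglik == pytest.approx(direct, abs=1e-8)

    def test_cycle_logliks_never_decrease(self, rich_subjects):
        model = npag_fit(rich_subjects, seed=2, n_init=64, max_cycles=3)
        lls = model.cycle_logliks
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_noise_free_recovery_of_identified_functionals(self, median_params, rich_subjects):
        """With exact data the fit concentrates on one prediction-equivalent point.

        The full 7-parameter vector is only set-identified from these samples,
        so the assertion targets the identified quantities: clearance, the
        steady-state ELF penetration ratio, and the fitted predictions.
        """
        error = ErrorModel(assay_sd={"plasma": (0.5, 0.0), "elf": (0.1, 0.0)})
        model = npag_fit(
            rich_subjects, error=error, seed=5, n_init=128, max_cycles=6,
            optimize_gamma=False,
        )
        k = int(np.argmax(model.weights))
        assert model.weights[k] > 0.95
        fitted = pk_core.StructuralParams.from_array(model.support[k])
        assert fitted.CL == pytest.approx(median_params.CL, rel=0.01)
        assert pk_core.steady_state_penetration(fitted) == pytest.approx(
            pk_core.steady_state_penetration(median_params), rel=0.01
        )
        for subj in rich_subjects:
            prof = pk_core.solve_profile(fitted, subj.schedule, np.unique(subj.times))
            truth = pk_core.solve_profile(median_params, subj.schedule, np.unique(subj.times))
            assert np.allclose(prof.c_plasma, truth.c_plasma, rtol=0.02, atol=0.05)

    def test_requires_two_subjects(self, rich_subjects):
        with pytest.raises(InputError):
            npag_fit(rich_subjects[:1], seed=0)


class TestVpc:
    def test_zero_variance_model_bands_collapse(self, median_params, ci_2g):
        model = PopulationModel(median_params.as_array()[None, :], np.array([1.0]))
        grid = pk_core.default_grid(72.0, step=1.0)
        bands = vpc(model, ci_2g, grid, n_sim=100, seed=0, error=None)
        prof = pk_core.solve_profile(median_params, ci_2g, grid)
        assert np.allclose(bands.p5, prof.c_plasma)
        assert np.allclose(bands.p50, prof.c_plasma)
        assert np.allclose(bands.p95, prof.c_plasma)

    def test_bands_are_nested(self, median_params, ci_2g):
        support = np.vstack([median_params.as_array() * f for f in (0.7, 1.0, 1.4)])
        model = PopulationModel(support, np.array([0.3, 0.4, 0.3]))
        grid = pk_core.default_grid(72.0, step=1.0)
        bands = vpc(model, ci_2g, grid, n_sim=200, seed=1, error=ErrorModel())
        assert np.all(bands.p5 <= bands.p50 + 1e-12)
        assert np.all(bands.p50 <= bands.p95 + 1e-12)


class TestNpde:
    def _population(self, median_params):
        rng = np.random.default_rng(10)
        support = median_params.as_array() * np.exp(
            0.3 * rng.standard_normal((8, 7))
        )
        w = rng.dirichlet(np.ones(8))
        return PopulationModel(support, w)

    def test_observation_at_simulation_median_maps_to_zero(self, median_params, ci_1g):
        model = PopulationModel(median_params.as_array()[None, :], np.array([1.0]))
        error = ErrorModel()
        times = np.array([49.5])
        prof = pk_core.solve_profile(median_params, ci_1g, times)
        subject = SubjectData(
            "s", ci_1g, times, np.array(["plasma"], dtype=object), prof.c_plasma
        )
        values = npde(model, [subject], n_sim=2000, seed=3, error=error)
        assert abs(values[0]) < 0.1  # observation equals the predictive median

    def test_extreme_observation_stays_finite(self, median_params, ci_1g):
        model = PopulationModel(median_params.as_array()[None, :], np.array([1.0]))
        subject = SubjectData(
            "s", ci_1g, np.array([49.5]), np.array(["plasma"], dtype=object), np.array([0.0])
        )
        values = npde(model, [subject], n_sim=500, seed=4, error=ErrorModel())
        assert np.isfinite(values[0])
        assert values[0] < -2.5  # at the floor quantile

    def test_null_distribution_is_standard_normal(self, median_params, ci_1g, ci_2g):
        """Observations simulated from the model itself give NPDE ~ N(0, 1)."""
        model = self._population(median_params)
        error = ErrorModel()
        rng = np.random.default_rng(11)
        times = np.array([48.0, 49.5, 51.0, 54.0, 56.0])
        subjects = []
        for i in range(40):
            sched = ci_1g if i % 2 else ci_2g
            theta = model.sample(1, rng)[0]
            prof = pk_core.solve_amounts(theta[None, :], sched, times)[0]
            cp = prof[:, 0] / theta[1]
            noisy = cp + error.sd("plasma", cp) * rng.standard_normal(len(cp))
            subjects.append(
                SubjectData(
                    f"s{i}", sched, times,
                    np.array(["plasma"] * len(times), dtype=object),
                    np.clip(noisy, 0.0, None),
                )
            )
        values = npde(model, subjects, n_sim=1000, seed=12, error=error)
        # cluster-robust bounds: within-subject NPDEs are correlated because
        # the decorrelation step is deliberately omitted
        per_subject = values.reshape(len(subjects), -1)
        J = len(subjects)
        se_mean = per_subject.mean(axis=1).std(ddof=1) / math.sqrt(J)
        assert abs(values.mean()) < 3.0 * se_mean
        sq = (per_subject**2).mean(axis=1)
        se_var = sq.std(ddof=1) / math.sqrt(J)
        assert abs(values.var() - 1.0) < 3.0 * se_var
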