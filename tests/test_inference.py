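"""Variational inference contracts: exactness for the linear-Gaussian case,
bound properties, damping behavior, parameter recovery, forecasting."""

import numpy as np
import pytest

from pwlds.inference import (
    elbo,
    filter_trial,
    fit_model,
    infer_posterior,
    predict_forward,
)
from pwlds.model import (
    EmissionMap,
    InitialState,
    LinearMode,
    PWLModel,
    RecurrentTransition,
    simulate,
)


def _make_lds(rng, H=2, N=4, q=0.05, s=0.1):
    A = 0.85 * np.eye(H) + 0.05 * rng.standard_normal((H, H))
    b = 0.1 * rng.standard_normal(H)
    C = rng.standard_normal((N, H))
    d = 0.2 * rng.standard_normal(N)
    return PWLModel([LinearMode(A, b, q * np.eye(H))], None,
                    EmissionMap(C, d, "gaussian", s * np.eye(N)),
                    InitialState(np.zeros(H), np.eye(H), [1.0]))


def _kalman_loglik(model, y):
    """Textbook Kalman-filter log-likelihood oracle (independent of the
    package's chain smoother)."""
    A, b, Q = model.modes[0].A, model.modes[0].b, model.modes[0].Q
    C, d, S = model.emission.C, model.emission.d, model.emission.S
    m, P = model.initial.mean.copy(), model.initial.cov.copy()
    N = len(d)
    ll = 0.0
    for t in range(len(y)):
        if t > 0:
            m = A @ m + b
            P = A @ P @ A.T + Q
        Sy = C @ P @ C.T + S
        innov = y[t] - C @ m - d
        ll += -0.5 * (N * np.log(2 * np.pi) + np.linalg.slogdet(Sy)[1]
                      + innov @ np.linalg.solve(Sy, innov))
        K = P @ C.T @ np.linalg.inv(Sy)
        m = m + K @ innov
        P = P - K @ Sy @ K.T
    return ll


@pytest.fixture(scope="module")
def lds_and_trials():
    rng = np.random.default_rng(0)
    model = _make_lds(rng)
    trials = [simulate(model, 30, rng=rng) for _ in range(4)]
    return model, trials


class TestElboExactness:
    def test_k1_gaussian_elbo_equals_kalman_loglik(self, lds_and_trials):
        model, trials = lds_and_trials
        oracle = sum(_kalman_loglik(model, t.observations) for t in trials)
        post = infer_posterior(model, trials, learning_rate=1.0, n_iters=2)
        assert post.elbo == pytest.approx(oracle, abs=1e-6)

    def test_partial_posterior_lower_bounds_loglik(self, lds_and_trials):
        model, trials = lds_and_trials
        oracle = sum(_kalman_loglik(model, t.observations) for t in trials)
        for lr, iters in ((0.1, 1), (0.3, 2), (1.0, 1)):
            post = infer_posterior(model, trials, learning_rate=lr, n_iters=iters)
            assert post.elbo <= oracle + 1e-8

    def test_duplicating_data_doubles_elbo(self, lds_and_trials):
        model, trials = lds_and_trials
        e1 = elbo(model, trials)
        e2 = elbo(model, trials + trials)
        assert e2 == pytest.approx(2 * e1, rel=1e-10)

    def test_filter_loglik_matches_oracle(self, lds_and_trials):
        model, trials = lds_and_trials
        fr = filter_trial(model, trials[0].observations)
        assert fr.loglik == pytest.approx(
            _kalman_loglik(model, trials[0].observations), abs=1e-8)


class TestInferPosterior:
    def test_rows_on_simplex_every_iteration(self, truth, gaussian_emission):
        model = PWLModel(truth.modes, truth.transition, gaussian_emission,
                         truth.initial)
        trials = [simulate(model, 40, rng=s) for s in range(3)]
        for iters in (1, 3, 10):
            post = infer_posterior(model, trials, learning_rate=0.25,
                                   n_iters=iters)
            for qz in post.mode_probs:
                np.testing.assert_allclose(qz.sum(axis=1), 1.0, atol=1e-8)
                assert np.all(qz >= 0)

    def test_learning_rate_one_is_undamped_update(self, lds_and_trials):
        """With lr=1 a single sweep equals the exact smoothing posterior for
        a linear-Gaussian model (no damping left over)."""
        model, trials = lds_and_trials
        p1 = infer_posterior(model, trials, learning_rate=1.0, n_iters=1)
        p2 = infer_posterior(model, trials, learning_rate=1.0, n_iters=5)
        np.testing.assert_allclose(p1.means[0], p2.means[0], atol=1e-10)

    def test_noiseless_posterior_matches_pseudoinverse(self):
        rng = np.random.default_rng(5)
        model = _make_lds(rng, H=2, N=5, q=0.3, s=1e-9)
        trial = simulate(model, 20, rng=rng)
        post = infer_posterior(model, [trial], learning_rate=1.0, n_iters=2)
        C, d = model.emission.C, model.emission.d
        recon = (trial.observations - d) @ np.linalg.pinv(C).T
        np.testing.assert_allclose(post.means[0], recon, atol=1e-6)

    def test_invalid_learning_rate_rejected(self, lds_and_trials):
        model, trials = lds_and_trials
        with pytest.raises(ValueError):
            infer_posterior(model, trials, learning_rate=0.0)


class TestFitModel:
    def test_lds_parameter_recovery_eigenvalues(self):
        """Fitting K=1 to data from a known low-noise LDS recovers the
        eigenvalue spectrum of A."""
        rng = np.random.default_rng(7)
        gen = _make_lds(rng, H=2, N=5, q=0.02, s=0.005)
        trials = [simulate(gen, 40, rng=rng) for _ in range(120)]
        fit, _ = fit_model(trials, K=1, H=2, family="gaussian", rng_seed=0,
                           n_iters=60, learning_rate=1.0)
        ev_true = np.sort_complex(np.linalg.eigvals(gen.modes[0].A))
        ev_fit = np.sort_complex(np.linalg.eigvals(fit.modes[0].A))
        assert np.max(np.abs(ev_true - ev_fit)) < 0.05

    def test_elbo_trace_nondecreasing_gaussian(self, gaussian_dataset):
        trials = list(gaussian_dataset.split("train"))[:40]
        _, trace = fit_model(trials, K=3, H=2, family="gaussian", rng_seed=1,
                             n_iters=25)
        assert np.all(np.diff(trace) > -1e-6)

    def test_elbo_trace_nondecreasing_k1(self, gaussian_dataset):
        trials = list(gaussian_dataset.split("train"))[:30]
        _, trace = fit_model(trials, K=1, H=2, family="gaussian", rng_seed=1,
                             n_iters=25, learning_rate=1.0)
        assert np.all(np.diff(trace) > -1e-6)

    def test_poisson_fit_improves_bound(self, small_poisson_dataset):
        trials = list(small_poisson_dataset.split("train"))[:30]
        _, trace = fit_model(trials, K=1, H=2, family="poisson", rng_seed=0,
                             n_iters=15)
        assert trace[-1] > trace[0]

    def test_negative_counts_rejected(self):
        bad = [np.array([[1, -2], [0, 3]])]
        with pytest.raises(ValueError):
            fit_model(bad, K=1, H=1, family="poisson", rng_seed=0, n_iters=2)


class TestForecasting:
    def test_fixed_point_forecast_is_constant(self):
        A = 0.5 * np.eye(2)
        b = np.array([0.5, 3.0])       # fixed point (1, 6)
        model = PWLModel([LinearMode(A, b, np.zeros((2, 2)))], None,
                         EmissionMap(np.eye(2), np.zeros(2), "gaussian",
                                     1e-12 * np.eye(2)),
                         InitialState(np.array([1.0, 6.0]), np.zeros((2, 2)), [1.0]))
        state = (np.array([1.0, 6.0]), np.zeros((2, 2)), np.array([1.0]))
        lat, obs = predict_forward(model, state, horizon=5, n_samples=20,
                                   rng_seed=0)
        np.testing.assert_allclose(lat, np.tile([1.0, 6.0], (5, 1)), atol=1e-6)

    def test_k1_one_step_forecast_is_linear_prediction(self, lds_and_trials):
        model, trials = lds_and_trials
        fr = filter_trial(model, trials[0].observations)
        m, P, pz = fr.state_at(10)
        lat, obs = predict_forward(model, (m, P, pz), horizon=1,
                                   n_samples=4000, rng_seed=1)
        A, b = model.modes[0].A, model.modes[0].b
        C, d = model.emission.C, model.emission.d
        exact = C @ (A @ m + b) + d
        np.testing.assert_allclose(obs[0], exact, atol=0.05)
        # the deterministic rollout is exact
        lat_m, obs_m = predict_forward(model, (m, P, pz), horizon=1,
                                       method="mode")
        np.testing.assert_allclose(obs_m[0], exact, atol=1e-10)

    def test_seeded_forecast_deterministic(self, lds_and_trials):
        model, trials = lds_and_trials
        fr = filter_trial(model, trials[0].observations)
        out1 = predict_forward(model, fr.state_at(5), 6, rng_seed=3)
        out2 = predict_forward(model, fr.state_at(5), 6, rng_seed=3)
        np.testing.assert_array_equal(out1[0], out2[0])

    def test_zero_horizon_rejected(self, lds_and_trials):
        model, trials = lds_and_trials
        fr = filter_trial(model, trials[0].observations)
        with pytest.raises(ValueError):
            predict_forward(model, fr.state_at(5), 0)

    def test_forecast_error_grows_with_horizon(self, truth, gaussian_emission,
                                               gaussian_dataset):
        """On ground-truth data, the truth's own forecast error (MED) is
        non-decreasing in the horizon on average."""
        from pwlds.benchmark import evaluate_predictions
        model = PWLModel(truth.modes, truth.transition, gaussian_emission,
                         truth.initial)
        test = list(gaussian_dataset.split("test"))[:15]
        df = evaluate_predictions(model, test, horizons=range(1, 11),
                                  n_samples=40, rng_seed=0)
        med = df[df.metric == "med"].groupby("horizon").value.mean()
        diffs = np.diff(med.to_numpy())
        assert med.iloc[-1] > med.iloc[0]
        assert np.mean(diffs >= -0.02) > 0.8
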