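"""Posterior inference, variational-EM fitting, filtering and forecasting.

The public surface:

* :func:`infer_posterior` — damped structured mean-field posterior over the
  discrete modes and continuous latent trajectories of given trials.
* :func:`elbo` — evidence lower bound of data under a model and posterior.
* :func:`fit_model` — variational EM from a data-driven (PCA + k-means)
  initialization; returns the fitted model and the per-iteration bound trace.
* :func:`filter_trial` / :func:`predict_forward` — causal (filtering)
  state estimates and seeded Monte-Carlo k-step-ahead forecasts, the
  ingredients of the forecasting benchmark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from . import _engine as eng
from .model import (
    EmissionMap,
    PWLModel,
    Trial,
    softplus,
    softplus_inverse,
)

__all__ = [
    "PosteriorEstimate",
    "FilterResult",
    "infer_posterior",
    "elbo",
    "fit_model",
    "filter_trial",
    "filter_trials",
    "predict_forward",
]


def _as_obs_list(trials) -> List[np.ndarray]:
    out = []
    for t in trials:
        y = t.observations if isinstance(t, Trial) else np.asarray(t)
        if y.ndim != 2:
            raise ValueError("each trial must be a (T, N) observation array")
        out.append(y)
    return out


def _group_batches(Ys: Sequence[np.ndarray], K: int, H: int, m_inits=None,
                   z_inits=None, z_conf: float = 0.85):
    """Group equal-length trials into batches; returns (batches, index lists).

    ``m_inits``/``z_inits`` optionally seed the continuous-state means and the
    mode responsibilities (labels smeared to ``z_conf`` confidence); without
    them the means start at zero and q(z) uniform."""
    byT: dict = {}
    for i, y in enumerate(Ys):
        byT.setdefault(y.shape[0], []).append(i)
    batches, indices = [], []
    for T, idx in sorted(byT.items()):
        Y = np.stack([Ys[i] for i in idx]).astype(float)
        m0 = None if m_inits is None else np.stack([m_inits[i] for i in idx])
        batch = eng.Batch.initialize(Y, K, H, m_init=m0)
        if z_inits is not None and K > 1:
            lab = np.stack([z_inits[i] for i in idx])
            w = np.full((len(idx), T, K), (1.0 - z_conf) / (K - 1))
            np.put_along_axis(w, lab[..., None], z_conf, axis=-1)
            batch.w = w
        batches.append(batch)
        indices.append(idx)
    return batches, indices


@dataclass
class PosteriorEstimate:
    """Mean-field posterior per trial: q(z_t) rows on the simplex, Gaussian
    q(x_t) means and marginal covariances, and the total bound."""

    mode_probs: List[np.ndarray]       # each (T, K)
    means: List[np.ndarray]            # each (T, H)
    covs: List[np.ndarray]             # each (T, H, H)
    elbo: float
    _batches: Optional[list] = None
    _indices: Optional[list] = None

    def __len__(self):
        return len(self.means)


def infer_posterior(model: PWLModel, trials, learning_rate: float = 0.25,
                    n_iters: int = 30) -> PosteriorEstimate:
    """Damped mean-field posterior under a fixed model.

    Mode responsibilities start uniform; each sweep replaces both q(z) and
    the q(x) mean by the convex combination ``(1-lr) old + lr proposed``
    (with ``learning_rate=1`` a sweep is the undamped coordinate update).
    """
    if not 0.0 < learning_rate <= 1.0:
        raise ValueError("learning_rate must lie in (0, 1]")
    Ys = _as_obs_list(trials)
    batches, indices = _group_batches(Ys, model.K, model.H)
    params = eng.Params.from_model(model)
    eng.run_e_step(params, batches, learning_rate, n_sweeps=n_iters)
    total = eng.total_elbo(params, batches)
    n = len(Ys)
    mode_probs: list = [None] * n
    means: list = [None] * n
    covs: list = [None] * n
    for batch, idx in zip(batches, indices):
        for row, i in enumerate(idx):
            mode_probs[i] = batch.w[row]
            means[i] = batch.m[row]
            covs[i] = batch.Sig[row]
    return PosteriorEstimate(mode_probs, means, covs, total,
                             _batches=batches, _indices=indices)


def elbo(model: PWLModel, trials, posterior: Optional[PosteriorEstimate] = None,
         learning_rate: float = 1.0, n_iters: int = 50) -> float:
    """Evidence lower bound of the trials under the model.

    With an explicit posterior (from :func:`infer_posterior`) the bound is
    evaluated at that posterior; otherwise the posterior is first inferred.
    For a K=1 Gaussian model the converged bound equals the exact log
    marginal likelihood (the chain posterior is exact).
    """
    if posterior is None:
        posterior = infer_posterior(model, trials, learning_rate=learning_rate,
                                    n_iters=n_iters)
        return posterior.elbo
    if posterior._batches is None:
        raise ValueError("posterior must come from infer_posterior")
    params = eng.Params.from_model(model)
    return eng.total_elbo(params, posterior._batches)


# --------------------------------------------------------------------------
# initialization and fitting
# --------------------------------------------------------------------------

def _sigmoid(v):
    return 1.0 / (1.0 + np.exp(-np.clip(v, -30, 30)))


def _fit_stick_logistic(X, labels, K, n_iters: int = 15):
    """Stick-breaking multinomial fit of hard labels on latent positions via
    the Jaakkola-Jordan bound (used only for initialization)."""
    S, H = X.shape
    Xt = np.concatenate([X, np.ones((S, 1))], axis=1)
    onehot = np.zeros((S, K))
    onehot[np.arange(S), labels] = 1.0
    tail = np.flip(np.cumsum(np.flip(onehot, axis=1), axis=1), axis=1)[:, :-1]
    alpha = onehot[:, :-1]
    c1 = alpha - 0.5 * tail
    Theta = np.zeros((K - 1, H + 1))
    for _ in range(n_iters):
        nu = Xt @ Theta.T
        xi = np.abs(nu) + 1e-6
        lam = eng.lambda_jj(xi)
        for j in range(K - 1):
            wgt = 2.0 * tail[:, j] * lam[:, j]
            M = (Xt * wgt[:, None]).T @ Xt + 1e-6 * np.eye(H + 1)
            v = Xt.T @ c1[:, j]
            Theta[j] = np.linalg.solve(M, v)
    return Theta[:, :H], Theta[:, H]


def _default_init(Ys, K, H, family, rng) -> tuple:
    """Data-driven starting point: PCA-style emission map, least-squares
    global dynamics, and (for K>1) k-means mode clusters with a stick-breaking
    boundary fit; randomness of the restart enters through the cluster seeds
    and parameter jitter."""
    Yall = np.concatenate(Ys).astype(float)
    S_total, N = Yall.shape
    if family == "gaussian":
        d0 = Yall.mean(axis=0)
        Yc = Yall - d0
        _, svals, Vt = np.linalg.svd(Yc, full_matrices=False)
        C0 = Vt[:H].T
        if C0.shape[1] < H:   # fewer observation dims than latents
            C0 = np.concatenate(
                [C0, rng.standard_normal((N, H - C0.shape[1]))], axis=1)
        scores_all = Yc @ C0
        resid = Yc - scores_all @ C0.T
        S0 = np.diag(np.maximum(resid.var(axis=0), 1e-4))
    else:
        ybar = Yall.mean(axis=0)
        d0 = softplus_inverse(np.maximum(ybar, 1e-2))
        Z = (Yall - ybar) / np.sqrt(ybar + 0.25)
        Zc = Z - Z.mean(axis=0)
        _, svals, Vt = np.linalg.svd(Zc, full_matrices=False)
        V = Vt[:H].T
        if V.shape[1] < H:
            V = np.concatenate([V, rng.standard_normal((N, H - V.shape[1]))], axis=1)
        scores_all = Zc @ V
        scores_all /= scores_all.std(axis=0) + 1e-9
        target = (Yall - softplus(d0)) / np.maximum(_sigmoid(d0), 1e-3)
        C0, *_ = np.linalg.lstsq(scores_all, target, rcond=None)
        C0 = C0.T
        S0 = None

    # per-trial latent guesses; spike-count scores are noisy per bin, so for
    # Poisson data they are smoothed in time before clustering and dynamics
    # regression (the smoother E-step refines against the raw counts later)
    xs, pos = [], 0
    for y in Ys:
        sc = scores_all[pos:pos + y.shape[0]]
        pos += y.shape[0]
        if family == "poisson" and sc.shape[0] >= 5:
            kern = np.ones(5) / 5.0
            sc = np.stack([np.convolve(np.pad(sc[:, j], 2, mode="edge"), kern,
                                       mode="valid") for j in range(H)], axis=1)
        xs.append(sc)

    X0 = np.concatenate([x[:-1] for x in xs])
    X1 = np.concatenate([x[1:] for x in xs])
    Xt = np.concatenate([X0, np.ones((X0.shape[0], 1))], axis=1)
    AB, *_ = np.linalg.lstsq(Xt, X1, rcond=None)
    A_g, b_g = AB[:H].T, AB[H]
    Qres = np.cov((X1 - Xt @ AB).T) if X1.shape[0] > H + 2 else np.eye(H)
    Q_g = eng._floor_psd(np.atleast_2d(Qres) + 1e-4 * np.eye(H))

    labels = None
    if K == 1:
        A = A_g[None]
        b = b_g[None]
        Q = Q_g[None]
        R = r = stick = None
    else:
        from sklearn.cluster import KMeans
        km = KMeans(n_clusters=K, n_init=1,
                    random_state=int(rng.integers(2 ** 31 - 1)))
        labels_all = km.fit_predict(np.concatenate(xs))
        labels = []
        pos = 0
        for x in xs:
            labels.append(labels_all[pos:pos + x.shape[0]])
            pos += x.shape[0]
        A = np.empty((K, H, H))
        b = np.empty((K, H))
        Q = np.empty((K, H, H))
        for k in range(K):
            mask = np.concatenate([lab[1:] == k for lab in labels])
            if mask.sum() < 3 * (H + 1):
                A[k], b[k], Q[k] = A_g, b_g, Q_g
            else:
                ABk, *_ = np.linalg.lstsq(Xt[mask], X1[mask], rcond=None)
                A[k], b[k] = ABk[:H].T, ABk[H]
                Qk = np.cov((X1[mask] - Xt[mask] @ ABk).T)
                Q[k] = eng._floor_psd(np.atleast_2d(Qk) + 1e-4 * np.eye(H))
            A[k] = A[k] + 0.02 * rng.standard_normal((H, H))
        R, r = _fit_stick_logistic(np.concatenate(xs), labels_all, K)
        R = R + 0.1 * rng.standard_normal(R.shape)
        stick = np.arange(K)

    x0s = np.stack([x[0] for x in xs])
    mu0 = x0s.mean(axis=0)
    Sig0 = eng._floor_psd(np.atleast_2d(np.cov(x0s.T)) + 1e-4 * np.eye(H)) \
        if x0s.shape[0] > 2 else np.eye(H)
    pi0 = np.full(K, 1.0 / K)
    params = eng.Params(A=A, b=b, Q=Q, C=C0, d=d0, family=family, S=S0,
                        mu0=mu0, Sig0=Sig0, pi0=pi0, R=R, r=r, stick_order=stick)
    return params, xs, labels


def fit_model(trials, K: int, H: int, family: str = "gaussian",
              rng_seed=None, n_iters: int = 75, learning_rate: float = 0.25,
              e_sweeps: int = 2, init_model: Optional[PWLModel] = None):
    """Variational-EM fit of a K-mode, H-dimensional model.

    Returns ``(model, elbo_trace)``; the trace is recorded after each E-step
    and is non-decreasing (up to numerical tolerance) for the Gaussian
    family, where every update is an exact coordinate maximization of the
    bound.  ``rng_seed`` controls the restart (initial clustering and
    parameter jitter).
    """
    if K < 1 or H < 1:
        raise ValueError("need K >= 1 and H >= 1")
    rng = np.random.default_rng(rng_seed)
    Ys = _as_obs_list(trials)
    if family == "poisson":
        for y in Ys:
            if np.any(np.asarray(y) < 0):
                raise ValueError("poisson observations must be non-negative")
    if init_model is not None:
        params = eng.Params.from_model(init_model)
        m_inits = z_inits = None
    else:
        params, m_inits, z_inits = _default_init(Ys, K, H, family, rng)
    batches, _ = _group_batches(Ys, K, H, m_inits=m_inits, z_inits=z_inits)
    params, trace = eng.fit_vem(params, batches, n_iters=n_iters,
                                learning_rate=learning_rate, e_sweeps=e_sweeps)
    return params.to_model(), trace


# --------------------------------------------------------------------------
# filtering (causal state estimates) and forecasting
# --------------------------------------------------------------------------

@dataclass
class FilterResult:
    """Per-time-step causal state estimates p(x_t, z_t | y_{1:t})."""

    means: np.ndarray        # (T, H)
    covs: np.ndarray         # (T, H, H)
    mode_probs: np.ndarray   # (T, K)
    loglik: float            # exact for K=1 gaussian, assumed-density otherwise

    def state_at(self, t: int):
        return self.means[t], self.covs[t], self.mode_probs[t]


def _gauss_update_batch(m, P, y, C, d, Sinv, logdetS):
    """Information-form Kalman measurement update, batched over trials.

    ``m (B,H)``, ``P (B,H,H)``, ``y (B,N)``.  Works in the latent dimension
    via the Woodbury identity and the matrix determinant lemma, so the cost
    scales with N, not N²: posterior precision ``P⁻¹ + C'S⁻¹C`` and
    ``log det(CPC' + S) = log det S + log det(I + C'S⁻¹C P)``.
    """
    B, H = m.shape
    N = y.shape[1]
    CtSi = C.T @ Sinv                              # (H,N)
    CtSiC = CtSi @ C                               # (H,H)
    Pinv = np.linalg.inv(P + 1e-12 * np.eye(H))
    Jpost = Pinv + CtSiC
    innov = y - m @ C.T - d                        # (B,N)
    h = np.einsum("ij,bj->bi", CtSi, innov)
    delta = np.linalg.solve(Jpost, h[..., None])[..., 0]
    m_post = m + delta
    P_post = np.linalg.inv(Jpost)
    P_post = 0.5 * (P_post + np.swapaxes(P_post, -1, -2))
    # log N(y; Cm+d, CPC'+S) via Woodbury: quad = e'S⁻¹e − h'Jpost⁻¹h
    quad = np.einsum("bi,ij,bj->b", innov, Sinv, innov) - np.einsum(
        "bi,bi->b", h, delta)
    sign, logdet_msg = np.linalg.slogdet(np.eye(H) + CtSiC @ P)
    ll = -0.5 * (N * eng.LOG2PI + logdetS + logdet_msg + quad)
    return m_post, P_post, ll


def _poisson_update_batch(m, P, y, C, d, n_newton: int = 8):
    """Batched Laplace measurement update for softplus-Poisson observations."""
    from scipy.special import gammaln
    B, H = m.shape
    Pinv = np.linalg.inv(P + 1e-12 * np.eye(H))
    x = m.copy()

    def parts(xc):
        eta = xc @ C.T + d
        val, d1, d2 = eng.poisson_eta_derivs(eta, y)
        dm = xc - m
        f = val.sum(axis=1) - 0.5 * np.einsum("bi,bij,bj->b", dm, Pinv, dm)
        return f, d1, d2

    f, d1, d2 = parts(x)
    for _ in range(n_newton):
        g = np.einsum("ni,bn->bi", C, d1) - np.einsum("bij,bj->bi", Pinv, x - m)
        Hmat = Pinv + np.einsum("bn,ni,nj->bij", -d2, C, C)
        step = np.linalg.solve(Hmat, g[..., None])[..., 0]
        scale = np.ones(B)
        for _ls in range(10):
            f_new, d1_new, d2_new = parts(x + scale[:, None] * step)
            worse = f_new < f - 1e-12
            if not np.any(worse):
                break
            scale[worse] *= 0.5
        accept = f_new >= f - 1e-12
        moved = np.max(np.abs(scale[:, None] * step), axis=1)
        x = np.where(accept[:, None], x + scale[:, None] * step, x)
        f = np.where(accept, f_new, f)
        _, d1, d2 = parts(x)
        if not np.any(accept) or np.max(moved[accept]) < 1e-8:
            break
    Hmat = Pinv + np.einsum("bn,ni,nj->bij", -d2, C, C)
    P_post = np.linalg.inv(Hmat)
    P_post = 0.5 * (P_post + np.swapaxes(P_post, -1, -2))
    sign, logdet_post = np.linalg.slogdet(P_post)
    sign, logdet_pr = np.linalg.slogdet(P)
    ll = f + 0.5 * (logdet_post - logdet_pr) - gammaln(y + 1.0).sum(axis=1)
    return x, P_post, ll


def filter_trials(model: PWLModel, observations_batch) -> List[FilterResult]:
    """Batched causal assumed-density filter over equal-length trials.

    The Gaussian belief over x_t is propagated through the mode mixture
    (moment matching after the measurement update); mode weights come from
    the stick-breaking probabilities at the current mean and the per-mode
    measurement likelihoods.  For a K=1 Gaussian model this is the exact
    Kalman filter with the exact log-likelihood.
    """
    Y = np.stack([np.asarray(y, dtype=float) for y in observations_batch])
    B, T, N = Y.shape
    K, H = model.K, model.H
    A, b, Q = model.stacked_dynamics()
    C, d = model.emission.C, model.emission.d
    if model.family == "gaussian":
        Sinv = np.linalg.inv(model.emission.S)
        sign, logdetS = np.linalg.slogdet(model.emission.S)

    def measurement(m, P, yt):
        if model.family == "gaussian":
            return _gauss_update_batch(m, P, yt, C, d, Sinv, logdetS)
        return _poisson_update_batch(m, P, yt, C, d)

    means = np.empty((B, T, H))
    covs = np.empty((B, T, H, H))
    wz = np.empty((B, T, K))
    loglik = np.zeros(B)

    m0 = np.broadcast_to(model.initial.mean, (B, H)).copy()
    P0 = np.broadcast_to(model.initial.cov + 1e-10 * np.eye(H), (B, H, H)).copy()
    means[:, 0], covs[:, 0], ll = measurement(m0, P0, Y[:, 0])
    wz[:, 0] = model.initial.mode_probs
    loglik += ll

    for t in range(1, T):
        u = np.maximum(model.mode_probabilities(means[:, t - 1]), 1e-12)
        u /= u.sum(axis=-1, keepdims=True)
        ms = np.empty((K, B, H))
        Ps = np.empty((K, B, H, H))
        lls = np.empty((K, B))
        for k in range(K):
            m_pred = means[:, t - 1] @ A[k].T + b[k]
            P_pred = A[k] @ covs[:, t - 1] @ A[k].T + Q[k]
            ms[k], Ps[k], lls[k] = measurement(m_pred, P_pred, Y[:, t])
        logw = np.log(u.T) + lls                     # (K,B)
        norm = logsumexp(logw, axis=0)
        wpost = np.exp(logw - norm)                  # (K,B)
        m_mix = np.einsum("kb,kbi->bi", wpost, ms)
        dm = ms - m_mix[None]
        P_mix = np.einsum("kb,kbij->bij", wpost,
                          Ps + np.einsum("kbi,kbj->kbij", dm, dm))
        means[:, t], covs[:, t], wz[:, t] = m_mix, P_mix, wpost.T
        loglik += norm
    return [FilterResult(means[i], covs[i], wz[i], float(loglik[i]))
            for i in range(B)]


def filter_trial(model: PWLModel, observations) -> FilterResult:
    """Causal assumed-density filter for one trial (see :func:`filter_trials`)."""
    return filter_trials(model, [observations])[0]


def rollout_batch(model: PWLModel, x0: np.ndarray, horizon: int, rng,
                  stochastic: bool = True):
    """Simulate `horizon` dynamics steps from each row of x0 (M, H).

    Returns latents (M, horizon, H).  Stochastic rollouts sample modes from
    the stick-breaking probabilities (deterministic argmax for hard-boundary
    models) and add process noise; deterministic rollouts follow the
    most-likely mode with no noise.
    """
    rng = np.random.default_rng(rng)
    M, H = x0.shape
    A, b, Q = model.stacked_dynamics()
    Lq = np.stack([np.linalg.cholesky(q + 1e-12 * np.eye(H)) for q in Q])
    hard = model.K > 1 and model.transition.hard
    x = x0.copy()
    out = np.empty((M, horizon, H))
    for step in range(horizon):
        if model.K == 1:
            z = np.zeros(M, dtype=int)
        else:
            p = model.mode_probabilities(x)
            if stochastic and not hard:
                cum = np.cumsum(p, axis=-1)
                z = (cum < rng.random(M)[:, None]).sum(axis=-1)
            else:
                z = np.argmax(p, axis=-1)
        x = np.einsum("mij,mj->mi", A[z], x) + b[z]
        if stochastic:
            x = x + np.einsum("mij,mj->mi", Lq[z], rng.standard_normal((M, H)))
        out[:, step] = x
    return out


def predict_forward(model: PWLModel, state, horizon: int,
                    n_samples: int = 100, rng_seed=None,
                    method: str = "sample"):
    """k-step-ahead forecast from a filtered state (mean, cov, mode_probs).

    ``method='sample'`` draws latent starting points from the filtered
    Gaussian and Monte-Carlo-averages stochastic rollouts (seeded and
    deterministic given the seed); ``method='mode'`` is a single most-likely
    rollout without noise.  Returns ``(latents (k,H), observations (k,N))``
    where the observation forecast is the expected observation (Gaussian) or
    the expected softplus rate (Poisson).
    """
    if horizon < 1:
        raise ValueError("horizon must be at least 1")
    mean, cov, _ = state
    rng = np.random.default_rng(rng_seed)
    if method == "mode":
        lat = rollout_batch(model, mean[None, :], horizon, rng, stochastic=False)
        obs = model.emission.mean_response(lat[0])
        return lat[0], obs
    L = np.linalg.cholesky(np.asarray(cov) + 1e-12 * np.eye(len(mean)))
    x0 = mean + rng.standard_normal((n_samples, len(mean))) @ L.T
    lat = rollout_batch(model, x0, horizon, rng, stochastic=True)
    lat_mean = lat.mean(axis=0)
    if model.family == "gaussian":
        obs = model.emission.mean_response(lat_mean)
    else:
        obs = softplus(np.einsum("mkh,nh->mkn", lat, model.emission.C)
                       + model.emission.d).mean(axis=0)
    return lat_mean, obs
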