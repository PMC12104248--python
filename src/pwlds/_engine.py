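"""Variational-EM engine for piecewise-linear latent dynamical systems.

Approximation family
--------------------
Structured mean field ``q(z) q(x)`` per trial:

* ``q(x)`` is a joint Gaussian over the whole latent trajectory with
  block-tridiagonal precision (a Gauss-Markov chain), updated by an exact
  information-form smoother given the current mode responsibilities.
* ``q(z_t)`` are independent categoricals.  Because the recurrent-only
  transition makes ``z_{t+1}`` depend only on ``x_t``, the optimal ``q(z)``
  factorizes over time exactly; no forward-backward pass over z is needed.
* The stick-breaking log-probabilities ``log sigma(+/- nu)`` are handled with
  the Jaakkola-Jordan quadratic bound with per-stick variational parameters
  ``xi``, so the evidence objective is a proper lower bound and every update
  (q(x), q(z), xi, and all M-steps) increases it in closed form for the
  Gaussian family.  Poisson emissions use a Laplace (Newton) update for q(x)
  and a second-order expansion of the emission term in the bound, so ascent
  is approximate there.
* Both ``q(z)`` and the ``q(x)`` mean are damped: the new value is the convex
  combination ``(1 - lr) * old + lr * proposed``, which avoids premature
  hard commitment to a single mode early in fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .model import (
    EmissionMap,
    InitialState,
    LinearMode,
    PWLModel,
    RecurrentTransition,
    softplus,
    softplus_inverse,
)

LOG2PI = np.log(2.0 * np.pi)
COV_EIG_FLOOR = 1e-8
_JITTER = 1e-10


# --------------------------------------------------------------------------
# block-tridiagonal Gaussian chains
# --------------------------------------------------------------------------

def solve_chain(Jd, Jo, h):
    """Moments of a Gaussian with block-tridiagonal precision.

    The energy convention is ``E(x) = 1/2 sum_t x_t' Jd_t x_t
    + sum_t x_t' Jo_t x_{t+1} - sum_t h_t' x_t`` with ``p(x) ~ exp(-E)``.

    Parameters are batched: ``Jd (B,T,H,H)``, ``Jo (B,T-1,H,H)``,
    ``h (B,T,H)``.  Returns per-step means ``m``, marginal covariances
    ``Sig``, lag-one cross-covariances ``Cross[t] = Cov(x_t, x_{t+1})`` and
    the log-determinant of the full precision (for entropies/normalizers).
    """
    B, T, H, _ = Jd.shape
    P = np.empty_like(Jd)
    hh = np.empty_like(h)
    W = np.empty((B, max(T - 1, 0), H, H))
    P[:, 0] = Jd[:, 0]
    hh[:, 0] = h[:, 0]
    logdet = np.zeros(B)
    for t in range(T - 1):
        L = _chol(P[:, t])
        logdet += 2.0 * np.log(np.diagonal(L, axis1=-2, axis2=-1)).sum(axis=-1)
        W[:, t] = np.linalg.solve(P[:, t], Jo[:, t])
        P[:, t + 1] = Jd[:, t + 1] - np.swapaxes(Jo[:, t], -1, -2) @ W[:, t]
        hh[:, t + 1] = h[:, t + 1] - np.einsum("bij,bi->bj", W[:, t], hh[:, t])
    L = _chol(P[:, T - 1])
    logdet += 2.0 * np.log(np.diagonal(L, axis1=-2, axis2=-1)).sum(axis=-1)

    m = np.empty((B, T, H))
    Sig = np.empty((B, T, H, H))
    Cross = np.empty((B, max(T - 1, 0), H, H))
    Sig[:, T - 1] = np.linalg.inv(P[:, T - 1])
    m[:, T - 1] = np.linalg.solve(P[:, T - 1], hh[:, T - 1][..., None])[..., 0]
    for t in range(T - 2, -1, -1):
        Pinv = np.linalg.inv(P[:, t])
        m[:, t] = np.einsum("bij,bj->bi", Pinv, hh[:, t]) - \
            np.einsum("bij,bj->bi", W[:, t], m[:, t + 1])
        Sig[:, t] = Pinv + W[:, t] @ Sig[:, t + 1] @ np.swapaxes(W[:, t], -1, -2)
        Cross[:, t] = -W[:, t] @ Sig[:, t + 1]
        Sig[:, t] = 0.5 * (Sig[:, t] + np.swapaxes(Sig[:, t], -1, -2))
    return m, Sig, Cross, logdet


def _chol(M):
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        H = M.shape[-1]
        scale = np.maximum(np.trace(M, axis1=-2, axis2=-1) / H, 1.0)
        jitter = (1e-8 * scale)[..., None, None] * np.eye(H)
        return np.linalg.cholesky(M + jitter)


def lambda_jj(xi):
    """Jaakkola-Jordan curvature ``tanh(xi/2) / (4 xi)`` with the xi -> 0 limit 1/8."""
    xi = np.asarray(xi, dtype=float)
    out = np.full_like(xi, 0.125)
    big = xi > 1e-4
    out[big] = np.tanh(xi[big] / 2.0) / (4.0 * xi[big])
    return out


def _log_sigmoid(v):
    return -softplus(-np.asarray(v, dtype=float))


# --------------------------------------------------------------------------
# parameter bundle (stacked arrays; mirrors PWLModel)
# --------------------------------------------------------------------------

@dataclass
class Params:
    A: np.ndarray                 # (K,H,H)
    b: np.ndarray                 # (K,H)
    Q: np.ndarray                 # (K,H,H)
    C: np.ndarray                 # (N,H)
    d: np.ndarray                 # (N,)
    family: str
    S: Optional[np.ndarray]       # (N,N) or None
    mu0: np.ndarray               # (H,)
    Sig0: np.ndarray              # (H,H)
    pi0: np.ndarray               # (K,)
    R: Optional[np.ndarray]       # (K-1,H) or None
    r: Optional[np.ndarray]       # (K-1,)
    stick_order: Optional[np.ndarray]

    @property
    def K(self):
        return self.A.shape[0]

    @property
    def H(self):
        return self.A.shape[1]

    @property
    def N(self):
        return self.C.shape[0]

    @classmethod
    def from_model(cls, model: PWLModel) -> "Params":
        A, b, Q = model.stacked_dynamics()
        t = model.transition
        return cls(A=A, b=b, Q=Q, C=model.emission.C, d=model.emission.d,
                   family=model.family, S=model.emission.S,
                   mu0=model.initial.mean, Sig0=model.initial.cov,
                   pi0=model.initial.mode_probs,
                   R=None if t is None else t.R, r=None if t is None else t.r,
                   stick_order=None if t is None else t.stick_order)

    def to_model(self, hard: bool = False) -> PWLModel:
        modes = [LinearMode(self.A[k], self.b[k], self.Q[k]) for k in range(self.K)]
        trans = None
        if self.K > 1:
            trans = RecurrentTransition(self.R, self.r, self.stick_order, hard)
        emission = EmissionMap(self.C, self.d, self.family, self.S)
        initial = InitialState(self.mu0, self.Sig0, self.pi0)
        return PWLModel(modes, trans, emission, initial)

    def precisions(self):
        Qinv = np.linalg.inv(self.Q)
        Sig0 = self.Sig0
        if np.linalg.eigvalsh(Sig0).min() < COV_EIG_FLOOR:
            Sig0 = Sig0 + COV_EIG_FLOOR * np.eye(self.H)
        return Qinv, np.linalg.inv(Sig0)


@dataclass
class Batch:
    """Mean-field state for a group of equal-length trials."""

    Y: np.ndarray                       # (B,T,N)
    w: np.ndarray                       # (B,T,K) q(z)
    xi: np.ndarray                      # (B,T-1,K-1)
    m: np.ndarray                       # (B,T,H)
    Sig: np.ndarray                     # (B,T,H,H)
    Cross: np.ndarray                   # (B,T-1,H,H)
    logdetJ: np.ndarray                 # (B,)

    @property
    def B(self):
        return self.Y.shape[0]

    @property
    def T(self):
        return self.Y.shape[1]

    @classmethod
    def initialize(cls, Y, K, H, m_init=None):
        B, T, _ = Y.shape
        w = np.full((B, T, K), 1.0 / K)
        xi = np.ones((B, max(T - 1, 0), max(K - 1, 0)))
        m = np.zeros((B, T, H)) if m_init is None else np.array(m_init, dtype=float)
        Sig = np.tile(np.eye(H), (B, T, 1, 1))
        Cross = np.zeros((B, max(T - 1, 0), H, H))
        return cls(Y=Y.astype(float) if Y.dtype.kind != "f" else Y,
                   w=w, xi=xi, m=m, Sig=Sig, Cross=Cross, logdetJ=np.zeros(B))

    def moments(self):
        Exx = self.Sig + np.einsum("bti,btj->btij", self.m, self.m)
        Ecross = self.Cross + np.einsum("bti,btj->btij", self.m[:, :-1], self.m[:, 1:])
        return Exx, Ecross


# --------------------------------------------------------------------------
# prior/dynamics/recurrence quadratic terms
# --------------------------------------------------------------------------

def prior_chain_terms(params: Params, batch: Batch):
    """Quadratic chain terms from initial state, dynamics and the JJ-bounded
    recurrence, given current q(z) and xi.  Emission terms are added by the
    caller (exact for Gaussian, quadratized for Poisson)."""
    K, H = params.K, params.H
    B, T = batch.B, batch.T
    Qinv, Sig0inv = params.precisions()
    Jd = np.zeros((B, T, H, H))
    Jo = np.zeros((B, max(T - 1, 0), H, H))
    h = np.zeros((B, T, H))

    Jd[:, 0] += Sig0inv
    h[:, 0] += Sig0inv @ params.mu0

    if T > 1:
        AtQi = np.einsum("kji,kjl->kil", params.A, Qinv)      # A' Qinv, (K,H,H)
        AtQiA = np.einsum("kij,kjl->kil", AtQi, params.A)
        Qib = np.einsum("kij,kj->ki", Qinv, params.b)
        AtQib = np.einsum("kij,kj->ki", AtQi, params.b)
        wt = batch.w[:, 1:]                                   # (B,T-1,K)
        Jd[:, :-1] += np.einsum("btk,kij->btij", wt, AtQiA)
        Jd[:, 1:] += np.einsum("btk,kij->btij", wt, Qinv)
        Jo -= np.einsum("btk,kij->btij", wt, AtQi)
        h[:, :-1] -= np.einsum("btk,ki->bti", wt, AtQib)
        h[:, 1:] += np.einsum("btk,ki->bti", wt, Qib)

        if K > 1:
            c1, c2 = _stick_coefficients(params, batch)       # (B,T-1,K-1) each
            RRt = np.einsum("ji,jl->jil", params.R, params.R)
            Jd[:, :-1] += 2.0 * np.einsum("btj,jil->btil", c2, RRt)
            h[:, :-1] += np.einsum("btj,ji->bti", c1 - 2.0 * c2 * params.r, params.R)
    return Jd, Jo, h


def _stick_masses(params: Params, w_next):
    """Per-stick responsibilities: alpha_j (mass of the mode at stick position
    j) and tail_j (mass at positions >= j), from q(z_{t+1})."""
    wp = w_next[..., params.stick_order]                      # position order
    tail = np.flip(np.cumsum(np.flip(wp, axis=-1), axis=-1), axis=-1)
    alpha = wp[..., :-1]
    return alpha, tail[..., :-1]


def _stick_coefficients(params: Params, batch: Batch):
    """Linear (c1) and quadratic (c2) coefficients of each stick logit in the
    expected JJ-bounded transition term."""
    alpha, tail = _stick_masses(params, batch.w[:, 1:])
    lam = lambda_jj(batch.xi)
    c2 = tail * lam
    c1 = alpha - 0.5 * tail        # alpha*(+1/2) + (tail-alpha)*(-1/2)
    return c1, c2


def stick_moments(params: Params, batch: Batch):
    """E[nu] and E[nu^2] of the stick logits under q(x) at times 0..T-2."""
    m, Sig = batch.m[:, :-1], batch.Sig[:, :-1]
    Enu = np.einsum("ji,bti->btj", params.R, m) + params.r
    var = np.einsum("ji,btil,jl->btj", params.R, Sig, params.R)
    return Enu, Enu2_from(Enu, var)


def Enu2_from(Enu, var):
    return Enu ** 2 + var


#: cap on the JJ variational parameter; keeps the quadratic weights away from
#: zero so sharp fitted boundaries cannot destabilize the (R, r) update
XI_MAX = 100.0


def update_xi(params: Params, batch: Batch):
    """Tightest JJ bound given q(x): xi_j = sqrt(E[nu_j^2]) (capped)."""
    if params.K > 1 and batch.T > 1:
        _, Enu2 = stick_moments(params, batch)
        batch.xi = np.minimum(np.sqrt(np.maximum(Enu2, 1e-12)), XI_MAX)


def _stick_bound_pieces(params: Params, batch: Batch):
    """Expected JJ lower bounds of log sigma(nu_j) and log sigma(-nu_j)
    per stick, shape (B, T-1, K-1) each."""
    Enu, Enu2 = stick_moments(params, batch)
    xi = batch.xi
    lam = lambda_jj(xi)
    base = _log_sigmoid(xi) - 0.5 * xi - lam * (Enu2 - xi ** 2)
    return base + 0.5 * Enu, base - 0.5 * Enu


def transition_mode_scores(params: Params, batch: Batch):
    """Expected (JJ-bounded) log transition probability of each mode for the
    transitions into times 1..T-1; shape (B, T-1, K), in mode-index order."""
    K = params.K
    plus, minus = _stick_bound_pieces(params, batch)
    B, Tm1 = plus.shape[0], plus.shape[1]
    scores_pos = np.empty((B, Tm1, K))
    cum_minus = np.concatenate(
        [np.zeros((B, Tm1, 1)), np.cumsum(minus, axis=-1)], axis=-1)
    for p in range(K):
        s = cum_minus[..., p]
        if p < K - 1:
            s = s + plus[..., p]
        scores_pos[..., p] = s
    scores = np.empty_like(scores_pos)
    scores[..., params.stick_order] = scores_pos
    return scores


# --------------------------------------------------------------------------
# expected dynamics log-densities (used by q(z) update and the ELBO)
# --------------------------------------------------------------------------

def dynamics_mode_scores(params: Params, batch: Batch):
    """E_q(x)[log N(x_{t+1}; A_k x_t + b_k, Q_k)] for every mode, (B,T-1,K)."""
    Exx, Ecross = batch.moments()
    Qinv, _ = params.precisions()
    H = params.H
    sign, logdetQ = np.linalg.slogdet(params.Q)
    m0, m1 = batch.m[:, :-1], batch.m[:, 1:]
    Exx0, Exx1 = Exx[:, :-1], Exx[:, 1:]

    # E[(x' - A x - b)' Qinv (x' - A x - b)] expanded in moments
    t1 = np.einsum("btij,kji->btk", Exx1, Qinv)
    QiA = np.einsum("kij,kjl->kil", Qinv, params.A)           # Qinv A
    # -2 E[x'^T Qinv A x] = -2 tr(Qinv A E[x x'^T]) ; E[x x'^T] = Ecross
    t2 = -2.0 * np.einsum("kij,btji->btk", QiA, Ecross)
    AtQiA = np.einsum("kji,kjl->kil", params.A, QiA)
    t3 = np.einsum("btij,kji->btk", Exx0, AtQiA)
    Qib = np.einsum("kij,kj->ki", Qinv, params.b)
    t4 = -2.0 * np.einsum("bti,ki->btk", m1, Qib)
    AtQib = np.einsum("kji,kj->ki", params.A, Qib)
    t5 = 2.0 * np.einsum("bti,ki->btk", m0, AtQib)
    t6 = np.einsum("ki,ki->k", params.b, Qib)
    quad = t1 + t2 + t3 + t4 + t5 + t6
    return -0.5 * (H * LOG2PI + logdetQ[None, None, :] + quad)


def initial_state_score(params: Params, batch: Batch):
    """E_q(x)[log N(x_0; mu0, Sig0)] per trial."""
    _, Sig0inv = params.precisions()
    Sig0 = np.linalg.inv(Sig0inv)
    sign, logdet0 = np.linalg.slogdet(Sig0)
    dm = batch.m[:, 0] - params.mu0
    quad = np.einsum("bi,ij,bj->b", dm, Sig0inv, dm) + \
        np.einsum("btij,ji->bt", batch.Sig[:, :1], Sig0inv)[:, 0]
    return -0.5 * (params.H * LOG2PI + logdet0 + quad)


# --------------------------------------------------------------------------
# emission terms
# --------------------------------------------------------------------------

def gaussian_emission_chain_terms(params: Params, batch: Batch):
    Sinv = np.linalg.inv(params.S)
    CtSi = params.C.T @ Sinv
    CtSiC = CtSi @ params.C
    Jd_e = np.broadcast_to(CtSiC, (batch.B, batch.T, params.H, params.H))
    h_e = np.einsum("ij,btj->bti", CtSi, batch.Y - params.d)
    return Jd_e, h_e


def gaussian_emission_elbo(params: Params, batch: Batch):
    Sinv = np.linalg.inv(params.S)
    sign, logdetS = np.linalg.slogdet(params.S)
    resid = batch.Y - np.einsum("ij,btj->bti", params.C, batch.m) - params.d
    quad = np.einsum("btn,nl,btl->b", resid, Sinv, resid)
    CtSiC = params.C.T @ Sinv @ params.C
    tr = np.einsum("btij,ji->b", batch.Sig, CtSiC)
    T = batch.T
    return -0.5 * (T * (params.N * LOG2PI + logdetS) + quad + tr)


def poisson_eta_derivs(eta, y):
    """Value, first and second derivative in eta of the per-cell Poisson
    log-likelihood ``y log softplus(eta) - softplus(eta)`` (without log y!)."""
    eta = np.clip(eta, -50.0, 500.0)   # only the negative tail is delicate
    e = np.exp(-np.abs(eta))
    sig = np.where(eta >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
    sp = np.log1p(e) + np.maximum(eta, 0.0)
    dsig = sig * (1.0 - sig)
    ratio = sig / sp
    val = y * np.log(sp) - sp
    d1 = y * ratio - sig
    d2 = y * (dsig / sp - ratio ** 2) - dsig
    return val, d1, np.minimum(d2, -1e-12)


def poisson_emission_elbo(params: Params, batch: Batch):
    """Second-order expectation of the Poisson emission term around the
    posterior mean (includes the log y! normalizer)."""
    from scipy.special import gammaln
    eta = np.einsum("ij,btj->bti", params.C, batch.m) + params.d
    val, _, d2 = poisson_eta_derivs(eta, batch.Y)
    var_eta = np.einsum("ni,btij,nj->btn", params.C, batch.Sig, params.C)
    per_cell = val + 0.5 * d2 * var_eta - gammaln(batch.Y + 1.0)
    return per_cell.sum(axis=(1, 2))


# --------------------------------------------------------------------------
# E-step updates
# --------------------------------------------------------------------------

def update_qx(params: Params, batch: Batch, learning_rate: float = 1.0,
              laplace_iters: int = 4, laplace_tol: float = 1e-7):
    """Update q(x) given q(z) and xi.

    Gaussian: one exact information-form smoothing pass.  Poisson: damped
    Newton (Laplace) iterations on the MAP trajectory, then the Gaussian
    approximation at the optimum.  The posterior mean is damped by
    ``learning_rate``; the covariance is taken from the proposed precision.
    """
    Jd, Jo, h = prior_chain_terms(params, batch)
    if params.family == "gaussian":
        Jd_e, h_e = gaussian_emission_chain_terms(params, batch)
        m, Sig, Cross, logdet = solve_chain(Jd + Jd_e, Jo, h + h_e)
    else:
        m, Sig, Cross, logdet = _laplace_qx(params, batch, Jd, Jo, h,
                                            laplace_iters, laplace_tol)
    if learning_rate < 1.0:
        m = (1.0 - learning_rate) * batch.m + learning_rate * m
    batch.m, batch.Sig, batch.Cross, batch.logdetJ = m, Sig, Cross, logdet


def _chain_quad_obj(Jd, Jo, h, x):
    """-1/2 x'Jx + h'x for a block-tridiagonal J (batched over trials)."""
    quad = np.einsum("bti,btij,btj->b", x, Jd, x)
    if Jo.shape[1] > 0:
        quad += 2.0 * np.einsum("bti,btij,btj->b", x[:, :-1], Jo, x[:, 1:])
    return -0.5 * quad + np.einsum("bti,bti->b", h, x)


def _laplace_qx(params: Params, batch: Batch, Jd, Jo, h, max_iters, tol):
    x = batch.m.copy()
    C, d = params.C, params.d

    def emis_val(xcur):
        eta = np.einsum("ij,btj->bti", C, xcur) + d
        val, d1, d2 = poisson_eta_derivs(eta, batch.Y)
        return val.sum(axis=(1, 2)), d1, d2

    fval, d1, d2 = emis_val(x)
    obj = _chain_quad_obj(Jd, Jo, h, x) + fval
    for _ in range(max_iters):
        Jd_e = np.einsum("btn,ni,nj->btij", -d2, C, C)
        h_e = np.einsum("ni,btn->bti", C, d1) + np.einsum("btij,btj->bti", Jd_e, x)
        x_new, _, _, _ = solve_chain(Jd + Jd_e, Jo, h + h_e)
        step = 1.0
        improved = False
        for _ls in range(12):
            cand = x + step * (x_new - x)
            fval_c, d1_c, d2_c = emis_val(cand)
            obj_c = _chain_quad_obj(Jd, Jo, h, cand) + fval_c
            if np.all(obj_c >= obj - 1e-10):
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        delta = np.max(np.abs(cand - x))
        x, obj, d1, d2 = cand, obj_c, d1_c, d2_c
        if delta < tol * (1.0 + np.max(np.abs(x))):
            break
    Jd_e = np.einsum("btn,ni,nj->btij", -d2, C, C)
    h_e = np.einsum("ni,btn->bti", C, d1) + np.einsum("btij,btj->bti", Jd_e, x)
    m, Sig, Cross, logdet = solve_chain(Jd + Jd_e, Jo, h + h_e)
    return m, Sig, Cross, logdet


def update_qz(params: Params, batch: Batch, learning_rate: float = 1.0):
    """Damped coordinate update of the mode responsibilities q(z)."""
    K = params.K
    if K == 1:
        batch.w[:] = 1.0
        return
    logrho = np.empty_like(batch.w)
    logrho[:, 0] = np.log(np.maximum(params.pi0, 1e-300))
    if batch.T > 1:
        logrho[:, 1:] = dynamics_mode_scores(params, batch) + \
            transition_mode_scores(params, batch)
    w_prop = np.exp(logrho - logsumexp(logrho, axis=-1, keepdims=True))
    batch.w = (1.0 - learning_rate) * batch.w + learning_rate * w_prop
    batch.w /= batch.w.sum(axis=-1, keepdims=True)


# --------------------------------------------------------------------------
# evidence lower bound
# --------------------------------------------------------------------------

def elbo_batch(params: Params, batch: Batch):
    """Per-trial ELBO (JJ surrogate) at the current q(z), q(x), xi."""
    if params.family == "gaussian":
        e_emis = gaussian_emission_elbo(params, batch)
    else:
        e_emis = poisson_emission_elbo(params, batch)
    e_init = initial_state_score(params, batch)
    total = e_emis + e_init
    if batch.T > 1:
        e_dyn = (batch.w[:, 1:] * dynamics_mode_scores(params, batch)).sum(axis=(1, 2))
        total = total + e_dyn
        if params.K > 1:
            e_trans = (batch.w[:, 1:] * transition_mode_scores(params, batch)).sum(axis=(1, 2))
            total = total + e_trans
    if params.K > 1:
        e_z0 = (batch.w[:, 0] * np.log(np.maximum(params.pi0, 1e-300))).sum(axis=-1)
        h_z = -np.sum(np.where(batch.w > 0, batch.w * np.log(np.maximum(batch.w, 1e-300)), 0.0),
                      axis=(1, 2))
        total = total + e_z0 + h_z
    h_x = 0.5 * (batch.T * params.H * (1.0 + LOG2PI) - batch.logdetJ)
    return total + h_x


# --------------------------------------------------------------------------
# M-step
# --------------------------------------------------------------------------

def _xtilde_moments(batch: Batch):
    """E[x~ x~'] with x~ = (x, 1): (B,T,H+1,H+1); and E[x~] (B,T,H+1)."""
    B, T, H = batch.m.shape
    Exx, _ = batch.moments()
    M = np.empty((B, T, H + 1, H + 1))
    M[..., :H, :H] = Exx
    M[..., :H, H] = batch.m
    M[..., H, :H] = batch.m
    M[..., H, H] = 1.0
    Ext = np.concatenate([batch.m, np.ones((B, T, 1))], axis=-1)
    return M, Ext


def m_step(params: Params, batches: Sequence[Batch],
           update_initial: bool = True) -> Params:
    """Closed-form parameter maximization given the mean-field posteriors."""
    K, H, N = params.K, params.H, params.N
    # ---- dynamics ----
    M1 = np.zeros((K, H + 1, H + 1))
    M2 = np.zeros((K, H, H + 1))
    Syy = np.zeros((K, H, H))
    Wsum = np.zeros(K)
    # ---- transition ----
    if K > 1:
        Mt = np.zeros((K - 1, H + 1, H + 1))
        vt = np.zeros((K - 1, H + 1))
    # ---- emissions ----
    Sxx = np.zeros((H + 1, H + 1))
    Sxy = np.zeros((N, H + 1))
    n_obs_total = 0
    # ---- initial state ----
    Ex0 = np.zeros(H)
    Ex0x0 = np.zeros((H, H))
    w0 = np.zeros(K)
    n_trials = 0

    for batch in batches:
        Exx, Ecross = batch.moments()
        Mx, Ext = _xtilde_moments(batch)
        if batch.T > 1:
            wt = batch.w[:, 1:]
            M1 += np.einsum("btk,btij->kij", wt, Mx[:, :-1])
            # E[x_{t+1} x~_t'] = [Ecross' , m_{t+1}]
            Exy = np.concatenate(
                [np.swapaxes(Ecross, -1, -2), batch.m[:, 1:, :, None]], axis=-1)
            M2 += np.einsum("btk,btij->kij", wt, Exy)
            Syy += np.einsum("btk,btij->kij", wt, Exx[:, 1:])
            Wsum += wt.sum(axis=(0, 1))
            if K > 1:
                c1, c2 = _stick_coefficients(params, batch)
                Mt += 2.0 * np.einsum("btj,btik->jik", c2, Mx[:, :-1])
                vt += np.einsum("btj,bti->ji", c1, Ext[:, :-1])
        Sxx += Mx.sum(axis=(0, 1))
        Sxy += np.einsum("btn,bti->ni", batch.Y, Ext)
        n_obs_total += batch.B * batch.T
        Ex0 += batch.m[:, 0].sum(axis=0)
        Ex0x0 += Exx[:, 0].sum(axis=0)
        w0 += batch.w[:, 0].sum(axis=0)
        n_trials += batch.B

    new = Params(**{f: getattr(params, f) for f in params.__dataclass_fields__})

    # dynamics per mode: [A b] = M2 M1^{-1}; Q from residual moments
    A = np.empty_like(params.A)
    b = np.empty_like(params.b)
    Q = np.empty_like(params.Q)
    for k in range(K):
        reg = _JITTER * max(np.trace(M1[k]) / (H + 1), 1.0) * np.eye(H + 1)
        AB = np.linalg.solve(M1[k] + reg, M2[k].T).T
        A[k] = AB[:, :H]
        b[k] = AB[:, H]
        resid = Syy[k] - AB @ M2[k].T - M2[k] @ AB.T + AB @ M1[k] @ AB.T
        Qk = resid / max(Wsum[k], 1e-8)
        Q[k] = _floor_psd(0.5 * (Qk + Qk.T))
    new.A, new.b, new.Q = A, b, Q

    # shared stick-breaking weights, with a trust region on the step: the
    # closed-form maximizer can overshoot wildly when the boundary logits are
    # already saturated (tiny JJ curvature), so the per-row step is limited
    # relative to the current weight magnitude
    if K > 1:
        R = np.empty_like(params.R)
        r = np.empty_like(params.r)
        for j in range(K - 1):
            reg = _JITTER * max(np.trace(Mt[j]) / (H + 1), 1.0) * np.eye(H + 1)
            theta_old = np.concatenate([params.R[j], [params.r[j]]])
            theta = np.linalg.solve(Mt[j] + reg, vt[j])
            step = theta - theta_old
            max_step = 2.0 + 0.5 * np.linalg.norm(theta_old)
            norm = np.linalg.norm(step)
            if norm > max_step:
                theta = theta_old + step * (max_step / norm)
            R[j] = theta[:H]
            r[j] = theta[H]
        new.R, new.r = R, r

    # emissions
    if params.family == "gaussian":
        reg = _JITTER * max(np.trace(Sxx) / (H + 1), 1.0) * np.eye(H + 1)
        CD = np.linalg.solve(Sxx + reg, Sxy.T).T
        C = CD[:, :H]
        d = CD[:, H]
        # diagonal observation-noise estimate via moments
        s = np.zeros(N)
        for batch in batches:
            resid = batch.Y - np.einsum("ij,btj->bti", C, batch.m) - d
            s += np.einsum("btn,btn->n", resid, resid)
            s += np.einsum("ni,btij,nj->n", C, batch.Sig, C)
        new.C, new.d = C, d
        new.S = np.diag(np.maximum(s / n_obs_total, 1e-10))
    else:
        new.C, new.d = _poisson_emission_newton(params, batches)

    if update_initial:
        mu0 = Ex0 / n_trials
        Sig0 = Ex0x0 / n_trials - np.outer(mu0, mu0)
        new.mu0 = mu0
        new.Sig0 = _floor_psd(0.5 * (Sig0 + Sig0.T))
        if K > 1:
            pi0 = np.maximum(w0 / n_trials, 1e-6)
            new.pi0 = pi0 / pi0.sum()
    return new


def _floor_psd(M, floor=COV_EIG_FLOOR):
    w, V = np.linalg.eigh(M)
    return (V * np.maximum(w, floor)) @ V.T


def _poisson_emission_newton(params: Params, batches, n_steps: int = 3):
    """Generalized M-step for softplus-Poisson emissions: backtracked Newton
    steps per neuron on the emission likelihood at the posterior means.

    The per-neuron objective is concave but has flat tails, so each Newton
    step is halved (per neuron) until the objective does not decrease."""
    H = params.H
    X = np.concatenate([np.concatenate(
        [b.m.reshape(-1, H), np.ones((b.B * b.T, 1))], axis=-1) for b in batches])
    Y = np.concatenate([b.Y.reshape(-1, params.N) for b in batches]).astype(float)
    Theta = np.concatenate([params.C, params.d[:, None]], axis=1)   # (N,H+1)

    def per_neuron_obj(Th):
        val, d1, d2 = poisson_eta_derivs(X @ Th.T, Y)
        return val.sum(axis=0), d1, d2

    obj, d1, d2 = per_neuron_obj(Theta)
    for _ in range(n_steps):
        grad = np.einsum("sn,si->ni", d1, X)
        Hess = np.einsum("sn,si,sj->nij", d2, X, X)
        Hess -= 1e-8 * np.eye(H + 1)
        step = -np.linalg.solve(Hess, grad[..., None])[..., 0]
        scale = np.ones(params.N)
        for _ls in range(15):
            cand = Theta + scale[:, None] * step
            obj_c, d1_c, d2_c = per_neuron_obj(cand)
            worse = obj_c < obj - 1e-10
            if not np.any(worse):
                break
            scale[worse] *= 0.5
        accept = obj_c >= obj - 1e-10
        Theta = np.where(accept[:, None], cand, Theta)
        obj = np.where(accept, obj_c, obj)
        _, d1, d2 = per_neuron_obj(Theta)
    return Theta[:, :H], Theta[:, H]


# --------------------------------------------------------------------------
# main loops
# --------------------------------------------------------------------------

def run_e_step(params: Params, batches: Sequence[Batch],
               learning_rate: float, n_sweeps: int = 1,
               laplace_iters: int = 4):
    """One or more damped coordinate sweeps: xi, then q(z), then q(x).

    Updating q(z) before q(x) matters: the initial continuous-state means
    carry the data-driven starting point, and a q(x) update under the
    uninformative uniform q(z) would average the mode dynamics and collapse
    that structure before the modes ever see it."""
    for _ in range(n_sweeps):
        for batch in batches:
            update_xi(params, batch)
            update_qz(params, batch, learning_rate=learning_rate)
            update_qx(params, batch, learning_rate=learning_rate,
                      laplace_iters=laplace_iters)


def total_elbo(params: Params, batches: Sequence[Batch]) -> float:
    val = float(sum(elbo_batch(params, b).sum() for b in batches))
    if not np.isfinite(val):
        raise FloatingPointError("non-finite ELBO; inference diverged")
    return val


def fit_vem(params: Params, batches: Sequence[Batch], n_iters: int,
            learning_rate: float, e_sweeps: int = 2,
            callback=None):
    """Variational EM: damped E-sweeps alternating with closed-form M-steps.

    The returned trace records the bound after each E-step (before the
    M-step), which is the monotone sequence for exact-update families.
    """
    trace = []
    for it in range(n_iters):
        # first sweep runs the Laplace solver to (near) convergence so the
        # warm-started short Newton runs of later sweeps start on target
        run_e_step(params, batches, learning_rate, n_sweeps=e_sweeps,
                   laplace_iters=25 if it == 0 else 4)
        trace.append(total_elbo(params, batches))
        params = m_step(params, batches)
        if callback is not None:
            callback(it, trace[-1], params)
    run_e_step(params, batches, learning_rate, n_sweeps=e_sweeps)
    trace.append(total_elbo(params, batches))
    return params, np.asarray(trace)
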