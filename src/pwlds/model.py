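"""Model containers and generative machinery for piecewise-linear latent dynamics.

A :class:`PWLModel` is a recurrent switching linear dynamical system (rSLDS):
a discrete mode ``z_t`` selects which of ``K`` linear dynamical laws drives the
continuous latent state ``x_t``, and the *next* mode is chosen from a
stick-breaking logistic link applied to the current continuous state,

    z_{t+1} | x_t  ~  pi_SB(R x_t + r),
    x_{t+1}        =  A_{z_{t+1}} x_t + b_{z_{t+1}} + v_t,   v_t ~ N(0, Q_{z_{t+1}}),

with either linear-Gaussian observations ``y_t = C x_t + d + w_t`` or Poisson
spike counts with a softplus rate, ``y_t ~ Poisson(softplus(C x_t + d))``.
We use the "recurrent only" variant: a single (R, r) shared by all modes, so
the mode partition is a fixed set of regions in latent space.  Setting K = 1
recovers a standard LDS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "LinearMode",
    "RecurrentTransition",
    "EmissionMap",
    "InitialState",
    "PWLModel",
    "LDSView",
    "Trial",
    "softplus",
    "softplus_inverse",
    "transition_probs",
    "simulate",
    "reduce_to_lds",
    "init_from_epoch_models",
]

#: logits are clipped at +/- LOGIT_CLIP before the logistic for numerical safety
LOGIT_CLIP = 30.0


def softplus(eta):
    """Numerically stable elementwise ``log(1 + exp(eta))``.

    Used as the rate link for Poisson emissions; strictly positive, and
    asymptotically ``eta`` for large ``eta`` and ``exp(eta)`` for very
    negative ``eta``.
    """
    eta = np.asarray(eta, dtype=float)
    # log1p(exp(-|eta|)) + max(eta, 0) is stable in both tails
    return np.log1p(np.exp(-np.abs(eta))) + np.maximum(eta, 0.0)


def softplus_inverse(rate):
    """Inverse of :func:`softplus`; input must be strictly positive."""
    rate = np.asarray(rate, dtype=float)
    if np.any(rate <= 0):
        raise ValueError("softplus_inverse requires strictly positive rates")
    # log(exp(r) - 1) = r + log(1 - exp(-r))
    return rate + np.log(-np.expm1(-rate))


def _sigmoid(v):
    v = np.clip(v, -LOGIT_CLIP, LOGIT_CLIP)
    return 1.0 / (1.0 + np.exp(-v))


@dataclass
class LinearMode:
    """One linear dynamical law ``x' = A x + b + N(0, Q)``."""

    A: np.ndarray
    b: np.ndarray
    Q: np.ndarray

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.b = np.asarray(self.b, dtype=float).ravel()
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        H = self.A.shape[0]
        if self.A.shape != (H, H) or self.b.shape != (H,) or self.Q.shape != (H, H):
            raise ValueError("inconsistent LinearMode shapes")
        if not np.allclose(self.Q, self.Q.T, atol=1e-10):
            raise ValueError("Q must be symmetric")
        if np.any(np.linalg.eigvalsh(self.Q) < -1e-10):
            raise ValueError("Q must be positive semi-definite")


@dataclass
class RecurrentTransition:
    """Shared stick-breaking transition: logits ``nu = R x + r``.

    ``stick_order[j]`` is the mode index occupying stick position ``j``; the
    last position receives the residual stick mass.  ``hard=True`` marks a
    ground-truth style model whose mode assignment is the deterministic argmax
    of the transition probabilities (hard region boundaries).
    """

    R: np.ndarray
    r: np.ndarray
    stick_order: Optional[np.ndarray] = None
    hard: bool = False

    def __post_init__(self):
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        self.r = np.asarray(self.r, dtype=float).ravel()
        K = self.R.shape[0] + 1
        if self.r.shape != (K - 1,):
            raise ValueError("R and r imply different numbers of modes")
        if self.stick_order is None:
            self.stick_order = np.arange(K)
        self.stick_order = np.asarray(self.stick_order, dtype=int)
        if sorted(self.stick_order.tolist()) != list(range(K)):
            raise ValueError("stick_order must be a permutation of 0..K-1")

    @property
    def n_modes(self) -> int:
        return self.R.shape[0] + 1


@dataclass
class EmissionMap:
    """Observation model: Gaussian ``y = Cx + d + N(0,S)`` or Poisson with
    softplus rate ``softplus(Cx + d)``."""

    C: np.ndarray
    d: np.ndarray
    family: str = "gaussian"
    S: Optional[np.ndarray] = None

    def __post_init__(self):
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        self.d = np.asarray(self.d, dtype=float).ravel()
        if self.family not in ("gaussian", "poisson"):
            raise ValueError(f"unknown emission family: {self.family!r}")
        if self.C.shape[0] != self.d.shape[0]:
            raise ValueError("C and d disagree on the number of observations")
        if self.family == "gaussian":
            if self.S is None:
                raise ValueError("gaussian emissions require a noise covariance S")
            self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
            if not np.allclose(self.S, self.S.T, atol=1e-10):
                raise ValueError("S must be symmetric")
        else:
            self.S = None

    @property
    def n_obs(self) -> int:
        return self.C.shape[0]

    def mean_response(self, x):
        """Expected observation (gaussian) or firing rate (poisson) at latent x."""
        eta = np.asarray(x) @ self.C.T + self.d
        return eta if self.family == "gaussian" else softplus(eta)


@dataclass
class InitialState:
    """Distribution of the first latent state: x_1 ~ N(mean, cov), z_1 ~ mode_probs."""

    mean: np.ndarray
    cov: np.ndarray
    mode_probs: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        self.mode_probs = np.asarray(self.mode_probs, dtype=float).ravel()
        if not np.isclose(self.mode_probs.sum(), 1.0, atol=1e-8):
            raise ValueError("initial mode probabilities must sum to 1")


@dataclass
class PWLModel:
    """K-mode piecewise-linear latent model with one emission map."""

    modes: Sequence[LinearMode]
    transition: Optional[RecurrentTransition]
    emission: EmissionMap
    initial: InitialState

    def __post_init__(self):
        self.modes = list(self.modes)
        K = len(self.modes)
        if K < 1:
            raise ValueError("need at least one mode")
        if K == 1 and self.transition is not None:
            raise ValueError("a single-mode model carries no transition parameters")
        if K > 1:
            if self.transition is None:
                raise ValueError("K>1 requires a RecurrentTransition")
            if self.transition.n_modes != K:
                raise ValueError("transition and modes disagree on K")
        H = self.modes[0].A.shape[0]
        if any(m.A.shape[0] != H for m in self.modes):
            raise ValueError("modes disagree on latent dimension")
        if self.emission.C.shape[1] != H:
            raise ValueError("emission map disagrees on latent dimension")
        if len(self.initial.mode_probs) != K:
            raise ValueError("initial mode distribution has wrong length")

    @property
    def K(self) -> int:
        return len(self.modes)

    @property
    def H(self) -> int:
        return self.modes[0].A.shape[0]

    @property
    def N(self) -> int:
        return self.emission.n_obs

    @property
    def family(self) -> str:
        return self.emission.family

    # -- convenience stacked parameter views (used by the inference engine) --
    def stacked_dynamics(self):
        A = np.stack([m.A for m in self.modes])
        b = np.stack([m.b for m in self.modes])
        Q = np.stack([m.Q for m in self.modes])
        return A, b, Q

    def mode_probabilities(self, x):
        """Transition probabilities pi_SB(R x + r) at latent position(s) x.

        For K = 1 this is identically 1.  Accepts a single H-vector or any
        (..., H) array; returns (..., K).
        """
        x = np.asarray(x, dtype=float)
        if self.K == 1:
            return np.ones(x.shape[:-1] + (1,))
        return transition_probs(x, self.transition, self.K)

    def assign_modes(self, x):
        """Deterministic mode assignment (argmax probability; ties -> lowest index)."""
        return np.argmax(self.mode_probabilities(x), axis=-1)

    def copy(self) -> "PWLModel":
        modes = [LinearMode(m.A.copy(), m.b.copy(), m.Q.copy()) for m in self.modes]
        trans = None
        if self.transition is not None:
            trans = RecurrentTransition(
                self.transition.R.copy(), self.transition.r.copy(),
                self.transition.stick_order.copy(), self.transition.hard)
        S = None if self.emission.S is None else self.emission.S.copy()
        emis = EmissionMap(self.emission.C.copy(), self.emission.d.copy(),
                           self.emission.family, S)
        init = InitialState(self.initial.mean.copy(), self.initial.cov.copy(),
                            self.initial.mode_probs.copy())
        return PWLModel(modes, trans, emis, init)


@dataclass
class Trial:
    """One simulated or recorded trial.

    ``choice`` is 1 or 2 for decided trials and ``None`` for trials that never
    left the accumulation mode; ``split`` tags benchmark membership.
    """

    observations: np.ndarray                  # (T, N)
    latents: Optional[np.ndarray] = None      # (T, H), known for synthetic data
    modes: Optional[np.ndarray] = None        # (T,) int, known for synthetic data
    choice: Optional[int] = None
    split: Optional[str] = None

    def __post_init__(self):
        self.observations = np.asarray(self.observations)
        T = self.observations.shape[0]
        if self.latents is not None:
            self.latents = np.asarray(self.latents, dtype=float)
            if self.latents.shape[0] != T:
                raise ValueError("latents and observations disagree on length")
        if self.modes is not None:
            self.modes = np.asarray(self.modes, dtype=int)
            if self.modes.shape[0] != T:
                raise ValueError("modes and observations disagree on length")
        if self.choice is not None and self.choice not in (1, 2):
            raise ValueError("choice must be 1, 2 or None")

    @property
    def T(self) -> int:
        return self.observations.shape[0]


def transition_probs(x, transition: RecurrentTransition, K: int):
    """Stick-breaking probabilities over the K modes at latent position(s) x.

    The logits ``nu = R x + r`` are split sequentially: stick position j keeps
    a fraction ``sigmoid(nu_j)`` of the remaining mass and the last position
    receives the residual.  Positions map to mode indices through
    ``transition.stick_order``.  Output rows sum to one.
    """
    if K < 2:
        raise ValueError("stick-breaking transitions need K >= 2")
    if transition.n_modes != K:
        raise ValueError("transition parameters disagree with K")
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != transition.R.shape[1]:
        raise ValueError("latent dimension mismatch in transition_probs")
    nu = x @ transition.R.T + transition.r          # (..., K-1)
    sig = _sigmoid(nu)
    # remaining stick mass before each position, then the residual at the end
    log_remain = np.cumsum(np.log1p(-sig + 1e-300), axis=-1)
    remain = np.concatenate(
        [np.ones(nu.shape[:-1] + (1,)), np.exp(log_remain)], axis=-1)
    probs_pos = np.concatenate([sig, np.ones(nu.shape[:-1] + (1,))], axis=-1)
    probs_pos = probs_pos * remain
    probs = np.empty_like(probs_pos)
    probs[..., transition.stick_order] = probs_pos
    # renormalize away accumulated rounding
    return probs / probs.sum(axis=-1, keepdims=True)


def _cov_factor(Q):
    """Matrix square root of a PSD covariance (tolerates exact zeros)."""
    w, V = np.linalg.eigh(np.atleast_2d(Q))
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def simulate(model: PWLModel, T: int, x0=None, z0=None, rng=None) -> Trial:
    """Generate one trial of length T from the model.

    Alternates the stick-breaking mode draw and the selected mode's linear
    update, then emits Gaussian vectors or Poisson counts.  With
    ``transition.hard`` (ground-truth style models) the next mode is the
    deterministic argmax of the transition probabilities, so the mode sequence
    is a deterministic function of the continuous trajectory.
    """
    if T < 1:
        raise ValueError("T must be at least 1")
    rng = np.random.default_rng(rng)
    H, K = model.H, model.K
    A, b, _ = model.stacked_dynamics()
    Lq = [_cov_factor(m.Q) for m in model.modes]

    x = np.empty((T, H))
    z = np.empty(T, dtype=int)
    if z0 is None:
        z[0] = rng.choice(K, p=model.initial.mode_probs)
    else:
        z[0] = int(z0)
    if x0 is None:
        x[0] = model.initial.mean + _cov_factor(model.initial.cov) @ rng.standard_normal(H)
    else:
        x[0] = np.asarray(x0, dtype=float)

    hard = model.K > 1 and model.transition.hard
    for t in range(T - 1):
        if K == 1:
            z[t + 1] = 0
        else:
            p = model.mode_probabilities(x[t])
            z[t + 1] = int(np.argmax(p)) if hard else int(rng.choice(K, p=p))
        k = z[t + 1]
        x[t + 1] = A[k] @ x[t] + b[k] + Lq[k] @ rng.standard_normal(H)

    eta = x @ model.emission.C.T + model.emission.d
    if model.family == "gaussian":
        Ls = _cov_factor(model.emission.S)
        y = eta + rng.standard_normal(eta.shape) @ Ls.T
    else:
        y = rng.poisson(softplus(eta)).astype(np.int64)
    return Trial(observations=y, latents=x, modes=z)


@dataclass
class LDSView:
    """Plain linear(-Gaussian or -Poisson) state-space view of a K=1 model.

    Exposes the flat parameter set (A, b, Q, C, d[, S]); simulation, inference
    and forecasting delegate to the underlying single-mode model, so results
    are identical by construction.
    """

    model: PWLModel

    def __post_init__(self):
        if self.model.K != 1:
            raise ValueError("LDS view requires a single-mode (K=1) model")

    @property
    def A(self):
        return self.model.modes[0].A

    @property
    def b(self):
        return self.model.modes[0].b

    @property
    def Q(self):
        return self.model.modes[0].Q

    @property
    def C(self):
        return self.model.emission.C

    @property
    def d(self):
        return self.model.emission.d

    @property
    def S(self):
        return self.model.emission.S

    def simulate(self, T, x0=None, rng=None) -> Trial:
        return simulate(self.model, T, x0=x0, z0=0, rng=rng)


def reduce_to_lds(model: PWLModel) -> LDSView:
    """Expose a K=1 model as a plain LDS; raises for K > 1."""
    return LDSView(model)


def init_from_epoch_models(lds_a: PWLModel, lds_b: PWLModel,
                           trials_a, trials_b,
                           boundary_sharpness: float = 10.0) -> PWLModel:
    """Build a 2-mode initialization from two single-mode models fit to
    different task epochs.

    The two modes carry the epoch models' dynamics, and the shared
    stick-breaking boundary is the perpendicular bisector of the segment
    joining the two epochs' latent-trajectory midpoints, oriented so each
    midpoint falls inside its own mode's region.  ``trials_a`` / ``trials_b``
    are sequences of (T, H) latent trajectories for the respective epochs.
    """
    if lds_a.K != 1 or lds_b.K != 1:
        raise ValueError("epoch models must be single-mode (K=1)")
    if lds_a.H != lds_b.H:
        raise ValueError("epoch models must share the latent dimension")
    mid_a = np.mean(np.concatenate([np.asarray(t).reshape(-1, lds_a.H) for t in trials_a]), axis=0)
    mid_b = np.mean(np.concatenate([np.asarray(t).reshape(-1, lds_b.H) for t in trials_b]), axis=0)
    w = mid_a - mid_b
    norm = np.linalg.norm(w)
    if norm < 1e-12:
        raise ValueError("epoch midpoints coincide; boundary undefined")
    w_hat = w / norm
    center = 0.5 * (mid_a + mid_b)
    # nu > 0 on mid_a's side of the bisector -> stick position 0 = mode A
    R = boundary_sharpness * w_hat[None, :]
    r = np.array([-boundary_sharpness * float(w_hat @ center)])
    transition = RecurrentTransition(R, r)
    modes = [LinearMode(lds_a.modes[0].A.copy(), lds_a.modes[0].b.copy(), lds_a.modes[0].Q.copy()),
             LinearMode(lds_b.modes[0].A.copy(), lds_b.modes[0].b.copy(), lds_b.modes[0].Q.copy())]
    emis = lds_a.emission
    S = None if emis.S is None else emis.S.copy()
    emission = EmissionMap(emis.C.copy(), emis.d.copy(), emis.family, S)
    initial = InitialState(lds_a.initial.mean.copy(), lds_a.initial.cov.copy(),
                           np.array([0.5, 0.5]))
    return PWLModel(modes, transition, emission, initial)
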