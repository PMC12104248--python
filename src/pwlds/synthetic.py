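"""Ground-truth decision simulator and synthetic trial datasets.

The generator emulates two-alternative perceptual decision dynamics as a
three-mode piecewise-linear system in a 2-D latent space:

* **Mode 1 (accumulation)** — trials start at the origin and drift along the
  diagonal (equal average evidence for both options) while process noise
  accumulates a difference between the two coordinates.
* **Modes 2 and 3 (commitment)** — once the absolute coordinate difference
  exceeds the switch threshold (one latent unit), the state enters one of two
  point-attractor modes, contracting toward (1, 6) or (6, 1).

The terminal mode defines the simulated choice.  Latent trajectories are
observed either as Gaussian vectors or as per-bin Poisson spike counts from a
population of simulated neurons with heterogeneous mean rates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .model import (
    EmissionMap,
    InitialState,
    LinearMode,
    PWLModel,
    RecurrentTransition,
    Trial,
    softplus,
    transition_probs,
)

__all__ = [
    "GroundTruthSpec",
    "EmissionCalibration",
    "TrialSet",
    "build_default_truth",
    "calibrate_emissions",
    "make_dataset",
    "simulate_latent_batch",
    "CHOICE_OF_MODE",
]

#: terminal mode index -> reported choice label (config constant)
CHOICE_OF_MODE = {1: 1, 2: 2}

#: slope of the stick-breaking logits of the ground truth; large enough that
#: the mode regions are effectively hard within ~0.2 latent units of the
#: boundary, small enough to stay clear of the logit clip
BOUNDARY_SHARPNESS = 25.0


@dataclass
class GroundTruthSpec:
    """Parameters of the three-mode ground-truth decision model.

    Attractor locations, the switch threshold and the origin start are the
    reference configuration; drift, contraction, noise levels and trial
    length are free simulation choices exposed here.
    """

    latent_dim: int = 2
    n_modes: int = 3
    attractor_1: tuple = (1.0, 6.0)
    attractor_2: tuple = (6.0, 1.0)
    switch_threshold: float = 1.0
    start_state: tuple = (0.0, 0.0)
    mode1_drift: float = 0.2            # per-bin drift of each coordinate
    mode_contraction: float = 0.9       # A = a*I in the attractor modes
    process_noise_var: float = 0.04     # accumulation-mode isotropic noise
    attractor_noise_var: float = 1e-3   # attractor-mode isotropic noise
    trial_length: int = 50              # bins per trial

    def validate(self):
        if self.latent_dim != 2 or self.n_modes != 3:
            raise ValueError("the reference ground truth is 2-D with 3 modes")
        if not (0.0 < self.mode_contraction < 1.0):
            raise ValueError("mode_contraction must lie in (0, 1)")
        if self.switch_threshold <= 0:
            raise ValueError("switch_threshold must be positive")
        for a, name in ((self.attractor_1, "attractor_1"), (self.attractor_2, "attractor_2")):
            if abs(a[0] - a[1]) <= self.switch_threshold:
                raise ValueError(
                    f"{name} lies inside the accumulation band |x1-x2| <= threshold")
        if self.attractor_1[1] - self.attractor_1[0] <= self.switch_threshold:
            raise ValueError("attractor_1 must lie in the x2 - x1 > threshold region")
        if self.attractor_2[0] - self.attractor_2[1] <= self.switch_threshold:
            raise ValueError("attractor_2 must lie in the x1 - x2 > threshold region")
        s = self.start_state
        if abs(s[0] - s[1]) > self.switch_threshold:
            raise ValueError("start_state must lie in the accumulation band")
        if self.trial_length < 2:
            raise ValueError("trial_length must be at least 2")


@dataclass
class EmissionCalibration:
    """How latent trajectories are observed.

    For ``family='poisson'``, ``target_mean_rate`` is the grand-mean spike
    count per bin across neurons, and ``rate_pct10`` / ``rate_pct90`` set the
    spread of per-neuron mean rates (log-normal across neurons).  For
    ``family='gaussian'``, ``noise_variance`` is the isotropic observation
    noise variance.
    """

    n_observations: int = 5
    family: str = "gaussian"
    noise_variance: float = 0.01
    target_mean_rate: float = 2.0
    rate_pct10: float = 0.1
    rate_pct90: float = 5.0
    latent_gain_sd: float = 1.0   # sd of the pre-offset drive c_n . x per neuron

    def validate(self):
        if self.n_observations < 1:
            raise ValueError("need at least one observation dimension")
        if self.family not in ("gaussian", "poisson"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "gaussian" and self.noise_variance <= 0:
            raise ValueError("gaussian noise variance must be positive")
        if self.family == "poisson":
            if self.target_mean_rate <= 0:
                raise ValueError("target mean rate must be positive")
            if not (0 < self.rate_pct10 < self.rate_pct90):
                raise ValueError("need 0 < rate_pct10 < rate_pct90")


class TrialSet:
    """A collection of trials plus the provenance needed to regenerate it."""

    def __init__(self, trials: Sequence[Trial], family: str,
                 seed: Optional[int] = None,
                 ground_truth_spec: Optional[dict] = None,
                 emission_calibration: Optional[dict] = None):
        self.trials = list(trials)
        self.family = family
        self.seed = seed
        self.ground_truth_spec = ground_truth_spec
        self.emission_calibration = emission_calibration

    def __len__(self):
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]

    def split(self, name: str) -> "TrialSet":
        """Sub-set of trials carrying the given split tag."""
        sub = [t for t in self.trials if t.split == name]
        return TrialSet(sub, self.family, self.seed,
                        self.ground_truth_spec, self.emission_calibration)

    def split_counts(self) -> dict:
        counts: dict = {}
        for t in self.trials:
            counts[t.split] = counts.get(t.split, 0) + 1
        return counts

    def decided(self) -> "TrialSet":
        """Trials with a defined choice label."""
        sub = [t for t in self.trials if t.choice is not None]
        return TrialSet(sub, self.family, self.seed,
                        self.ground_truth_spec, self.emission_calibration)


def build_default_truth(spec: Optional[GroundTruthSpec] = None,
                        emission: Optional[EmissionMap] = None) -> PWLModel:
    """Construct the three-mode ground-truth model from a spec.

    Mode 1 (index 0) is the accumulation mode: identity dynamics plus a
    diagonal drift and isotropic process noise.  Modes 2 and 3 (indices 1, 2)
    contract with factor ``mode_contraction`` toward the configured
    attractors, so
    their fixed points ``(I - A)^{-1} b`` equal the attractors exactly and all
    eigenvalues of A have modulus below one (asymptotically stable).

    The stick-breaking transition encodes the hard region rule: Mode 2 iff
    ``x2 - x1 > threshold``, Mode 3 iff ``x1 - x2 > threshold``, Mode 1 on the
    (closed) band in between.  A placeholder single-observation Gaussian
    emission is attached when none is given; calibrated emissions normally
    replace it via :func:`calibrate_emissions` / :func:`make_dataset`.
    """
    spec = spec or GroundTruthSpec()
    spec.validate()
    a = spec.mode_contraction
    a1 = np.asarray(spec.attractor_1, dtype=float)
    a2 = np.asarray(spec.attractor_2, dtype=float)
    I2 = np.eye(2)
    modes = [
        LinearMode(I2, np.full(2, spec.mode1_drift), spec.process_noise_var * I2),
        LinearMode(a * I2, (1 - a) * a1, spec.attractor_noise_var * I2),
        LinearMode(a * I2, (1 - a) * a2, spec.attractor_noise_var * I2),
    ]
    s = BOUNDARY_SHARPNESS
    th = spec.switch_threshold
    # stick position 0 -> Mode 2, position 1 -> Mode 3, residual -> Mode 1;
    # the tiny logit offset keeps boundary points (|x1-x2| = threshold) in Mode 1
    eps = 1e-9
    R = np.array([[-s, s], [s, -s]])
    r = np.array([-s * th - eps, -s * th - eps])
    transition = RecurrentTransition(R, r, stick_order=np.array([1, 2, 0]), hard=True)
    if emission is None:
        emission = EmissionMap(C=np.ones((1, 2)), d=np.zeros(1), family="gaussian",
                               S=np.eye(1))
    initial = InitialState(np.asarray(spec.start_state, dtype=float),
                           np.zeros((2, 2)), np.array([1.0, 0.0, 0.0]))
    return PWLModel(modes, transition, emission, initial)


def simulate_latent_batch(truth: PWLModel, n_trials: int, T: int, rng) -> tuple:
    """Vectorized simulation of latent trajectories and modes from the truth.

    Returns ``(x, z)`` with shapes (n_trials, T, H) and (n_trials, T).
    Transitions follow the model's hard/stochastic convention.
    """
    rng = np.random.default_rng(rng)
    H, K = truth.H, truth.K
    A, b, _ = truth.stacked_dynamics()
    Lq = np.stack([_psd_factor(m.Q) for m in truth.modes])
    x = np.empty((n_trials, T, H))
    z = np.empty((n_trials, T), dtype=int)
    init_cov = truth.initial.cov
    x[:, 0] = truth.initial.mean + rng.standard_normal((n_trials, H)) @ _psd_factor(init_cov).T
    z[:, 0] = rng.choice(K, size=n_trials, p=truth.initial.mode_probs)
    hard = truth.K > 1 and truth.transition.hard
    for t in range(T - 1):
        if K == 1:
            znext = np.zeros(n_trials, dtype=int)
        else:
            p = truth.mode_probabilities(x[:, t])           # (B, K)
            if hard:
                znext = np.argmax(p, axis=-1)
            else:
                u = rng.random(n_trials)[:, None]
                znext = (np.cumsum(p, axis=-1) < u).sum(axis=-1)
        z[:, t + 1] = znext
        noise = rng.standard_normal((n_trials, H))
        xn = np.einsum("bij,bj->bi", A[znext], x[:, t]) + b[znext]
        x[:, t + 1] = xn + np.einsum("bij,bj->bi", Lq[znext], noise)
    return x, z


def _psd_factor(Q):
    w, V = np.linalg.eigh(np.atleast_2d(Q))
    return V * np.sqrt(np.clip(w, 0.0, None))


def calibrate_emissions(cal: EmissionCalibration, truth: PWLModel,
                        rng_seed=None, n_calibration_trials: int = 100,
                        trial_length: int = 50) -> EmissionMap:
    """Choose emission parameters (C, d[, S]) matching the calibration target.

    Gaussian: rows of C are random directions of unit expected norm and the
    noise covariance is ``noise_variance * I``.

    Poisson: per-neuron mean rates are drawn log-normally across neurons so
    that their 10th/90th percentiles match the configured spread, then
    rescaled to hit the grand-mean target exactly in sample.  Each neuron gets
    a random latent direction with a drive sd of ``latent_gain_sd``, and its
    offset ``d_n`` is solved by bisection so the time-averaged
    ``softplus(c_n . x + d_n)`` over simulated ground-truth trajectories
    equals the neuron's target rate.
    """
    cal.validate()
    rng = np.random.default_rng(rng_seed)
    N, H = cal.n_observations, truth.H

    if cal.family == "gaussian":
        C = rng.standard_normal((N, H)) / np.sqrt(H)
        d = np.zeros(N)
        S = cal.noise_variance * np.eye(N)
        return EmissionMap(C, d, "gaussian", S)

    # Poisson: simulate latent trajectories for rate calibration
    x, _ = simulate_latent_batch(truth, n_calibration_trials, trial_length, rng)
    X = x.reshape(-1, H)

    # per-neuron target mean rates: log-normal spread hitting the percentile
    # ratio.  Stratified quantile sampling (shuffled across neurons) keeps the
    # sample percentiles on target; the final rescale pins the grand mean.
    from scipy.stats import norm as _norm
    z90 = _norm.ppf(0.9)
    sigma = np.log(cal.rate_pct90 / cal.rate_pct10) / (2 * z90)
    mu = np.log(cal.target_mean_rate) - 0.5 * sigma ** 2
    zq = _norm.ppf((np.arange(N) + 0.5) / N)
    m = np.exp(mu + sigma * zq)
    rng.shuffle(m)
    m *= cal.target_mean_rate / m.mean()

    # random unit directions scaled so sd(c_n . x) = latent_gain_sd
    U = rng.standard_normal((N, H))
    U /= np.linalg.norm(U, axis=1, keepdims=True)
    drive = X @ U.T                                     # (samples, N)
    sd = drive.std(axis=0)
    sd[sd < 1e-9] = 1.0
    gain = cal.latent_gain_sd / sd
    drive = drive * gain

    # bisection on the offset: mean softplus(drive + d) is monotone in d
    # (upper bound must clear the highest per-neuron target rate)
    lo = np.full(N, -60.0)
    hi = np.full(N, max(60.0, 3.0 * float(m.max())))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        mean_rate = softplus(drive + mid).mean(axis=0)
        too_high = mean_rate > m
        hi = np.where(too_high, mid, hi)
        lo = np.where(too_high, lo, mid)
    d = 0.5 * (lo + hi)
    C = U * gain[:, None]

    achieved = softplus(X @ C.T + d).mean()
    if not np.isfinite(achieved) or abs(achieved - cal.target_mean_rate) > 0.05 * cal.target_mean_rate:
        raise RuntimeError(
            f"emission calibration failed: achieved grand-mean rate {achieved:.3f} "
            f"vs target {cal.target_mean_rate:.3f}")
    return EmissionMap(C, d, "poisson", None)


def _split_counts(n: int, ratios) -> list:
    """Integer split sizes: floor allocation, remainder to the largest shares."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.min() < 0 or abs(ratios.sum() - 1.0) > 1e-8:
        raise ValueError("split ratios must be non-negative and sum to 1")
    raw = n * ratios
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    for i in range(rem):
        base[order[i]] += 1
    return base.tolist()


def make_dataset(truth: PWLModel, emission: EmissionMap,
                 n_trials: int = 250,
                 split_ratios=(0.7, 0.1, 0.2),
                 rng_seed=None,
                 trial_length: Optional[int] = None,
                 spec: Optional[GroundTruthSpec] = None,
                 calibration: Optional[EmissionCalibration] = None) -> TrialSet:
    """Simulate a dataset of trials from the ground truth with emissions.

    Each trial carries the choice implied by its terminal mode (Mode 2 ->
    choice 1, Mode 3 -> choice 2); trials that never leave the accumulation
    mode keep an unset choice and are retained with a warning.  Split tags
    (train/validation/test) are assigned by a seeded shuffle with integer
    counts matching the ratios (7:1:2 on 250 trials gives 175/25/50).
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(rng_seed)
    T = trial_length or (spec.trial_length if spec is not None else 50)
    model = PWLModel(truth.modes, truth.transition, emission, truth.initial)
    x, z = simulate_latent_batch(model, n_trials, T, rng)

    eta = x @ emission.C.T + emission.d
    if emission.family == "gaussian":
        Ls = _psd_factor(emission.S)
        y = eta + rng.standard_normal(eta.shape) @ Ls.T
    else:
        y = rng.poisson(softplus(eta)).astype(np.int64)

    counts = _split_counts(n_trials, split_ratios)
    tags = np.array(["train"] * counts[0] + ["validation"] * counts[1] + ["test"] * counts[2],
                    dtype=object)
    tags = tags[rng.permutation(n_trials)]

    trials = []
    n_undecided = 0
    for i in range(n_trials):
        terminal = int(z[i, -1])
        choice = CHOICE_OF_MODE.get(terminal)
        if choice is None:
            n_undecided += 1
        trials.append(Trial(observations=y[i], latents=x[i], modes=z[i],
                            choice=choice, split=str(tags[i])))
    if n_undecided:
        warnings.warn(f"{n_undecided} of {n_trials} trials never left the "
                      "accumulation mode; their choice is unset", stacklevel=2)
    seed_repr = rng_seed if isinstance(rng_seed, (int, np.integer)) else None
    return TrialSet(trials, emission.family, seed=seed_repr,
                    ground_truth_spec=asdict(spec) if spec is not None else None,
                    emission_calibration=asdict(calibration) if calibration is not None else None)
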