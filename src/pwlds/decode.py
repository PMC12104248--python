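"""Choice-information embedding and per-time-step choice decoding.

The difference-response matrix ``D = 0.5 (xbar_choice1 - xbar_choice2)``
collects, per time step, half the difference of the choice-conditioned
trial-averaged latent trajectories.  Its rows are samples of the direction
in which choice information lives; a PCA on these rows yields a 2-D
projection that preserves choice separability.  Decodability itself is
measured by training a linear SVM per time step on 90% of trials' latent
states and scoring the held-out 10%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

__all__ = [
    "difference_response",
    "ChoiceEmbedding",
    "fit_choice_embedding",
    "DecodingCurve",
    "decode_choice_timecourse",
]


def difference_response(latents_choice1, latents_choice2) -> np.ndarray:
    """Half-difference of choice-conditioned trial-averaged latents, (T, L).

    Trials are truncated to the shortest common length (with a warning when
    truncation occurs); each group must be non-empty.
    """
    g1 = [np.atleast_2d(np.asarray(x, dtype=float)) for x in latents_choice1]
    g2 = [np.atleast_2d(np.asarray(x, dtype=float)) for x in latents_choice2]
    if not g1 or not g2:
        raise ValueError("both choice groups must be non-empty")
    T = min(x.shape[0] for x in g1 + g2)
    if any(x.shape[0] != T for x in g1 + g2):
        warnings.warn(f"truncating trials to the common length {T}", stacklevel=2)
    m1 = np.mean([x[:T] for x in g1], axis=0)
    m2 = np.mean([x[:T] for x in g2], axis=0)
    return 0.5 * (m1 - m2)


@dataclass
class ChoiceEmbedding:
    """2-D choice-preserving projection fitted on difference-response rows."""

    components: np.ndarray               # (2, L)
    explained_variance_ratio: np.ndarray

    def transform(self, latents):
        """Project (..., L) latents onto the 2-D choice plane."""
        return np.asarray(latents, dtype=float) @ self.components.T


def fit_choice_embedding(D: np.ndarray, center: bool = True) -> ChoiceEmbedding:
    """PCA basis of the difference-response rows; top two components.

    Rows are centered by default (standard PCA convention).  A rank-zero D
    (identical choice-conditioned means) carries no choice direction and is
    rejected.
    """
    D = np.atleast_2d(np.asarray(D, dtype=float))
    if D.shape[0] < 2:
        raise ValueError("need at least two time steps to fit the embedding")
    if D.shape[1] < 2:
        raise ValueError("latent dimension must be at least 2")
    Dc = D - D.mean(axis=0) if center else D
    if np.linalg.matrix_rank(np.atleast_2d(Dc), tol=1e-12) == 0:
        raise ValueError("difference response has rank 0: no choice direction")
    # sklearn's PCA always centers; emulate the uncentered variant by a plain
    # SVD on the raw rows when centering is switched off
    if center:
        pca = PCA(n_components=2)
        pca.fit(D)
        comps = pca.components_.copy()
        evr = pca.explained_variance_ratio_.copy()
    else:
        _, svals, Vt = np.linalg.svd(D, full_matrices=False)
        comps = Vt[:2].copy()
        power = svals ** 2
        evr = power[:2] / power.sum()
    return ChoiceEmbedding(components=comps, explained_variance_ratio=evr)


@dataclass
class DecodingCurve:
    """Per-time-step decoding accuracy of the upcoming choice."""

    accuracy: np.ndarray          # (T,), NaN where undefined
    n_test: int
    n_dims: int
    accuracy_sd: Optional[np.ndarray] = None


def decode_choice_timecourse(latents, choices, rng_seed=None,
                             test_fraction: float = 0.1, svm_c: float = 1.0,
                             n_repeats: int = 1) -> DecodingCurve:
    """Linear-SVM decoding of choice from latent states, per time step.

    ``latents`` is (n_trials, T, L) (or a list of equal-length (T, L)
    arrays) and ``choices`` the per-trial labels.  At each time step the
    trials are split 90/10 (stratified by choice, seeded), a linear-kernel
    SVM is trained on the training latents at that time, and accuracy is the
    fraction of correctly classified held-out trials.  Time steps whose
    training split contains a single class get NaN accuracy.  With
    ``n_repeats > 1`` the split is redrawn and the mean (and sd) reported.
    """
    X = np.stack([np.asarray(x, dtype=float) for x in latents])
    y = np.asarray(choices)
    if X.ndim != 3:
        raise ValueError("latents must stack into (n_trials, T, L)")
    classes = np.unique(y)
    if len(classes) != 2 or np.min(np.bincount(np.searchsorted(classes, y))) < 2:
        raise ValueError("need at least two trials of each choice")
    n_trials, T, L = X.shape
    rng = np.random.default_rng(rng_seed)
    acc = np.full((n_repeats, T), np.nan)
    n_test = max(1, int(round(test_fraction * n_trials)))
    for rep in range(n_repeats):
        for t in range(T):
            seed_t = int(rng.integers(2 ** 31 - 1))
            tr_ix, te_ix = train_test_split(
                np.arange(n_trials), test_size=test_fraction,
                random_state=seed_t, stratify=y)
            if len(np.unique(y[tr_ix])) < 2:
                continue
            clf = SVC(kernel="linear", C=svm_c)
            clf.fit(X[tr_ix, t], y[tr_ix])
            acc[rep, t] = clf.score(X[te_ix, t], y[te_ix])
    mean_acc = np.nanmean(acc, axis=0) if n_repeats > 1 else acc[0]
    sd = np.nanstd(acc, axis=0) if n_repeats > 1 else None
    return DecodingCurve(accuracy=mean_acc, n_test=n_test, n_dims=L,
                         accuracy_sd=sd)
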