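"""Forecast-quality metrics for continuous and spike-count observations.

* ``med`` — mean Euclidean distance between predicted and observed vectors.
* ``r2_euclidean`` — multi-dimensional coefficient of determination based on
  Euclidean distances, with the time-mean vector as the null predictor.
* ``poisson_deviance`` / ``r2_deviance_poisson`` — deviance-based pseudo-R²
  for independent per-neuron Poisson counts.  Note the deviance convention
  here is ``y log(y/mu) - (y - mu)`` (no factor 2); the factor would cancel
  in the R² ratio anyway.
* ``expected_r2_poisson`` — the ceiling on the deviance R² attainable by a
  model with exactly correct rates, obtained by replacing each observed
  deviance with its expectation under Poisson(rate).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import gammaln, xlogy

__all__ = [
    "med",
    "r2_euclidean",
    "poisson_deviance",
    "r2_deviance_poisson",
    "expected_poisson_deviance",
    "expected_r2_poisson",
]


def _check_pair(observed, predicted):
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.ndim == 1:
        observed = observed[:, None]
    if predicted.ndim == 1:
        predicted = predicted[:, None]
    if observed.shape != predicted.shape:
        raise ValueError(
            f"observed {observed.shape} and predicted {predicted.shape} shapes differ")
    return observed, predicted


def med(observed, predicted) -> float:
    """Mean over time of the Euclidean norm of the residual vectors."""
    observed, predicted = _check_pair(observed, predicted)
    if observed.shape[0] < 1:
        raise ValueError("need at least one time point")
    return float(np.linalg.norm(observed - predicted, axis=1).mean())


def r2_euclidean(observed, predicted) -> float:
    """Multi-dimensional R²: 1 - SS_res / SS_tot with Euclidean norms.

    The null predictor is the time-mean of the observed vectors, so a
    constant-mean forecast scores exactly 0 and a perfect forecast scores 1.
    Constant observations make the denominator vanish; that is flagged and
    returned as NaN.
    """
    observed, predicted = _check_pair(observed, predicted)
    if observed.shape[0] < 2:
        raise ValueError("r2_euclidean needs at least two time points")
    ybar = observed.mean(axis=0)
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - ybar) ** 2))
    if ss_tot <= 0:
        warnings.warn("constant observations: multi-dimensional R² undefined",
                      stacklevel=2)
        return float("nan")
    return 1.0 - ss_res / ss_tot


def poisson_deviance(y, mu):
    """Per-cell Poisson deviance ``y log(y/mu) - (y - mu)`` (convention 0*log 0 = 0).

    Non-negative, zero iff y == mu.  Accepts scalars or arrays (broadcast).
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("predicted rates must be strictly positive")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    dev = xlogy(y, y / mu) - (y - mu)
    out = np.maximum(dev, 0.0)  # clip tiny negative rounding at y == mu
    return float(out) if out.ndim == 0 else out


def r2_deviance_poisson(observed, predicted_rates, return_parts: bool = False):
    """Deviance-based pseudo-R² for multi-neuron Poisson counts.

    ``observed`` are counts and ``predicted_rates`` strictly positive rates,
    both (T, N).  The null model is each neuron's mean count over time;
    neurons whose counts are all zero have an undefined null deviance and are
    excluded with a warning.
    """
    observed, predicted_rates = _check_pair(observed, predicted_rates)
    ybar = observed.mean(axis=0)
    keep = ybar > 0
    if not np.all(keep):
        warnings.warn(f"excluding {int((~keep).sum())} all-zero neuron(s) from "
                      "the deviance R²", stacklevel=2)
    if not np.any(keep):
        raise ValueError("no neuron with positive mean count")
    y = observed[:, keep]
    mu = predicted_rates[:, keep]
    num = float(poisson_deviance(y, mu).sum())
    den = float(poisson_deviance(y, np.broadcast_to(ybar[keep], y.shape)).sum())
    if den <= 0:
        warnings.warn("null deviance is zero: deviance R² undefined", stacklevel=2)
        return float("nan")
    r2 = 1.0 - num / den
    if return_parts:
        return r2, num, den
    return r2


def expected_poisson_deviance(mu):
    """E_{y ~ Poisson(mu)}[D(y, mu)] by a truncated series.

    The series is summed to ``ceil(mu + 10 sqrt(mu) + 20)``, where the tail
    is negligible (< 1e-12 for mu <= 100).  Approaches 1/2 as mu grows
    (second-order expansion of the deviance).  Accepts scalars or arrays.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("rates must be strictly positive")
    scalar = mu.ndim == 0
    flat = np.atleast_1d(mu).ravel()
    out = np.empty_like(flat)
    ymax = int(np.ceil(flat.max() + 10 * np.sqrt(flat.max()) + 20))
    y = np.arange(ymax + 1, dtype=float)
    # process in chunks to bound the (cells x ymax) table
    chunk = max(1, int(2_000_000 / (ymax + 1)))
    for start in range(0, flat.size, chunk):
        m = flat[start:start + chunk][:, None]
        logp = xlogy(y, m) - m - gammaln(y + 1.0)
        dev = xlogy(y, y / m) - (y - m)
        out[start:start + chunk] = np.sum(np.exp(logp) * dev, axis=1)
    out = out.reshape(np.atleast_1d(mu).shape)
    return float(out[0]) if scalar else out


def expected_r2_poisson(observed, predicted_rates) -> float:
    """Ceiling R²: numerator deviances replaced by their Poisson expectations.

    The denominator is the observed null deviance (per-neuron mean counts),
    unchanged; all-zero neurons are excluded as in :func:`r2_deviance_poisson`.
    """
    observed, predicted_rates = _check_pair(observed, predicted_rates)
    if np.any(predicted_rates <= 0):
        raise ValueError("predicted rates must be strictly positive")
    ybar = observed.mean(axis=0)
    keep = ybar > 0
    if not np.any(keep):
        raise ValueError("no neuron with positive mean count")
    y = observed[:, keep]
    mu = predicted_rates[:, keep]
    num = float(expected_poisson_deviance(mu).sum())
    den = float(poisson_deviance(y, np.broadcast_to(ybar[keep], y.shape)).sum())
    if den <= 0:
        warnings.warn("null deviance is zero: expected R² undefined", stacklevel=2)
        return float("nan")
    return 1.0 - num / den
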