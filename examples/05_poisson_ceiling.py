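"""Deviance pseudo-R² for spike counts and its Poisson ceiling.

Even a model with exactly correct firing rates cannot predict individual
Poisson counts; the expected R² quantifies that ceiling.  This example
scores the true rates of a simulated spike-count dataset.
"""

import warnings

import numpy as np

from pwlds import (EmissionCalibration, GroundTruthSpec, build_default_truth,
                   calibrate_emissions, make_dataset, metrics, softplus)

warnings.filterwarnings("ignore")

truth = build_default_truth(GroundTruthSpec())
cal = EmissionCalibration(n_observations=100, family="poisson",
                          target_mean_rate=2.0)
emission = calibrate_emissions(cal, truth, rng_seed=0)
ts = make_dataset(truth, emission, n_trials=100, rng_seed=1)

counts = np.concatenate([t.observations for t in ts])
lat = np.concatenate([t.latents for t in ts])
rates = softplus(lat @ emission.C.T + emission.d)

print(f"grand-mean rate: {counts.mean():.2f} spikes/bin "
      f"(10th pct {np.percentile(counts.mean(0), 10):.2f}, "
      f"90th pct {np.percentile(counts.mean(0), 90):.2f})")
r2 = metrics.r2_deviance_poisson(counts, rates)
ceiling = metrics.expected_r2_poisson(counts, rates)
print(f"deviance R² of the true rates: {r2:.3f}")
print(f"expected (ceiling) R²:         {ceiling:.3f}")
print(f"E[D] per cell at rate 1: {metrics.expected_poisson_deviance(1.0):.3f} "
      f"(approaches 0.5 for large rates: "
      f"{metrics.expected_poisson_deviance(1e4):.3f})")
# Interpretation: the achieved R² of perfect rates matches the ceiling up to
# sampling error; fitted models are judged against this ceiling, not
# against 1.
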