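"""Comparison protocol: restart selection, forecast scoring, rank tests and
fit-quality histograms."""

import warnings

import numpy as np
import pandas as pd
import pytest

from pwlds.benchmark import (
    FitEnsemble,
    compare_forecasts,
    evaluate_predictions,
    multi_restart_fit,
    quality_histogram,
    wilcoxon_compare,
)
from pwlds.model import (
    EmissionMap,
    InitialState,
    LinearMode,
    PWLModel,
    RecurrentTransition,
)
from pwlds.synthetic import GroundTruthSpec, build_default_truth, make_dataset


class TestWilcoxon:
    def test_identical_samples_no_advantage(self):
        x = np.arange(10.0)
        out = wilcoxon_compare(x, x)
        assert out["pvalue"] == 1.0 and out["advantage"] == "none"

    def test_constant_shift_strongly_significant(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=50)
        out = wilcoxon_compare(base, base + 1.0)
        assert out["pvalue"] < 1e-3
        assert out["advantage"] == "rslds"

    def test_direction_flips_with_metric_sense(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=30)
        better_high = wilcoxon_compare(base, base + 1.0, better="higher")
        better_low = wilcoxon_compare(base, base + 1.0, better="lower")
        assert better_high["advantage"] == "rslds"
        assert better_low["advantage"] == "lds"

    def test_swap_symmetry(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=40)
        b = a + rng.normal(size=40) + 0.4
        ab = wilcoxon_compare(a, b)
        ba = wilcoxon_compare(b, a)
        assert ab["pvalue"] == pytest.approx(ba["pvalue"])
        assert {ab["advantage"], ba["advantage"]} == {"rslds", "lds"}

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_compare([1.0, 2.0], [2.0, 3.0])


@pytest.fixture(scope="module")
def noiseless_setup():
    """Noiseless ground truth and a small dataset generated from it."""
    spec = GroundTruthSpec(process_noise_var=0.0, attractor_noise_var=0.0)
    truth = build_default_truth(spec)
    C = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
    emission = EmissionMap(C, np.zeros(3), "gaussian", 1e-12 * np.eye(3))
    model = PWLModel(truth.modes, truth.transition, emission, truth.initial)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ts = make_dataset(truth, emission, n_trials=10, rng_seed=0,
                          trial_length=25)
    return model, ts


class TestEvaluatePredictions:
    def test_true_model_noiseless_perfect(self, noiseless_setup):
        """The generating model forecasts noiseless data exactly."""
        model, ts = noiseless_setup
        df = evaluate_predictions(model, list(ts)[:5], horizons=[1, 3],
                                  n_samples=5, rng_seed=0)
        r2 = df[df.metric == "r2"].value
        med = df[df.metric == "med"].value
        assert np.all(r2 > 1 - 1e-6)
        assert np.all(med < 1e-4)

    def test_frame_is_tidy_with_expected_columns(self, noiseless_setup):
        model, ts = noiseless_setup
        df = evaluate_predictions(model, list(ts)[:3], horizons=[1, 2],
                                  n_samples=5, rng_seed=0,
                                  spaces=("observation", "latent"))
        assert set(df.columns) == {"model", "family", "trial", "horizon",
                                   "metric", "space", "value"}
        assert set(df.horizon) == {1, 2}
        assert set(df.space) == {"observation", "latent"}

    def test_horizon_exceeding_trials_rejected(self, noiseless_setup):
        model, ts = noiseless_setup
        with pytest.raises(ValueError, match="horizon"):
            evaluate_predictions(model, list(ts)[:2], horizons=[40],
                                 n_samples=3, rng_seed=0)

    def test_poisson_expected_r2_is_a_ceiling(self, truth):
        """The expected (ceiling) R² upper-bounds the achieved deviance R²
        in expectation, even when forecasting with the generating model; the
        residual gap is the filter's estimation error."""
        from pwlds.synthetic import EmissionCalibration, calibrate_emissions
        cal = EmissionCalibration(n_observations=40, family="poisson",
                                  target_mean_rate=2.0)
        em = calibrate_emissions(cal, truth, rng_seed=1)
        model = PWLModel(truth.modes, truth.transition, em, truth.initial)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ts = make_dataset(truth, em, n_trials=25, rng_seed=2)
            df = evaluate_predictions(model, list(ts)[:25], horizons=[1],
                                      n_samples=40, rng_seed=3,
                                      expected_r2=True)
        ach = df[df.metric == "r2"].value.mean()
        exp = df[df.metric == "expected_r2"].value.mean()
        assert np.isfinite(ach) and np.isfinite(exp)
        assert ach <= exp + 0.02
        # with the true per-bin rates (known latents) the two agree closely
        counts = np.concatenate([t.observations for t in ts])
        from pwlds.model import softplus
        rates = softplus(np.concatenate([t.latents for t in ts]) @ em.C.T + em.d)
        from pwlds import metrics as mx
        assert mx.r2_deviance_poisson(counts, rates) == pytest.approx(
            mx.expected_r2_poisson(counts, rates), abs=0.03)


class TestMultiRestart:
    def test_selection_contract_and_determinism(self, gaussian_dataset):
        ens1 = multi_restart_fit(gaussian_dataset, K=1, H=2, n_restarts=3,
                                 base_seed=40, n_iters=15)
        ens2 = multi_restart_fit(gaussian_dataset, K=1, H=2, n_restarts=3,
                                 base_seed=40, n_iters=15)
        assert len(ens1.models) == 3
        assert ens1.selected_index == int(np.argmax(ens1.val_scores))
        np.testing.assert_array_equal(ens1.val_scores, ens2.val_scores)
        np.testing.assert_allclose(ens1.selected_model.modes[0].A,
                                   ens2.selected_model.modes[0].A)

    def test_seeds_are_consecutive_from_base(self, gaussian_dataset):
        ens = multi_restart_fit(gaussian_dataset, K=1, H=2, n_restarts=2,
                                base_seed=7, n_iters=10)
        assert ens.seeds == [7, 8]

    def test_missing_split_rejected(self, truth, gaussian_emission):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ts = make_dataset(truth, gaussian_emission, n_trials=8,
                              split_ratios=(1.0, 0.0, 0.0), rng_seed=0)
        with pytest.raises(ValueError, match="validation"):
            multi_restart_fit(ts, K=1, H=2, n_restarts=1, base_seed=0)


class TestQualityHistogram:
    def _ensemble_of(self, models):
        return FitEnsemble(models=models, seeds=list(range(len(models))),
                           val_scores=np.zeros(len(models)), selected_index=0)

    def test_all_excellent(self, gaussian_truth):
        ens = self._ensemble_of([gaussian_truth.copy() for _ in range(3)])
        frac = quality_histogram(ens, gaussian_truth)
        assert frac == {"excellent": 1.0, "good": 0.0, "poor": 0.0}

    def test_fraction_counting(self, gaussian_truth):
        good = gaussian_truth.copy()
        good.modes[1] = LinearMode(good.modes[1].A,
                                   good.modes[1].b + np.array([0.0, 0.1]),
                                   good.modes[1].Q)   # attractor off by 1.0
        poor = gaussian_truth.copy()
        poor.modes[1] = LinearMode(poor.modes[1].A,
                                   poor.modes[1].b + np.array([0.0, 0.9]),
                                   poor.modes[1].Q)   # attractor off by 9.0
        ens = self._ensemble_of([gaussian_truth.copy(), good, poor])
        frac = quality_histogram(ens, gaussian_truth)
        assert frac["excellent"] == pytest.approx(1 / 3)
        assert frac["poor"] == pytest.approx(1 / 3)
        assert sum(frac.values()) == pytest.approx(1.0)


def test_compare_frame_has_row_per_metric_horizon(noiseless_setup=None):
    rng = np.random.default_rng(3)
    rows_l, rows_r = [], []
    for k in range(1, 11):
        for i in range(12):
            base = rng.normal()
            rows_l.append(("lds", "gaussian", i, k, "r2", "observation", base))
            rows_r.append(("rslds", "gaussian", i, k, "r2", "observation", base + 0.5))
            rows_l.append(("lds", "gaussian", i, k, "med", "observation", base + 1.0))
            rows_r.append(("rslds", "gaussian", i, k, "med", "observation", base))
    cols = ["model", "family", "trial", "horizon", "metric", "space", "value"]
    comp = compare_forecasts(pd.DataFrame(rows_l, columns=cols),
                             pd.DataFrame(rows_r, columns=cols))
    assert len(comp) == 20                       # 2 metrics x 10 horizons
    assert (comp.advantage == "rslds").all()
    assert (comp.pvalue < 0.001).all()
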