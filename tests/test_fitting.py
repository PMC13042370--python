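"""Empirical-risk estimation of the irreversible potential."""

import numpy as np
import pandas as pd
import pytest

from ecohyst import (
    DataError,
    FitConfig,
    HysteresisEstimator,
    K_STAR_NORMALIZED,
    LoopDataset,
    ModelParams,
    SyntheticConfig,
    bootstrap_ci,
    estimate_K,
    evaluate_driver,
    generate_loop,
    loss,
)

from conftest import NOISE_SD


def rescale(data: LoopDataset, driver=(1.0, 0.0), state=(1.0, 0.0)) -> LoopDataset:
    frame = data.frame.copy()
    frame["driver"] = driver[0] * frame["driver"] + driver[1]
    frame["state"] = state[0] * frame["state"] + state[1]
    return LoopDataset(frame)


class TestLoss:
    def test_near_zero_at_true_k(self, loop9):
        assert loss(9.0, loop9) <= 1e-12

    def test_larger_at_wrong_k(self, loop9):
        assert loss(12.0, loop9) > loss(9.0, loop9)

    def test_infinite_below_critical_for_jumping_data(self, loop9):
        assert loss(5.0, loop9) == np.inf

    def test_requires_min_records(self, loop9):
        tiny = LoopDataset(loop9.frame.iloc[[0, 1, 50, 51]].reset_index(drop=True))
        with pytest.raises(DataError):
            loss(9.0, tiny)


class TestEstimateK:
    @pytest.mark.parametrize("k_true, tol", [(9.0, 0.05), (12.0, 0.1)])
    def test_noiseless_recovery(self, k_true, tol):
        data = generate_loop(
            SyntheticConfig(params=ModelParams.normalized(k_true), seed=2)
        )
        result = estimate_K(data)
        assert abs(result.k_hat - k_true) <= tol
        assert result.regime.label == "hysteretic"

    def test_argmin_property_over_grid(self, loop9):
        result = estimate_K(loop9)
        cfg = FitConfig()
        grid = np.linspace(cfg.effective_k_min, cfg.k_max, 25)
        for k in grid:
            assert result.loss <= loss(float(k), loop9) + 1e-12

    def test_rmse_is_root_mean_loss(self, loop9):
        result = estimate_K(loop9)
        assert result.rmse == pytest.approx(np.sqrt(result.loss / len(loop9)))

    def test_invariant_to_driver_rescaling(self, loop9):
        base = estimate_K(loop9).k_hat
        scaled = estimate_K(rescale(loop9, driver=(3.0, 7.0))).k_hat
        assert scaled == pytest.approx(base, abs=1e-6)

    def test_invariant_to_state_rescaling(self, loop9):
        base = estimate_K(loop9).k_hat
        scaled = estimate_K(rescale(loop9, state=(10.0, 2.0))).k_hat
        assert scaled == pytest.approx(base, abs=1e-6)

    def test_non_hysteretic_data(self):
        """Monotone data from a sub-critical K fits below K*, labeled continuous."""
        k_true = 4.0
        ys = np.linspace(1.01, np.e - 0.2, 40)
        xs = evaluate_driver(ys, ModelParams.normalized(k_true))
        frame = pd.concat(
            [
                pd.DataFrame({"driver": xs, "state": ys, "direction": d})
                for d in ("forward", "backward")
            ]
        ).reset_index(drop=True)
        result = estimate_K(
            LoopDataset(frame), FitConfig(allow_nonhysteretic=True)
        )
        assert result.k_hat <= K_STAR_NORMALIZED
        assert result.regime.label == "continuous"

    def test_noisy_recovery_median_within_ten_percent(self):
        errs = []
        for seed in range(5):
            data = generate_loop(
                SyntheticConfig(
                    params=ModelParams.normalized(9.0), noise_sd=NOISE_SD, seed=seed
                )
            )
            errs.append(abs(estimate_K(data).k_hat - 9.0) / 9.0)
        assert np.median(errs) <= 0.10


class TestEstimatorInterface:
    def test_fitted_attributes(self, loop9):
        est = HysteresisEstimator().fit(loop9)
        assert est.k_ == pytest.approx(9.0, abs=0.05)
        assert est.loss_ >= 0
        assert est.n_forward_ == 50 and est.n_backward_ == 50
        assert est.regime_.label == "hysteretic"
        assert est.ci_ is None

    def test_get_set_params_round_trip(self):
        est = HysteresisEstimator(k_max=40.0)
        params = est.get_params()
        assert params["k_max"] == 40.0
        est.set_params(seed=5)
        assert est.seed == 5

    def test_predict_reproduces_noiseless_drivers(self, loop9):
        est = HysteresisEstimator().fit(loop9)
        fitted = est.predict(loop9)
        observed = loop9.frame["driver"].to_numpy()
        # plateau records map to the tipping driver rather than their own
        # driver, so compare off-plateau points only
        close = np.abs(fitted - observed) <= 1e-6 * np.maximum(observed, 1.0)
        assert close.mean() > 0.9

    def test_result_serializes(self, loop9):
        payload = HysteresisEstimator().fit(loop9).result_.to_dict()
        assert set(payload) >= {
            "K_hat", "loss", "rmse", "ci", "regime",
            "alignment", "transform", "n_forward", "n_backward",
        }


class TestBootstrap:
    def test_deterministic_for_fixed_seed(self, norm9):
        data = generate_loop(
            SyntheticConfig(params=norm9, n_per_branch=20, noise_sd=NOISE_SD, seed=4)
        )
        cfg = FitConfig(bootstrap_reps=50, seed=123)
        assert bootstrap_ci(data, cfg) == bootstrap_ci(data, cfg)

    def test_narrow_interval_on_noiseless_loop(self, loop9):
        lo, hi = bootstrap_ci(loop9, FitConfig(bootstrap_reps=60, seed=0))
        assert hi - lo < 0.1
        assert lo <= 9.0 + 1e-6

    def test_requires_enough_replicates(self, loop9):
        with pytest.raises(DataError):
            bootstrap_ci(loop9, FitConfig(bootstrap_reps=10))

    def test_coverage_on_noisy_loops(self, norm9):
        """The 95% interval should contain the generating K in most runs."""
        hits = 0
        n_loops = 25
        for seed in range(n_loops):
            data = generate_loop(
                SyntheticConfig(params=norm9, noise_sd=NOISE_SD, seed=100 + seed)
            )
            lo, hi = bootstrap_ci(data, FitConfig(bootstrap_reps=50, seed=seed))
            hits += lo <= 9.0 <= hi
        assert hits / n_loops >= 0.80
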