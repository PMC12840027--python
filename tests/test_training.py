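"""Normalization, rolling windows, the 6:2:2 split, training loop
behavior, evaluation metrics, baselines, and the benchmark table."""

import numpy as np
import pytest

from yubadry.metrics import mae, r_squared, rmse
from yubadry.nn import make_baseline
from yubadry.training import (
    TrainConfig,
    benchmark_table,
    build_dataset,
    evaluate_model,
    fit_normalizer,
    make_windows,
    split_622,
    train_model,
)


class TestNormalizer:
    def test_endpoints_map_to_unit_interval(self):
        norm = fit_normalizer(np.array([[2.0], [4.0], [6.0]]), ("f",))
        np.testing.assert_allclose(norm.apply(np.array([[2.0], [4.0], [6.0]])),
                                   [[0.0], [0.5], [1.0]])

    def test_constant_feature_maps_to_half(self):
        norm = fit_normalizer(np.array([[7.0], [7.0], [7.0]]), ("f",))
        np.testing.assert_allclose(norm.apply(np.array([[7.0], [7.0]])),
                                   [[0.5], [0.5]])

    def test_apply_invert_round_trip(self, rng):
        train = rng.normal(size=(50, 4)) * [1, 10, 100, 0.01]
        norm = fit_normalizer(train, ("a", "b", "c", "d"))
        x = rng.normal(size=(20, 4))
        np.testing.assert_allclose(norm.invert(norm.apply(x)), x, atol=1e-12)

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            fit_normalizer(np.empty((0, 3)), ("a", "b", "c"))


class TestMakeWindows:
    def test_sample_count_formula(self, traj60):
        n = len(traj60)
        for w, h in [(10, 1), (5, 3), (1, 1)]:
            assert len(make_windows(traj60, w, h)) == n - w - h + 1

    def test_boundary_single_sample(self, traj60):
        from yubadry.twin import Trajectory

        short = Trajectory(states=traj60.states[:11], metadata=traj60.metadata)
        assert len(make_windows(short, 10, 1)) == 1

    def test_consecutive_windows_overlap(self, traj60):
        samples = make_windows(traj60, 10, 1)
        np.testing.assert_array_equal(samples[0].inputs[1:], samples[1].inputs[:-1])

    def test_target_is_next_stage_values(self, traj60):
        samples = make_windows(traj60, 10, 1)
        s = samples[0]
        state = traj60.states[s.origin[1]]
        np.testing.assert_allclose(s.target, [state.DR, state.SR, state.dE])

    def test_conditioning_appends_next_temperature(self, traj60):
        samples = make_windows(traj60, 10, 1, conditioning="append")
        assert samples[0].inputs.shape[1] == 6
        t_air = traj60.column("T_air")
        np.testing.assert_allclose(samples[0].inputs[:, 5], t_air[1:11])

    def test_too_short_trajectory_rejected(self, traj60):
        from yubadry.twin import Trajectory

        short = Trajectory(states=traj60.states[:5], metadata=traj60.metadata)
        with pytest.raises(ValueError):
            make_windows(short, 10, 1)


class TestSplit622:
    def test_exact_ratio(self):
        train, val, test = split_622(list(range(100)))
        assert (len(train), len(val), len(test)) == (60, 20, 20)

    def test_remainder_goes_to_test(self):
        train, val, test = split_622(list(range(101)))
        assert (len(train), len(val), len(test)) == (60, 20, 21)

    def test_concatenation_preserves_order(self):
        items = list(range(57))
        train, val, test = split_622(items)
        assert train + val + test == items

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            split_622([1, 2, 3])


class TestMetrics:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == pytest.approx(1.0)
        assert rmse(y, y) == 0.0
        assert mae(y, y) == 0.0

    def test_mean_predictor_has_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = np.full(4, y.mean())
        assert r_squared(y, yhat) == pytest.approx(0.0)

    def test_hand_computed_sums(self):
        y = np.array([1.0, 2.0, 3.0])
        yhat = np.array([1.0, 2.0, 4.0])
        assert r_squared(y, yhat) == pytest.approx(0.5)
        assert rmse(y, yhat) == pytest.approx(np.sqrt(1.0 / 3.0))
        assert mae(y, yhat) == pytest.approx(1.0 / 3.0)

    def test_constant_offset_rmse(self, rng):
        y = rng.normal(size=30)
        assert rmse(y, y + 0.7) == pytest.approx(0.7)
        assert mae(y, y + 0.7) == pytest.approx(0.7)

    def test_rmse_dominates_mae(self, rng):
        for _ in range(20):
            y = rng.normal(size=15)
            yhat = y + rng.normal(size=15)
            assert rmse(y, yhat) >= mae(y, yhat) - 1e-12

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import (
            mean_absolute_error,
            mean_squared_error,
            r2_score,
        )

        for _ in range(10):
            y = rng.normal(size=40)
            yhat = y + 0.3 * rng.normal(size=40)
            assert r_squared(y, yhat) == pytest.approx(r2_score(y, yhat), abs=1e-10)
            assert rmse(y, yhat) == pytest.approx(
                np.sqrt(mean_squared_error(y, yhat)), abs=1e-10)
            assert mae(y, yhat) == pytest.approx(
                mean_absolute_error(y, yhat), abs=1e-10)

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestBaselines:
    def test_linear_interpolates_linear_data(self, rng):
        X = rng.normal(size=(40, 4, 2))
        coefs = rng.normal(size=(8, 3))
        Y = X.reshape(40, 8) @ coefs + 1.5
        model = make_baseline("linear", window=4, features=2).fit(X, Y)
        pred = model.predict(X)
        for j in range(3):
            assert r_squared(Y[:, j], pred[:, j]) == pytest.approx(1.0, abs=1e-10)

    def test_polynomial_fits_quadratic_data(self, rng):
        X = rng.normal(size=(60, 3, 2))
        flat = X.reshape(60, 6)
        Y = np.column_stack([flat[:, 0] ** 2, flat[:, 1] * flat[:, 2], flat[:, 3]])
        model = make_baseline("polynomial", window=3, features=2).fit(X, Y)
        pred = model.predict(X)
        for j in range(3):
            assert r_squared(Y[:, j], pred[:, j]) == pytest.approx(1.0, abs=1e-8)

    def test_linear_coefficients_match_normal_equations(self):
        """3-point system solved by hand via the normal equations."""
        X = np.array([[0.0], [1.0], [2.0]]).reshape(3, 1, 1)
        Y = np.tile(np.array([[1.0], [3.0], [5.0]]), (1, 3))  # y = 1 + 2x
        model = make_baseline("linear", window=1, features=1).fit(X, Y)
        np.testing.assert_allclose(model.coef_[0], [1.0, 1.0, 1.0], atol=1e-10)
        np.testing.assert_allclose(model.coef_[1], [2.0, 2.0, 2.0], atol=1e-10)

    def test_rank_deficient_design_warns(self, rng):
        X = np.zeros((10, 2, 2))  # all-constant windows
        Y = rng.normal(size=(10, 3))
        with pytest.warns(UserWarning, match="rank-deficient"):
            make_baseline("linear", window=2, features=2).fit(X, Y)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_baseline("forest", window=2, features=2)


class TestTrainModel:
    def test_mlp_drives_loss_down_and_is_deterministic(self, rng):
        X = rng.normal(size=(64, 5, 3))
        Y = 0.1 * X[:, -1, :]
        cfg = TrainConfig(window=5, iterations=150, seed=3)
        histories = []
        for _ in range(2):
            model = make_baseline("mlp", window=5, features=3, hidden=16, seed=3)
            histories.append(train_model(model, X, Y, cfg))
        assert histories[0] == histories[1]
        assert histories[0][-1] < 0.1 * histories[0][0]
        assert all(v >= 0 for v in histories[0])

    def test_minibatch_mode(self, rng):
        X = rng.normal(size=(64, 4, 2))
        Y = X[:, -1, :].repeat(2, axis=1)[:, :3]
        model = make_baseline("mlp", window=4, features=2, hidden=8, seed=0)
        hist = train_model(model, X, Y, TrainConfig(window=4, iterations=50,
                                                    batch_size=16, seed=0))
        assert len(hist) == 50

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergence_aborts_with_diagnostic(self, rng):
        X = rng.normal(size=(8, 2, 2)) * 1e200
        Y = rng.normal(size=(8, 3)) * 1e200
        model = make_baseline("mlp", window=2, features=2, hidden=4, seed=0)
        with pytest.raises(RuntimeError, match="non-finite"):
            train_model(model, X, Y, TrainConfig(window=2, iterations=10))


class TestDatasetAndBenchmark:
    def test_build_dataset_shapes_and_normalization(self, scenario_trajectories):
        ds = build_dataset(scenario_trajectories[:3], w=10)
        total = sum(len(t) - 10 for t in scenario_trajectories[:3])
        assert len(ds.X_train) + len(ds.X_val) + len(ds.X_test) == total
        assert ds.X_train.shape[1:] == (10, 6)
        assert ds.X_train.min() >= 0.0 and ds.X_train.max() <= 1.0
        # val/test may exceed [0,1]: statistics come from the train split only
        assert np.isfinite(ds.X_test).all()

    @pytest.mark.filterwarnings("ignore:design matrix")
    def test_benchmark_table_shape_and_self_consistency(self, scenario_trajectories):
        ds = build_dataset(scenario_trajectories[:2], w=10)
        lin = make_baseline("linear", window=10, features=6).fit(ds.X_train,
                                                                 ds.y_train)
        table = benchmark_table({"LR": lin}, {"setA": ds, "setB": ds})
        assert len(table) == 2 * 3  # scenarios x targets for one model
        rep = evaluate_model(lin, ds.X_test, ds.y_test, ds.normalizer)
        sub = table[table.scenario == "setA"].reset_index(drop=True)
        np.testing.assert_allclose(sub.RMSE.to_numpy(), rep.RMSE.to_numpy())
        assert (table.RMSE >= table.MAE - 1e-12).all()

    def test_mean_predictor_scores_zero_r2(self, scenario_trajectories):
        ds = build_dataset(scenario_trajectories[:4], w=10)

        class MeanStub:
            name = "mean"

            def predict(self, X):
                return np.tile(ds.y_test.mean(axis=0), (len(X), 1))

        rep = evaluate_model(MeanStub(), ds.X_test, ds.y_test, ds.normalizer)
        assert np.all(np.abs(rep.R2) < 0.05)
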