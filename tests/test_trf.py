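"""Lagged designs, ridge TRF estimation, scoring, cross-validation."""

import numpy as np
import pytest

from speechtrack.acoustic import FeatureMatrix
from speechtrack.dataset import EEGDataset
from speechtrack.simulate import make_ground_truth_kernels, simulate_eeg
from speechtrack.trf import (
    TemporalResponseModel,
    build_lagged_design,
    crossval_fit,
    event_mask,
    fit_trf,
    lag_samples,
    make_fold_plan,
    score,
    tune_lambda,
)


def naive_ridge(X, Y, lam):
    """Independent normal-equations solver: explicit centering, dense solve."""
    xm = X.mean(axis=0)
    ym = Y.mean(axis=0)
    Xc = X - xm
    Yc = Y - ym
    G = Xc.T @ Xc
    m = np.trace(G) / G.shape[0]
    W = np.linalg.solve(G + lam * m * np.eye(G.shape[0]), Xc.T @ Yc)
    return W, ym - W.T @ xm


def naive_lagged(F, lags):
    """Independent lagged-design construction by explicit row loops."""
    T, P = F.shape
    X = np.zeros((T, P * len(lags)))
    for t in range(T):
        for p in range(P):
            for j, l in enumerate(lags):
                if 0 <= t - l < T:
                    X[t, p * len(lags) + j] = F[t - l, p]
    return X


class TestLagDesign:
    def test_standard_lag_grid(self):
        lags = lag_samples((-100, 800), 128.0)
        assert lags[0] == -13 and lags[-1] == 102 and lags.size == 116

    def test_impulse_shifts_to_lagged_column(self):
        F = np.zeros((50, 1))
        F[20, 0] = 1.0
        fm = FeatureMatrix(F, ["x"], 128.0)
        d = build_lagged_design(fm, (-100, 800))
        j = list(d.lags).index(5)
        col = d.matrix[:, j]
        assert col[25] == 1.0 and np.count_nonzero(col) == 1

    def test_matches_naive_construction(self, rng):
        F = rng.standard_normal((40, 3))
        fm = FeatureMatrix(F, list("abc"), 128.0)
        d = build_lagged_design(fm, (-30, 60))
        np.testing.assert_allclose(d.matrix, naive_lagged(F, d.lags), atol=0)

    def test_all_zero_features_all_zero_design(self):
        fm = FeatureMatrix(np.zeros((30, 2)), ["a", "b"], 128.0)
        assert not build_lagged_design(fm).matrix.any()


class TestFitTRF:
    def test_matches_normal_equations_oracle(self, rng):
        F = rng.standard_normal((50, 3))
        fm = FeatureMatrix(F, list("abc"), 128.0)
        Y = rng.standard_normal((50, 4))  # 4 channels
        res = fit_trf(fm, Y.T, alpha=0.5, lag_range_ms=(0, 1000 / 128))
        X = naive_lagged(F, res.model.lags)
        W, icpt = naive_ridge(X, Y, 0.5)
        np.testing.assert_allclose(res.weights, W, atol=1e-10)
        np.testing.assert_allclose(res.intercept, icpt, atol=1e-10)

    def test_large_lambda_shrinks_weights(self, rng):
        F = rng.standard_normal((100, 2))
        fm = FeatureMatrix(F, ["a", "b"], 128.0)
        Y = rng.standard_normal((100, 2))
        w1 = fit_trf(fm, Y.T, alpha=1.0).weights
        w2 = fit_trf(fm, Y.T, alpha=1e6).weights
        assert np.abs(w2).max() < 1e-3 * np.abs(w1).max()

    def test_noiseless_recovery_of_ground_truth(self, rng):
        names = ["a", "b"]
        kern = make_ground_truth_kernels(names, n_channels=3, seed=3)
        feats = {}
        for tid in range(6):
            F = (rng.random((400, 2)) < 0.05).astype(float)
            feats[tid] = FeatureMatrix(F, names, 128.0)
        ds = simulate_eeg(feats, kern, noise_sd=0.0, seed=0)
        res = fit_trf(list(feats.values()), ds.epochs, alpha=1e-8)
        assert np.abs(res.kernels - kern.kernels).max() < 1e-4

    def test_singular_design_warns_and_solves(self, rng):
        F = np.zeros((30, 2))
        F[:, 0] = rng.standard_normal(30)
        F[:, 1] = F[:, 0]  # duplicated predictor
        fm = FeatureMatrix(F, ["a", "b"], 128.0)
        with pytest.warns(UserWarning, match="singular"):
            res = fit_trf(fm, rng.standard_normal((1, 30)), alpha=0.0, lag_range_ms=(0, 1000 / 128))
        assert np.all(np.isfinite(res.weights))

    def test_negative_alpha_rejected(self, rng):
        fm = FeatureMatrix(rng.standard_normal((20, 1)), ["a"], 128.0)
        with pytest.raises(ValueError):
            fit_trf(fm, rng.standard_normal((1, 20)), alpha=-1.0)


class TestPredictScore:
    def _fitted(self, rng):
        F = rng.standard_normal((200, 2))
        fm = FeatureMatrix(F, ["a", "b"], 128.0)
        lags = lag_samples((-50, 100), 128.0)
        W_true = rng.standard_normal((2 * lags.size, 3))
        Y = (naive_lagged(F, lags) @ W_true).T + rng.standard_normal((3, 1))
        return fm, Y, fit_trf(fm, Y, alpha=1e-10, lag_range_ms=(-50, 100))

    def test_zero_features_give_intercept(self, rng):
        fm, Y, res = self._fitted(rng)
        zero = FeatureMatrix(np.zeros_like(fm.data), fm.names, fm.sfreq)
        pred = res.predict(zero)
        np.testing.assert_allclose(pred, res.intercept[:, None] * np.ones_like(pred))

    def test_interpolation_on_training_data(self, rng):
        fm, Y, res = self._fitted(rng)
        pred = res.predict(fm)
        assert score(pred, Y).min() > 0.99

    def test_prediction_linear_in_features(self, rng):
        fm, Y, res = self._fitted(rng)
        doubled = FeatureMatrix(fm.data * 2, fm.names, fm.sfreq)
        p1 = res.predict(fm) - res.intercept[:, None]
        p2 = res.predict(doubled) - res.intercept[:, None]
        np.testing.assert_allclose(p2, 2 * p1, atol=1e-8)

    def test_score_perfect_and_anticorrelated(self, rng):
        Y = rng.standard_normal((4, 100))
        np.testing.assert_allclose(score(Y, Y), 1.0)
        np.testing.assert_allclose(score(-Y, Y), -1.0)

    def test_score_affine_invariance(self, rng):
        Y = rng.standard_normal((4, 100))
        np.testing.assert_allclose(score(3.2 * Y + 1.7, Y), 1.0)

    def test_zero_variance_channel_scores_zero(self, rng):
        Y = rng.standard_normal((2, 50))
        P = Y.copy()
        P[1] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            r = score(P, Y)
        assert r[0] == pytest.approx(1.0) and r[1] == 0.0

    def test_event_mask_covers_window(self):
        m = event_mask([0.5], n_samples=256, rate=128.0, window_s=(0.0, 0.8))
        assert m[64] and m[166] and not m[63] and not m[168]


class TestCrossval:
    def _toy_datasets(self, rng, n_participants=3, n_trials=4):
        names = ["a"]
        kern = make_ground_truth_kernels(names, n_channels=2, seed=1)
        feats = {
            t: FeatureMatrix((rng.random((300, 1)) < 0.05).astype(float), names, 128.0)
            for t in range(n_trials)
        }
        labels = {t: ("correct" if t % 2 == 0 else "incorrect") for t in range(n_trials)}
        datasets = {
            f"P{i}": simulate_eeg(
                feats, kern, noise_sd=0.5, condition_labels=labels,
                participant=f"P{i}", seed=100 + i,
            )
            for i in range(n_participants)
        }
        return datasets, feats

    def test_fold_plan_disjoint(self):
        plan = make_fold_plan(list("abcdefghij"), n_folds=20, test_size=3, seed=0)
        for train, test in plan.folds:
            assert not set(train) & set(test)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            make_fold_plan(["a", "b"], test_size=2)

    def test_expected_test_appearances(self):
        # 50 folds, 8 test of 43: each participant expected in ~9.3 folds
        plan = make_fold_plan([f"P{i}" for i in range(43)], 50, 8, seed=5)
        counts = {}
        for _, test in plan.folds:
            for p in test:
                counts[p] = counts.get(p, 0) + 1
        mean_count = np.mean(list(counts.values()))
        assert mean_count == pytest.approx(50 * 8 / 43, abs=1e-9)  # exact: every fold has 8

    def test_scores_come_from_held_out_models(self, rng):
        datasets, feats = self._toy_datasets(rng)
        plan = make_fold_plan(list(datasets), n_folds=6, test_size=1, seed=2)
        fs = crossval_fit(datasets, feats, plan, alpha=0.1)
        # every scored trial was tested at least once and rows align
        assert (fs.frame["n_folds"] >= 1).all()
        assert set(fs.frame["variant"]) == {"correct", "incorrect"}
        assert np.all(np.abs(fs.scores) <= 1.0)

    def test_training_ignores_test_participant_response(self, rng):
        # leakage check: the model scoring a test participant never saw
        # any test participant's EEG, so tampering with one test
        # participant's data leaves the other's scores bit-identical
        from speechtrack.trf import FoldPlan

        datasets, feats = self._toy_datasets(rng, n_participants=4)
        pids = list(datasets)
        plan = FoldPlan([((pids[2], pids[3]), (pids[0], pids[1]))])
        fs1 = crossval_fit(datasets, feats, plan, alpha=0.1)
        tampered = dict(datasets)
        ds = datasets[pids[0]]
        tampered[pids[0]] = EEGDataset(
            ds.participant,
            [rng.standard_normal(e.shape) for e in ds.epochs],
            list(ds.trial_ids), ds.ch_names, ds.sfreq, list(ds.condition_labels),
        )
        fs2 = crossval_fit(tampered, feats, plan, alpha=0.1)
        r1 = fs1.scores[(fs1.frame["participant"] == pids[1]).to_numpy()]
        r2 = fs2.scores[(fs2.frame["participant"] == pids[1]).to_numpy()]
        np.testing.assert_allclose(r1, r2, atol=0)

    def test_identical_variant_data_gives_identical_models(self, rng):
        # same trials labelled correct for one dataset copy and
        # incorrect for another -> both variants see identical data
        names = ["a"]
        kern = make_ground_truth_kernels(names, n_channels=2, seed=4)
        feats = {
            t: FeatureMatrix((rng.random((200, 1)) < 0.05).astype(float), names, 128.0)
            for t in range(2)
        }
        datasets = {}
        for i in range(3):
            base = simulate_eeg(
                feats, kern, noise_sd=0.3,
                condition_labels={0: "correct", 1: "incorrect"},
                participant=f"P{i}", seed=i,
            )
            # mirror every epoch into the other variant
            datasets[f"P{i}"] = EEGDataset(
                base.participant,
                base.epochs + base.epochs,
                base.trial_ids + [t + 10 for t in base.trial_ids],
                base.ch_names, base.sfreq,
                ["correct", "correct", "incorrect", "incorrect"],
            )
        feats_all = dict(feats)
        feats_all.update({t + 10: feats[t] for t in feats})
        plan = make_fold_plan(list(datasets), n_folds=3, test_size=1, seed=1)
        fs = crossval_fit(datasets, feats_all, plan, alpha=0.1)
        for pid in datasets:
            sub = fs.frame["participant"] == pid
            sc = fs.scores[sub.to_numpy()]
            fr = fs.frame[sub]
            c = sc[(fr["variant"] == "correct").to_numpy()]
            i = sc[(fr["variant"] == "incorrect").to_numpy()]
            np.testing.assert_allclose(np.sort(c, axis=0), np.sort(i, axis=0), atol=1e-10)

    def test_missing_variant_rejected(self, rng):
        datasets, feats = self._toy_datasets(rng)
        pid = list(datasets)[0]
        ds = datasets[pid]
        datasets[pid] = EEGDataset(
            ds.participant, ds.epochs, ds.trial_ids, ds.ch_names, ds.sfreq,
            ["correct"] * ds.n_trials,
        )
        plan = make_fold_plan(list(datasets), n_folds=2, test_size=1, seed=0)
        with pytest.raises(ValueError, match="incorrect"):
            crossval_fit(datasets, feats, plan, alpha=0.1)


class TestTuneLambda:
    def test_single_value_grid_returned(self, rng):
        names = ["a"]
        kern = make_ground_truth_kernels(names, n_channels=2, seed=2)
        feats = {
            t: FeatureMatrix((rng.random((150, 1)) < 0.05).astype(float), names, 128.0)
            for t in range(2)
        }
        labels = {0: "correct", 1: "incorrect"}
        datasets = {
            f"P{i}": simulate_eeg(feats, kern, noise_sd=0.5, condition_labels=labels,
                                  participant=f"P{i}", seed=i)
            for i in range(3)
        }
        plan = make_fold_plan(list(datasets), n_folds=2, test_size=1, seed=1)
        assert tune_lambda([0.3], datasets, feats, plan) == 0.3

    def test_noise_level_moves_selected_lambda(self, rng):
        # noiseless data is best fitted unregularized; heavy noise makes
        # the shrunk model generalize better across participants
        names = ["a", "b"]
        kern = make_ground_truth_kernels(names, n_channels=4, seed=6)
        feats = {
            t: FeatureMatrix((rng.random((300, 2)) < 0.08).astype(float), names, 128.0)
            for t in range(6)
        }
        labels = {t: ("correct" if t < 3 else "incorrect") for t in range(6)}
        grid = [1e-8, 1.0]
        mk = lambda sd, seed: {
            f"P{i}": simulate_eeg(feats, kern, noise_sd=sd, condition_labels=labels,
                                  participant=f"P{i}", seed=seed + i)
            for i in range(4)
        }
        plan = make_fold_plan([f"P{i}" for i in range(4)], n_folds=4, test_size=1, seed=2)
        assert tune_lambda(grid, mk(0.0, 10), feats, plan) == pytest.approx(1e-8)
        assert tune_lambda(grid, mk(8.0, 20), feats, plan) == pytest.approx(1.0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            tune_lambda([], {}, {}, None)
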