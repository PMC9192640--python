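"""Classifier correctness, CV hygiene, regime behaviour, determinism."""

import numpy as np
import pytest

from featdecode import decoders as dc, features as ft
from featdecode.errors import ConfigurationError, DegeneratePopulationError


def make_fm(X, y, trials, distractor="present", pairing="black6_white7.5",
            feature_index=None):
    n = len(y)
    if feature_index is None:
        chans = "ABCDE"
        feature_index = [(c, f) for c in chans for f in (6.0, 7.5)]
    return ft.FeatureMatrix(
        X=X, feature_index=feature_index, variant="simple",
        y=np.asarray(y, dtype=object), trial_index=np.asarray(trials),
        distractor=np.asarray([distractor] * n, dtype=object),
        pairing=np.asarray([pairing] * n, dtype=object),
    )


def random_fm(rng, n_trials=40, epochs_per_trial=12, signal=0.0, distractor="present"):
    """Balanced two-class feature set; `signal` shifts the 6 Hz columns of
    the black class and the 7.5 Hz columns of the white class."""
    n = n_trials * epochs_per_trial
    X = rng.normal(1.0, 0.5, size=(n, 10))
    trials = np.repeat(np.arange(n_trials), epochs_per_trial)
    y = np.repeat(np.array(["black", "white"] * (n_trials // 2), dtype=object),
                  epochs_per_trial)
    cols6 = np.arange(0, 10, 2)
    cols75 = np.arange(1, 10, 2)
    X[np.ix_(y == "black", cols6)] += signal
    X[np.ix_(y == "white", cols75)] += signal
    return make_fm(X, y, trials, distractor=distractor)


class TestZScore:
    def test_matches_independent_oracle(self, rng):
        fm_train = random_fm(rng, signal=0.3)
        fm_test = random_fm(rng, signal=0.3)
        stats = dc.PopulationStats.from_features(fm_train)
        pred = dc.zscore_classify(fm_test, stats, "black6_white7.5", rng=0)

        # independent re-derivation: channel-mean amplitude per frequency,
        # z-score against training mean/SD (ddof=1), argmax -> paired colour
        def oracle(fm):
            a6 = fm.X[:, np.arange(0, 10, 2)].mean(axis=1)
            a75 = fm.X[:, np.arange(1, 10, 2)].mean(axis=1)
            t6 = fm_train.X[:, np.arange(0, 10, 2)].mean(axis=1)
            t75 = fm_train.X[:, np.arange(1, 10, 2)].mean(axis=1)
            z6 = (a6 - t6.mean()) / t6.std(ddof=1)
            z75 = (a75 - t75.mean()) / t75.std(ddof=1)
            # under black6_white7.5, 6 Hz maps to black
            return np.where(z6 > z75, "black", np.where(z75 > z6, "white", "tie"))

        expected = oracle(fm_test)
        ties = expected == "tie"
        assert not ties.any()
        assert np.array_equal(pred, expected.astype(object))

    def test_constructed_argmax(self):
        stats = dc.PopulationStats(mean={6.0: 1.0, 7.5: 1.0}, sd={6.0: 0.1, 7.5: 0.1})
        X = np.ones((1, 10))
        X[0, np.arange(0, 10, 2)] = 1.2  # 6 Hz two SDs up
        fm = make_fm(X, ["black"], [0])
        assert dc.zscore_classify(fm, stats, "black6_white7.5", rng=0)[0] == "black"
        # the same evidence under the flipped pairing names the other colour
        assert dc.zscore_classify(fm, stats, "black7.5_white6", rng=0)[0] == "white"

    def test_tie_break_is_seeded_coin(self):
        stats = dc.PopulationStats(mean={6.0: 1.0, 7.5: 1.0}, sd={6.0: 0.1, 7.5: 0.1})
        X = np.ones((200, 10))  # every epoch exactly at both means: z = 0, 0
        fm = make_fm(X, ["black"] * 200, np.arange(200))
        pred = dc.zscore_classify(fm, stats, "black6_white7.5", rng=3)
        again = dc.zscore_classify(fm, stats, "black6_white7.5", rng=3)
        assert np.array_equal(pred, again)
        frac = (pred == "black").mean()
        assert 0.3 < frac < 0.7  # fair coin over 200 flips

    def test_mean_of_z_mode_agrees_on_homogeneous_channels(self, rng):
        """When all channels share one population, per-channel z-scoring and
        channel-mean z-scoring rank the frequencies identically."""
        fm_train = random_fm(rng, signal=0.5)
        fm_test = random_fm(rng, signal=0.5)
        stats = dc.PopulationStats.from_features(fm_train)
        a = dc.zscore_classify(fm_test, stats, "black6_white7.5", rng=0)
        b = dc.zscore_classify(fm_test, stats, "black6_white7.5", rng=0, mode="mean_of_z")
        assert (a == b).mean() > 0.9  # sampling noise only
        with pytest.raises(ConfigurationError):
            dc.zscore_classify(fm_test, stats, "black6_white7.5", mode="nope")

    def test_degenerate_population(self):
        with pytest.raises(DegeneratePopulationError):
            dc.PopulationStats(mean={6.0: 1.0, 7.5: 1.0}, sd={6.0: 0.0, 7.5: 0.1})


class TestTrainClassifier:
    def test_separable_blobs_all_kinds(self, rng):
        n = 150
        X = np.vstack([rng.normal(0, 1, (n, 10)), rng.normal(10, 1, (n, 10))])
        y = np.array(["black"] * n + ["white"] * n, dtype=object)
        Xh = np.vstack([rng.normal(0, 1, (40, 10)), rng.normal(10, 1, (40, 10))])
        yh = np.array(["black"] * 40 + ["white"] * 40, dtype=object)
        for kind in ("lda", "lr", "svm", "mlp", "knn"):
            model = dc.train_classifier(kind, X, y, seed=1)
            assert (model.predict(Xh) == yh).all(), kind

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 4))
        with pytest.raises(ConfigurationError):
            dc.train_classifier("lda", X, np.array(["black"] * 20), seed=0)

    def test_lda_matches_pooled_covariance_solution(self, rng):
        """Decision values equal the closed form w = S_pooled^-1 (mu1 - mu0)
        with the midpoint threshold, on a 2-feature toy set."""
        n = 60
        X0 = rng.multivariate_normal([0, 0], [[1.0, 0.3], [0.3, 0.5]], n)
        X1 = rng.multivariate_normal([1.2, 0.4], [[1.0, 0.3], [0.3, 0.5]], n)
        X = np.vstack([X0, X1])
        y = np.array(["black"] * n + ["white"] * n, dtype=object)
        model = dc.train_classifier("lda", X, y, seed=0)

        mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
        S = (
            (X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)
        ) / (2 * n - 2)
        w = np.linalg.solve(S, mu1 - mu0)
        scores = (X - (mu0 + mu1) / 2) @ w
        by_hand = np.where(scores > 0, "white", "black")
        assert np.array_equal(model.predict(X), by_hand)


class TestCrossValidation:
    def test_fold_sizes_and_disjointness(self, rng):
        fm = random_fm(rng, n_trials=20)
        folds = dc.trial_folds(fm.trial_index, 10, rng)
        assert all(len(f) == 2 for f in folds)
        combined = np.concatenate(folds)
        assert len(np.unique(combined)) == 20

    def test_no_trial_leakage_any_fold(self, rng):
        fm = random_fm(rng, n_trials=34, epochs_per_trial=7)
        labels = {int(t): fm.y[fm.trial_index == t][0] for t in np.unique(fm.trial_index)}
        folds = dc.trial_folds(fm.trial_index, 10, rng, trial_labels=labels)
        for fold in folds:
            train_trials = np.setdiff1d(np.unique(fm.trial_index), fold)
            assert len(np.intersect1d(fold, train_trials)) == 0

    def test_stratified_folds_balance_classes(self, rng):
        fm = random_fm(rng, n_trials=40)
        labels = {int(t): fm.y[fm.trial_index == t][0] for t in np.unique(fm.trial_index)}
        folds = dc.trial_folds(fm.trial_index, 10, rng, trial_labels=labels)
        for fold in folds:
            classes = [labels[int(t)] for t in fold]
            assert classes.count("black") == classes.count("white")

    def test_fewer_trials_than_folds(self, rng):
        fm = random_fm(rng, n_trials=8)
        with pytest.raises(ConfigurationError):
            dc.crossvalidate_present(fm, "lda", k=10)

    def test_strong_signal_reaches_high_accuracy(self, rng):
        fm = random_fm(rng, signal=5.0)
        acc, n = dc.crossvalidate_present(fm, "lda", seed=0)
        assert acc == 100.0
        assert n == len(fm)

    def test_noiseless_pipeline_is_perfectly_separable(self, noiseless_trials):
        fm = ft.extract_features(
            noiseless_trials, 1.0, "simple", channel_labels=list("ABCDE")
        )
        fm = ft.balance_classes(fm, rng=0)
        sel = (fm.distractor == "present") & (fm.pairing == "black6_white7.5")
        acc, _ = dc.crossvalidate_present(fm.subset(sel), "lda", seed=0)
        assert acc == 100.0


def test_train_absent_test_present_single_iteration(rng):
    fm_abs = random_fm(rng, signal=3.0, distractor="absent")
    fm_pres = random_fm(rng, signal=3.0)
    acc, n = dc.train_absent_test_present(fm_abs, fm_pres, "lda", seed=0)
    assert acc > 95.0
    assert n == len(fm_pres)


class TestRunGrid:
    def test_grid_shape_and_determinism(self, noisy_trials):
        cfg = dc.GridConfig(
            windows=(1.0,), variants=("simple", "simple+harmonic"),
            classifiers=("zscore", "lda"), seed=5, channel_labels=tuple("ABCDE"),
        )
        res1 = dc.run_grid(noisy_trials, cfg, "sub-01")
        res2 = dc.run_grid(noisy_trials, cfg, "sub-01")
        assert res1.equals(res2)
        # zscore runs once per (window, pairing, regime) on the simple set
        z = res1[res1.classifier == "zscore"]
        assert set(z.variant) == {"simple"}
        lda = res1[res1.classifier == "lda"]
        assert len(lda) == 1 * 2 * 2 * 2  # windows x variants x regimes x pairings
        assert res1.accuracy.between(0, 100).all()

    def test_variant_subset_matches_direct_extraction(self, noisy_trials):
        full = ft.extract_features(noisy_trials[:6], 1.0, "simple+alpha+harmonic",
                                   channel_labels=list("ABCDE"))
        direct = ft.extract_features(noisy_trials[:6], 1.0, "simple+alpha",
                                     channel_labels=list("ABCDE"))
        sub = dc._subset_variant(full, "simple+alpha", 5)
        assert sub.feature_index == direct.feature_index
        assert np.allclose(sub.X, direct.X)

    def test_pairing_average(self, noisy_trials):
        cfg = dc.GridConfig(
            windows=(1.0,), variants=("simple",), classifiers=("zscore",),
            regimes=("train_present_cv10",), seed=5, channel_labels=tuple("ABCDE"),
        )
        res = dc.run_grid(noisy_trials, cfg, "s")
        avg = dc.pairing_average(res)
        assert len(avg) == 1
        assert avg.accuracy.iloc[0] == pytest.approx(res.accuracy.mean())
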