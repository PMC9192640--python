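"""Classification of the attended colour: six algorithms, two training regimes.

The baseline is a first-principles z-score rule: within each display
configuration (distractor condition x colour-frequency pairing) the
channel-averaged SSVEP amplitudes at 6.0 and 7.5 Hz are z-scored against
populations built from the training epochs, and the frequency with the larger
z-score is classified as attended. Against this baseline run five standard
learners on the full feature vector: LDA (pooled covariance), logistic
regression fitted by SGD with L2 penalty lambda = 1/n, an RBF-kernel SVM with
a median-distance kernel-scale heuristic, a fully connected 2x10 multi-layer
perceptron trained by gradient descent with momentum and an adaptive learning
rate on squared-error loss, and 1-nearest-neighbour (Euclidean).

Training regimes: 10-fold cross-validation with folds cut by *trial* (epochs
from one trial never span train and test), or a single iteration of training
on distractor-absent trials and testing on distractor-present trials.
Classifiers are fitted separately for the two colour-frequency pairings and
accuracies averaged across them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import SGDClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigurationError, DegeneratePopulationError
from .features import (
    FLICKER,
    STEP,
    VARIANTS,
    FeatureMatrix,
    balance_classes,
    extract_features,
)
from .io_bids import LabelledTrial
from .task_design import PAIRINGS, pairing_frequency

CLASSIFIERS: tuple[str, ...] = ("zscore", "lda", "lr", "svm", "mlp", "knn")
REGIMES: tuple[str, ...] = ("train_present_cv10", "train_absent_test_present")

#: classifiers whose inputs are column-standardised by training-fold statistics
_SCALED = {"lr", "svm", "mlp", "knn"}


# ---------------------------------------------------------------------------
# z-score baseline


def channel_mean_amplitude(fm: FeatureMatrix, freq: float) -> np.ndarray:
    """Per-epoch amplitude at ``freq`` averaged across channels."""
    cols = [i for i, (_, f) in enumerate(fm.feature_index) if f == freq]
    if not cols:
        raise ConfigurationError(f"feature matrix has no {freq} Hz columns")
    return fm.X[:, cols].mean(axis=1)


def _freq_columns(fm: FeatureMatrix, freq: float) -> list[int]:
    return [i for i, (_, f) in enumerate(fm.feature_index) if f == freq]


@dataclass
class PopulationStats:
    """Mean/SD of channel-averaged SSVEP amplitude per flicker frequency,
    estimated from the training epochs of one display configuration.

    ``channel_mean``/``channel_sd`` additionally keep per-channel statistics
    for the alternative mean-of-per-channel-z normalisation.
    """

    mean: dict[float, float]
    sd: dict[float, float]
    channel_mean: dict[float, np.ndarray] | None = None
    channel_sd: dict[float, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for f, s in self.sd.items():
            if not s > 0:
                raise DegeneratePopulationError(f"zero-variance population at {f} Hz")

    @classmethod
    def from_features(cls, fm: FeatureMatrix, freqs: Sequence[float] = FLICKER) -> "PopulationStats":
        amps = {f: channel_mean_amplitude(fm, f) for f in freqs}
        per_ch = {f: fm.X[:, _freq_columns(fm, f)] for f in freqs}
        return cls(
            mean={f: float(a.mean()) for f, a in amps.items()},
            sd={f: float(a.std(ddof=1)) for f, a in amps.items()},
            channel_mean={f: x.mean(axis=0) for f, x in per_ch.items()},
            channel_sd={f: x.std(axis=0, ddof=1) for f, x in per_ch.items()},
        )


def zscore_classify(
    fm: FeatureMatrix,
    stats: PopulationStats,
    pairing: str,
    rng: np.random.Generator | int | None = None,
    mode: str = "channel_mean",
) -> np.ndarray:
    """Predict the attended colour per epoch from z-scored SSVEP amplitudes.

    z_f = (A_f - mu_f) / sigma_f for each flicker frequency; the colour
    paired with the argmax frequency is predicted. Exact ties are broken by
    a seeded fair coin. ``mode`` selects the channel handling: the default
    averages amplitudes across channels before normalising
    ("channel_mean"); "mean_of_z" z-scores each channel against its own
    population and averages the z-scores.
    """
    rng = np.random.default_rng(rng)
    freqs = sorted(stats.mean)
    if mode == "channel_mean":
        z = np.stack(
            [(channel_mean_amplitude(fm, f) - stats.mean[f]) / stats.sd[f] for f in freqs],
            axis=1,
        )
    elif mode == "mean_of_z":
        if stats.channel_mean is None or stats.channel_sd is None:
            raise ConfigurationError("population lacks per-channel statistics")
        cols_z = []
        for f in freqs:
            sd = np.asarray(stats.channel_sd[f])
            if not (sd > 0).all():
                raise DegeneratePopulationError(f"zero-variance channel population at {f} Hz")
            zf = (fm.X[:, _freq_columns(fm, f)] - stats.channel_mean[f]) / sd
            cols_z.append(zf.mean(axis=1))
        z = np.stack(cols_z, axis=1)
    else:
        raise ConfigurationError(f"unknown z-score mode {mode!r}")
    best = np.argmax(z, axis=1)
    ties = z[:, 0] == z[:, 1]
    if ties.any():
        best[ties] = rng.integers(0, 2, size=int(ties.sum()))
    freq_colour = {
        pairing_frequency(pairing, colour): colour for colour in ("black", "white")
    }
    return np.asarray([freq_colour[freqs[b]] for b in best], dtype=object)


# ---------------------------------------------------------------------------
# learned classifiers


class SquaredErrorMLP(BaseEstimator, ClassifierMixin):
    """2x10 MLP trained on squared-error loss with SGD + momentum + adaptive
    learning rate; class predicted by thresholding the regression output.

    Training stops after 500 passes or when the loss improvement stays below
    1e-6 for 20 passes, so hitting the pass cap is the intended stopping
    rule, not a convergence failure.
    """

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        self.net_ = MLPRegressor(
            hidden_layer_sizes=(10, 10),
            activation="tanh",
            solver="sgd",
            learning_rate="adaptive",
            learning_rate_init=0.01,
            momentum=0.9,
            max_iter=500,
            tol=1e-6,
            n_iter_no_change=20,
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.net_.fit(X, (y == self.classes_[1]).astype(float))
        return self

    def predict(self, X):
        return self.classes_[(self.net_.predict(X) > 0.5).astype(int)]

    def __sklearn_is_fitted__(self) -> bool:
        return hasattr(self, "net_")


def _median_distance(X: np.ndarray, rng: np.random.Generator, cap: int = 1000) -> float:
    """Median pairwise Euclidean distance on at most ``cap`` subsampled rows."""
    if X.shape[0] > cap:
        X = X[rng.choice(X.shape[0], size=cap, replace=False)]
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    iu = np.triu_indices_from(d2, k=1)
    med = float(np.sqrt(np.median(d2[iu])))
    return med if med > 0 else 1.0


def train_classifier(kind: str, X_train: np.ndarray, y_train: np.ndarray, seed: int = 0):
    """Fit one of the five learned classifiers (the z-score rule is handled
    separately since it needs population statistics, not a decision model)."""
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ConfigurationError("training set contains a single class")
    n = X_train.shape[0]
    rng = np.random.default_rng(seed)

    if kind == "lda":
        # classes are balanced by design after the balancing step; empirical
        # priors would only re-import per-fold sampling noise
        model = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
    elif kind == "lr":
        model = make_pipeline(
            StandardScaler(),
            SGDClassifier(
                loss="log_loss", penalty="l2", alpha=1.0 / n,
                max_iter=1000, tol=1e-4, random_state=seed,
            ),
        )
    elif kind == "svm":
        scaled = StandardScaler().fit_transform(X_train)
        gamma = 1.0 / _median_distance(scaled, rng) ** 2
        model = make_pipeline(StandardScaler(), SVC(kernel="rbf", gamma=gamma, C=1.0))
    elif kind == "mlp":
        model = make_pipeline(StandardScaler(), SquaredErrorMLP(random_state=seed))
    elif kind == "knn":
        model = make_pipeline(
            StandardScaler(), KNeighborsClassifier(n_neighbors=1, metric="euclidean")
        )
    else:
        raise ConfigurationError(f"unknown classifier {kind!r}")
    return model.fit(X_train, y_train)


# ---------------------------------------------------------------------------
# training regimes


def trial_folds(
    trial_ids: np.ndarray,
    k: int,
    rng: np.random.Generator | int | None = None,
    trial_labels: dict[int, object] | None = None,
) -> list[np.ndarray]:
    """Partition the unique trial indices into k shuffled folds.

    When per-trial class labels are given the partition is stratified: trials
    are shuffled within class and dealt round-robin, so every fold carries a
    near-equal class mix. Unstratified folds on class-balanced data leave
    each training fold leaning *against* its test fold's majority class,
    which biases weak classifiers below chance.
    """
    rng = np.random.default_rng(rng)
    unique = np.unique(np.asarray(trial_ids))
    if len(unique) < k:
        raise ConfigurationError(f"{len(unique)} trials cannot fill {k} folds")
    folds: list[list] = [[] for _ in range(k)]
    if trial_labels is None:
        groups = [rng.permutation(unique)]
    else:
        classes = sorted({str(trial_labels[t]) for t in unique})
        groups = [
            rng.permutation([t for t in unique if str(trial_labels[t]) == c])
            for c in classes
        ]
    i = 0
    for group in groups:
        for t in group:
            folds[i % k].append(t)
            i += 1
    return [np.sort(np.asarray(f)) for f in folds]


def _predict(kind: str, train: FeatureMatrix, test: FeatureMatrix,
             pairing: str, seed: int) -> np.ndarray:
    if kind == "zscore":
        stats = PopulationStats.from_features(train)
        return zscore_classify(test, stats, pairing, rng=seed)
    model = train_classifier(kind, train.X, train.y, seed=seed)
    return np.asarray(model.predict(test.X), dtype=object)


def crossvalidate_present(
    fm: FeatureMatrix,
    kind: str,
    k: int = 10,
    seed: int = 0,
    pairing: str | None = None,
) -> tuple[float, int]:
    """Trial-wise k-fold cross-validated accuracy (%) on one stratum.

    Folds partition trial indices, so overlapping epochs of a trial never
    appear in both train and test. Population statistics for the z-score rule
    are recomputed per fold from the training trials only. Returns
    (pooled accuracy %, number of test epochs).
    """
    if pairing is None:
        pairing = str(fm.pairing[0])
    rng = np.random.default_rng(seed)
    trial_labels = {int(t): fm.y[fm.trial_index == t][0] for t in np.unique(fm.trial_index)}
    folds = trial_folds(fm.trial_index, k, rng, trial_labels=trial_labels)
    correct = total = 0
    for fold in folds:
        test_mask = np.isin(fm.trial_index, fold)
        train, test = fm.subset(~test_mask), fm.subset(test_mask)
        if len(test) == 0:
            continue
        pred = _predict(kind, train, test, pairing, seed=int(rng.integers(2**31)))
        correct += int((pred == test.y).sum())
        total += len(test)
    return 100.0 * correct / total, total


def train_absent_test_present(
    fm_absent: FeatureMatrix,
    fm_present: FeatureMatrix,
    kind: str,
    seed: int = 0,
    pairing: str | None = None,
) -> tuple[float, int]:
    """Single fit on all distractor-absent epochs of a pairing, tested once
    on all its distractor-present epochs. Returns (accuracy %, n test)."""
    if pairing is None:
        pairing = str(fm_present.pairing[0])
    pred = _predict(kind, fm_absent, fm_present, pairing, seed=seed)
    return 100.0 * float((pred == fm_present.y).mean()), len(fm_present)


# ---------------------------------------------------------------------------
# the full grid


@dataclass
class GridConfig:
    """Which cells of the (classifier x window x variant x regime) grid to run."""

    windows: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)
    variants: tuple[str, ...] = tuple(VARIANTS)
    classifiers: tuple[str, ...] = CLASSIFIERS
    regimes: tuple[str, ...] = REGIMES
    k_folds: int = 10
    step: float = STEP
    fs: float = 1200.0
    seed: int = 0
    channel_labels: tuple[str, ...] | None = None


def _variant_columns(variant: str, n_channels: int) -> list[int]:
    """Column positions of ``variant`` inside the full 13-frequency layout."""
    full = VARIANTS["simple+alpha+harmonic"]
    wanted = VARIANTS[variant]
    per_channel: list[int] = []
    used: set[int] = set()
    for f in wanted:
        j = next(i for i, g in enumerate(full) if g == f and i not in used)
        used.add(j)
        per_channel.append(j)
    k = len(full)
    return [c * k + j for c in range(n_channels) for j in per_channel]


def _subset_variant(fm_full: FeatureMatrix, variant: str, n_channels: int) -> FeatureMatrix:
    cols = _variant_columns(variant, n_channels)
    out = FeatureMatrix(
        X=fm_full.X[:, cols],
        feature_index=[fm_full.feature_index[c] for c in cols],
        variant=variant,
        y=fm_full.y, trial_index=fm_full.trial_index,
        distractor=fm_full.distractor, pairing=fm_full.pairing,
    )
    return out


def run_grid(
    trials: Sequence[LabelledTrial],
    config: GridConfig = GridConfig(),
    participant_id: str = "",
) -> pd.DataFrame:
    """Per-participant accuracy for every requested grid cell.

    Features are extracted once per window with the full frequency set and
    column-subset per variant so every variant sees identical epochs and the
    identical balancing draw. Returns a tidy frame with one row per
    (classifier, window, variant, regime, pairing) cell.
    """
    labels = (
        list(config.channel_labels)
        if config.channel_labels
        else [f"ch{i}" for i in range(trials[0].data.shape[0])]
    )
    n_ch = len(labels)
    rows = []
    for wi, window in enumerate(config.windows):
        ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(wi,))
        rng = np.random.default_rng(ss)
        fm_full = extract_features(
            trials, window, "simple+alpha+harmonic",
            step=config.step, fs=config.fs, channel_labels=labels,
        )
        fm_full = balance_classes(fm_full, rng=rng)
        for pairing in PAIRINGS:
            in_p = fm_full.pairing == pairing
            present = fm_full.subset(in_p & (fm_full.distractor == "present"))
            absent = fm_full.subset(in_p & (fm_full.distractor == "absent"))
            for kind in config.classifiers:
                # the z-score rule uses only the two flicker amplitudes
                variants = ("simple",) if kind == "zscore" else config.variants
                for variant in variants:
                    pres_v = _subset_variant(present, variant, n_ch)
                    abs_v = _subset_variant(absent, variant, n_ch)
                    cell_seed = int(
                        np.random.SeedSequence(
                            entropy=config.seed,
                            spawn_key=(
                                wi,
                                PAIRINGS.index(pairing),
                                CLASSIFIERS.index(kind),
                                list(VARIANTS).index(variant),
                            ),
                        ).generate_state(1)[0] % (2**31)
                    )
                    for regime in config.regimes:
                        if regime == "train_present_cv10":
                            acc, n = crossvalidate_present(
                                pres_v, kind, k=config.k_folds, seed=cell_seed, pairing=pairing
                            )
                        elif regime == "train_absent_test_present":
                            acc, n = train_absent_test_present(
                                abs_v, pres_v, kind, seed=cell_seed, pairing=pairing
                            )
                        else:
                            raise ConfigurationError(f"unknown regime {regime!r}")
                        rows.append(
                            {
                                "participant": participant_id,
                                "classifier": kind,
                                "window": window,
                                "variant": variant,
                                "regime": regime,
                                "pairing": pairing,
                                "accuracy": acc,
                                "n_epochs": n,
                            }
                        )
    return pd.DataFrame(rows)


def pairing_average(results: pd.DataFrame) -> pd.DataFrame:
    """Average accuracies across the two colour-frequency pairings."""
    keys = ["participant", "classifier", "window", "variant", "regime"]
    return (
        results.groupby(keys, as_index=False)
        .agg(accuracy=("accuracy", "mean"), n_epochs=("n_epochs", "sum"))
    )
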