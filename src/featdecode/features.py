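"""Sliding-window FFT features with artifact and motion-contamination screening.

Each labelled 15 s trial is cut into overlapping epochs at five window sizes
(0.25-4 s, stepped every 0.25 s). Epochs are screened by two exclusion rules:
any sample exceeding 150 uV absolute in any channel (movement artifacts), and
more than a third of the epoch falling inside the 1 s post-onset period of a
coherent-motion target (bottom-up transients). Surviving epochs are balanced
across the two attended-colour classes within each (distractor, pairing)
stratum, zero-padded to at least 2 s for 0.5 Hz spectral resolution, Fourier
transformed, and the single-sided amplitudes at the tagged frequencies (plus
optionally their second harmonics and the alpha band) form the feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_bids import LabelledTrial
from .task_design import STIM_DURATION

WINDOW_SIZES: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)
STEP: float = 0.25
AMPLITUDE_THRESHOLD: float = 150.0   # uV, strict inequality
CONTAMINATION_PERIOD: float = 1.0    # s after each motion onset
MAX_CONTAMINATION_FRACTION: float = 1.0 / 3.0
PAD_TO: float = 2.0                  # s, minimum FFT length -> 0.5 Hz bins

FLICKER: tuple[float, ...] = (6.0, 7.5)
HARMONICS: tuple[float, ...] = (12.0, 15.0)
ALPHA_BAND: tuple[float, ...] = tuple(np.arange(8.0, 12.5, 0.5))

#: frequency list per feature-set variant (concatenated, not deduplicated,
#: so the full variant is 13 frequencies x 5 channels = 65 features)
VARIANTS: dict[str, tuple[float, ...]] = {
    "simple": FLICKER,
    "simple+harmonic": FLICKER + HARMONICS,
    "simple+alpha": FLICKER + ALPHA_BAND,
    "simple+alpha+harmonic": FLICKER + HARMONICS + ALPHA_BAND,
}


@dataclass
class EpochSet:
    """Sliding-window epochs of one trial with validity flags.

    ``epochs`` is (n x channels x samples); ``starts`` gives each epoch's
    offset from stimulation onset in seconds. ``reason`` is "ok",
    "amplitude" or "motion_overlap".
    """

    epochs: np.ndarray
    window: float
    step: float
    fs: float
    starts: np.ndarray
    valid: np.ndarray
    reason: np.ndarray

    def __len__(self) -> int:
        return self.epochs.shape[0]


def n_epochs_per_trial(window: float, step: float = STEP, duration: float = STIM_DURATION) -> int:
    """floor((duration - window) / step) + 1 epochs fit in one trial."""
    if window > duration:
        raise ConfigurationError(f"window {window}s exceeds trial duration {duration}s")
    return int(np.floor((duration - window) / step + 1e-9)) + 1


def slide_epochs(trial: LabelledTrial, window: float, step: float = STEP,
                 fs: float = 1200.0) -> EpochSet:
    """Cut one trial into sliding-window epochs at ``t = 0, step, ..., 15 - window``."""
    n = n_epochs_per_trial(window, step)
    starts = np.arange(n) * step
    ws = int(round(window * fs))
    hop = int(round(step * fs))
    view = np.lib.stride_tricks.sliding_window_view(trial.data, ws, axis=1)
    epochs = view[:, ::hop, :][:, :n, :].transpose(1, 0, 2)
    return EpochSet(
        epochs=epochs, window=window, step=step, fs=fs, starts=starts,
        valid=np.ones(n, dtype=bool), reason=np.array(["ok"] * n, dtype=object),
    )


def reject_amplitude(epochs: np.ndarray, threshold: float = AMPLITUDE_THRESHOLD) -> np.ndarray:
    """True where an epoch survives: no sample in any channel exceeds
    ``threshold`` uV in absolute value (strictly greater is excluded)."""
    epochs = np.asarray(epochs)
    return ~(np.abs(epochs).max(axis=(-2, -1)) > threshold)


def reject_motion_overlap(
    starts: np.ndarray,
    window: float,
    motion_onsets: Sequence[float],
    contamination: float = CONTAMINATION_PERIOD,
    max_fraction: float = MAX_CONTAMINATION_FRACTION,
) -> np.ndarray:
    """True where an epoch survives the motion-contamination rule.

    An epoch [t, t+window) is excluded when strictly more than
    ``max_fraction`` of it overlaps the union of the 1 s periods following
    each coherent-motion onset.
    """
    starts = np.asarray(starts, dtype=float)
    overlap = np.zeros_like(starts)
    for onset in motion_onsets:
        lo = np.maximum(starts, onset)
        hi = np.minimum(starts + window, onset + contamination)
        overlap += np.clip(hi - lo, 0.0, None)
    return ~(overlap / window > max_fraction)


def apply_exclusions(es: EpochSet, motion_onsets: Sequence[float]) -> EpochSet:
    """Stamp validity flags (amplitude first, then motion overlap) in place."""
    amp_ok = reject_amplitude(es.epochs)
    mot_ok = reject_motion_overlap(es.starts, es.window, motion_onsets)
    es.valid = amp_ok & mot_ok
    es.reason = np.where(amp_ok, np.where(mot_ok, "ok", "motion_overlap"), "amplitude")
    return es


def compute_spectrum(
    epoch: np.ndarray, fs: float = 1200.0, pad_to: float = PAD_TO
) -> tuple[np.ndarray, np.ndarray]:
    """Single-sided amplitude spectrum of a (channels x samples) epoch.

    Epochs shorter than ``pad_to`` seconds are zero-padded out to it; longer
    epochs are transformed at native length. Amplitudes are scaled by
    2 / N_signal with N_signal the *unpadded* sample count, so a unit
    sinusoid reads ~1 regardless of padding. Returns (frequencies, amplitude).
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    n_signal = epoch.shape[-1]
    n_fft = max(n_signal, int(round(pad_to * fs)))
    amp = (2.0 / n_signal) * np.abs(np.fft.rfft(epoch, n=n_fft, axis=-1))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    return freqs, amp


def _bin_indices(freqs_wanted: Sequence[float], fs: float, n_fft: int) -> np.ndarray:
    df = fs / n_fft
    idx = np.asarray(freqs_wanted, dtype=float) / df
    rounded = np.round(idx).astype(int)
    if not np.allclose(idx, rounded, atol=1e-6):
        raise ConfigurationError(
            f"frequencies {freqs_wanted} do not fall on the {df} Hz FFT grid"
        )
    return rounded


def amplitudes_at(
    epochs: np.ndarray,
    freqs_wanted: Sequence[float],
    fs: float = 1200.0,
    pad_to: float = PAD_TO,
) -> np.ndarray:
    """Single-sided amplitudes of (n x channels x samples) epochs at exact
    bin frequencies; identical to reading :func:`compute_spectrum` at those
    bins, vectorised over epochs. Returns (n x channels x len(freqs))."""
    epochs = np.asarray(epochs, dtype=float)
    n_signal = epochs.shape[-1]
    n_fft = max(n_signal, int(round(pad_to * fs)))
    idx = _bin_indices(freqs_wanted, fs, n_fft)
    spec = np.fft.rfft(epochs, n=n_fft, axis=-1)[..., idx]
    return (2.0 / n_signal) * np.abs(spec)


@dataclass
class FeatureMatrix:
    """Per-epoch FFT-amplitude features with class labels and CV metadata.

    ``X`` is (n x n_features) in channel-major, frequency-minor order;
    ``y`` holds the attended colour; ``trial_index`` supports trial-wise
    cross-validation; ``distractor``/``pairing`` identify each epoch's
    stratum.
    """

    X: np.ndarray
    feature_index: list[tuple[str, float]]
    variant: str
    y: np.ndarray
    trial_index: np.ndarray
    distractor: np.ndarray
    pairing: np.ndarray

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X[mask], feature_index=self.feature_index, variant=self.variant,
            y=self.y[mask], trial_index=self.trial_index[mask],
            distractor=self.distractor[mask], pairing=self.pairing[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{ch}_{f:g}Hz" for ch, f in self.feature_index]
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "pairing", self.pairing)
        df.insert(0, "distractor", self.distractor)
        df.insert(0, "trial", self.trial_index)
        df.insert(0, "label", self.y)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_features(
    amplitudes: np.ndarray,
    channel_labels: Sequence[str],
    freqs_used: Sequence[float],
    variant: str,
) -> tuple[np.ndarray, list[tuple[str, float]]]:
    """Flatten (n x channels x freqs) amplitudes into the feature layout.

    Channel-major, frequency-minor: all of channel 1's frequencies, then
    channel 2's, and so on.
    """
    n, n_ch, n_f = amplitudes.shape
    X = amplitudes.reshape(n, n_ch * n_f)
    index = [(ch, f) for ch in channel_labels for f in freqs_used]
    return X, index


def extract_features(
    trials: Sequence[LabelledTrial],
    window: float,
    variant: str = "simple",
    step: float = STEP,
    fs: float = 1200.0,
    channel_labels: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Run the full per-trial screening + FFT pipeline over labelled trials.

    Invalid epochs (amplitude or motion-contamination exclusions) are
    dropped; the result is *not* yet class-balanced (see
    :func:`balance_classes`).
    """
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown feature variant {variant!r}")
    freqs_used = VARIANTS[variant]
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(trials[0].data.shape[0])]

    blocks, labels, trial_idx, dists, pairings = [], [], [], [], []
    for ti, trial in enumerate(trials):
        es = slide_epochs(trial, window, step, fs)
        apply_exclusions(es, trial.spec.motion_onsets)
        if not es.valid.any():
            continue
        amps = amplitudes_at(es.epochs[es.valid], freqs_used, fs)
        blocks.append(amps)
        n_valid = int(es.valid.sum())
        labels.extend([trial.spec.cued_colour] * n_valid)
        trial_idx.extend([ti] * n_valid)
        dists.extend([trial.spec.distractor] * n_valid)
        pairings.extend([trial.spec.pairing] * n_valid)

    amplitudes = (
        np.concatenate(blocks, axis=0)
        if blocks
        else np.empty((0, len(channel_labels), len(freqs_used)))
    )
    X, index = build_features(amplitudes, channel_labels, freqs_used, variant)
    return FeatureMatrix(
        X=X, feature_index=index, variant=variant,
        y=np.asarray(labels, dtype=object), trial_index=np.asarray(trial_idx, dtype=int),
        distractor=np.asarray(dists, dtype=object), pairing=np.asarray(pairings, dtype=object),
    )


def balance_indices(
    labels: np.ndarray,
    strata: np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Boolean mask equalising class counts within each stratum.

    Epochs of the larger class are removed uniformly at random until the two
    classes match; a fixed seed reproduces the removals exactly.
    """
    rng = np.random.default_rng(rng)
    labels = np.asarray(labels)
    strata = np.asarray(strata)
    keep = np.ones(len(labels), dtype=bool)
    for s in pd.unique(strata):
        in_s = strata == s
        classes = pd.unique(labels[in_s])
        if len(classes) < 2:
            continue
        counts = {c: int((in_s & (labels == c)).sum()) for c in classes}
        target = min(counts.values())
        for c, cnt in counts.items():
            if cnt > target:
                members = np.flatnonzero(in_s & (labels == c))
                drop = rng.choice(members, size=cnt - target, replace=False)
                keep[drop] = False
    return keep


def balance_classes(
    fm: FeatureMatrix, rng: np.random.Generator | int | None = None
) -> FeatureMatrix:
    """Equalise attended-colour counts within each (distractor, pairing) stratum."""
    strata = np.array(
        [f"{d}|{p}" for d, p in zip(fm.distractor, fm.pairing)], dtype=object
    )
    return fm.subset(balance_indices(fm.y, strata, rng))
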