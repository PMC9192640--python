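"""Sliding windows, exclusion rules, balancing and FFT feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from featdecode import features as ft
from featdecode.errors import ConfigurationError
from featdecode.io_bids import LabelledTrial
from featdecode.task_design import TrialSpec


def _trial(data, onsets=(2.0, 5.0, 8.0, 11.0, 13.0), colour="black"):
    spec = TrialSpec(
        block=1, trial=1, distractor="present", cued_colour=colour,
        pairing="black6_white7.5",
        motion_onsets=tuple(onsets), motion_directions=(0, 90, 180, 270, 0),
    )
    return LabelledTrial(data=data, spec=spec, t0=0.0)


@pytest.mark.parametrize(
    "window,expected", [(0.25, 60), (0.5, 59), (1.0, 57), (2.0, 53), (4.0, 45)]
)
def test_epoch_count_closed_form(window, expected):
    assert ft.n_epochs_per_trial(window) == expected


def test_slide_epochs_layout():
    fs = 1200.0
    data = np.arange(5 * int(15 * fs), dtype=float).reshape(5, -1)
    es = ft.slide_epochs(_trial(data), window=4.0, fs=fs)
    assert es.epochs.shape == (45, 5, 4800)
    # epoch k starts at sample k*300
    assert es.epochs[3, 0, 0] == data[0, 3 * 300]
    assert es.starts[-1] == pytest.approx(11.0)
    with pytest.raises(ConfigurationError):
        ft.slide_epochs(_trial(data), window=16.0, fs=fs)


def test_single_epoch_when_window_is_trial():
    data = np.zeros((2, 18000))
    assert ft.n_epochs_per_trial(15.0) == 1


class TestAmplitudeRejection:
    def test_boundary_is_strict(self):
        e = np.zeros((2, 3, 100))
        e[0, 1, 50] = -151.0
        e[1, 2, 10] = 150.0  # exactly at threshold: kept
        e[1, 0, 11] = -150.0
        flags = ft.reject_amplitude(e)
        assert flags.tolist() == [False, True]

    def test_matches_brute_force(self, rng):
        epochs = rng.normal(0, 80, size=(300, 4, 60))
        flags = ft.reject_amplitude(epochs)
        brute = np.array(
            [not (np.abs(ep) > 150.0).any() for ep in epochs]
        )
        assert np.array_equal(flags, brute)


class TestMotionOverlapRejection:
    def test_spec_boundary_cases(self):
        # 0.25 s epoch starting at a motion onset: 100% contaminated
        assert not ft.reject_motion_overlap([5.0], 0.25, [5.0])[0]
        # 4 s epoch containing one full 1 s window: 25% <= 1/3, kept
        assert ft.reject_motion_overlap([4.0], 4.0, [5.0])[0]
        # 2 s epoch overlapping 0.7 s: 35% > 1/3, excluded
        assert not ft.reject_motion_overlap([5.3], 2.0, [5.0])[0]
        # overlap of exactly 1/3 is kept (strictly-greater rule)
        assert ft.reject_motion_overlap([1.0], 3.0, [3.0])[0]

    def test_union_of_overlapping_periods(self):
        # two onsets whose windows both intersect a 2 s epoch
        flags = ft.reject_motion_overlap([4.5], 2.0, [4.0, 6.0])
        # overlap = [4.5,5.0) + [6.0,6.5) = 1.0 -> 50% > 1/3
        assert not flags[0]

    def test_matches_brute_force(self, rng):
        onsets = [2.0, 5.0, 8.0, 11.0, 13.0]
        starts = rng.uniform(0, 13, size=500)
        window = 2.0
        flags = ft.reject_motion_overlap(starts, window, onsets)
        grid = np.linspace(0, window, 20001)[:-1]  # fine time grid oracle
        for s, flag in zip(starts[:100], flags[:100]):
            t = s + grid
            inside = np.zeros_like(t, dtype=bool)
            for o in onsets:
                inside |= (t >= o) & (t < o + 1.0)
            frac = inside.mean()
            assert flag == (not frac > 1 / 3 + 1e-9)


class TestSpectrum:
    def test_pure_tone_at_exact_bin(self):
        fs, amp_true = 1200.0, 2.3
        t = np.arange(int(2 * fs)) / fs
        epoch = amp_true * np.sin(2 * np.pi * 6.0 * t)[None, :]
        freqs, amp = ft.compute_spectrum(epoch, fs)
        assert amp[0, np.argmin(np.abs(freqs - 6.0))] == pytest.approx(amp_true, abs=1e-9)

    def test_zero_epoch(self):
        _, amp = ft.compute_spectrum(np.zeros((3, 600)), 1200.0)
        assert np.all(amp == 0)

    def test_padded_epoch_matches_direct_dft(self):
        """0.25 s epoch zero-padded to 2 s equals a brute-force DFT of the
        padded vector under 2/N_signal scaling."""
        fs = 1200.0
        rng = np.random.default_rng(5)
        x = np.sin(2 * np.pi * 6.0 * np.arange(300) / fs) + rng.normal(0, 0.3, 300)
        freqs, amp = ft.compute_spectrum(x[None, :], fs)
        padded = np.concatenate([x, np.zeros(2400 - 300)])
        n = np.arange(2400)
        for f in (6.0, 7.5, 10.0):
            k = int(round(f / 0.5))
            coeff = np.sum(padded * np.exp(-2j * np.pi * k * n / 2400))
            assert amp[0, k] == pytest.approx(2.0 / 300 * abs(coeff), rel=1e-9)

    def test_parseval_unpadded(self):
        fs = 1200.0
        rng = np.random.default_rng(6)
        x = rng.normal(size=(1, 2400))
        spec = np.fft.rfft(x[0])
        # Parseval: sum|x|^2 == (|X0|^2 + 2*sum|Xk|^2 + |XN/2|^2)/N
        lhs = np.sum(x**2)
        rhs = (abs(spec[0]) ** 2 + 2 * np.sum(np.abs(spec[1:-1]) ** 2) + abs(spec[-1]) ** 2) / 2400
        assert lhs == pytest.approx(rhs, rel=1e-6)
        # and compute_spectrum is consistent with that rfft scaling
        _, amp = ft.compute_spectrum(x, fs)
        assert amp[0, 10] == pytest.approx(2 / 2400 * abs(spec[10]), rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        scale=st.floats(1e-3, 1e3),
        freq=st.sampled_from([6.0, 7.5, 12.0, 15.0]),
        seed=st.integers(0, 2**16),
    )
    def test_amplitude_is_homogeneous_in_signal_scale(self, scale, freq, seed):
        """Scaling an epoch scales every amplitude bin by the same factor."""
        x = np.random.default_rng(seed).normal(size=(1, 300))
        base = ft.amplitudes_at(x, [freq], 1200.0)
        scaled = ft.amplitudes_at(scale * x, [freq], 1200.0)
        assert scaled == pytest.approx(scale * base, rel=1e-9)

    def test_amplitudes_at_equals_spectrum_read(self, rng):
        fs = 1200.0
        epochs = rng.normal(size=(20, 3, 300))
        wanted = (6.0, 7.5, 12.0, 15.0)
        amps = ft.amplitudes_at(epochs, wanted, fs)
        for i in (0, 7, 19):
            freqs, full = ft.compute_spectrum(epochs[i], fs)
            for j, f in enumerate(wanted):
                k = np.argmin(np.abs(freqs - f))
                assert amps[i, :, j] == pytest.approx(full[:, k], rel=1e-12)


class TestFeatureLayout:
    @pytest.mark.parametrize(
        "variant,n_feat",
        [
            ("simple", 10),
            ("simple+harmonic", 20),
            ("simple+alpha", 55),
            ("simple+alpha+harmonic", 65),
        ],
    )
    def test_feature_counts(self, variant, n_feat, noiseless_trials):
        fm = ft.extract_features(
            noiseless_trials[:4], 1.0, variant, channel_labels=list("ABCDE")
        )
        assert fm.X.shape[1] == n_feat
        assert len(fm.feature_index) == n_feat

    def test_channel_major_order(self, noiseless_trials):
        fm = ft.extract_features(
            noiseless_trials[:2], 1.0, "simple", channel_labels=list("ABCDE")
        )
        assert fm.feature_index[:4] == [("A", 6.0), ("A", 7.5), ("B", 6.0), ("B", 7.5)]

    def test_channel_permutation_permutes_blocks(self, noiseless_trials):
        trial = noiseless_trials[0]
        perm = [4, 3, 2, 1, 0]
        swapped = LabelledTrial(data=trial.data[perm], spec=trial.spec, t0=trial.t0)
        a = ft.extract_features([trial], 2.0, "simple", channel_labels=list("ABCDE"))
        b = ft.extract_features([swapped], 2.0, "simple",
                                channel_labels=[list("ABCDE")[i] for i in perm])
        blocks_a = a.X.reshape(len(a), 5, 2)
        blocks_b = b.X.reshape(len(b), 5, 2)
        assert np.allclose(blocks_a[:, perm, :], blocks_b)


class TestBalancing:
    def _fm(self, labels, strata):
        n = len(labels)
        return ft.FeatureMatrix(
            X=np.arange(n, dtype=float)[:, None],
            feature_index=[("x", 6.0)], variant="simple",
            y=np.asarray(labels, dtype=object),
            trial_index=np.arange(n),
            distractor=np.asarray([s.split("|")[0] for s in strata], dtype=object),
            pairing=np.asarray([s.split("|")[1] for s in strata], dtype=object),
        )

    def test_downsamples_larger_class(self):
        labels = ["black"] * 120 + ["white"] * 100
        fm = self._fm(labels, ["present|p1"] * 220)
        out = ft.balance_classes(fm, rng=0)
        assert (out.y == "black").sum() == (out.y == "white").sum() == 100

    def test_equal_classes_unchanged(self):
        fm = self._fm(["black"] * 50 + ["white"] * 50, ["present|p1"] * 100)
        out = ft.balance_classes(fm, rng=0)
        assert len(out) == 100

    def test_seeded_removal_reproducible(self):
        labels = ["black"] * 80 + ["white"] * 55
        fm = self._fm(labels, ["present|p1"] * 135)
        a = ft.balance_classes(fm, rng=42)
        b = ft.balance_classes(fm, rng=42)
        assert np.array_equal(a.X, b.X)

    def test_balance_is_per_stratum(self):
        labels = (["black"] * 30 + ["white"] * 20) + (["black"] * 10 + ["white"] * 25)
        strata = ["present|p1"] * 50 + ["absent|p2"] * 35
        fm = self._fm(labels, strata)
        out = ft.balance_classes(fm, rng=1)
        s1 = out.distractor == "present"
        assert (out.y[s1] == "black").sum() == (out.y[s1] == "white").sum() == 20
        assert (out.y[~s1] == "black").sum() == (out.y[~s1] == "white").sum() == 10
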