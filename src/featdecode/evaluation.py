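"""Group-level aggregation: behaviour, SSVEP amplitudes, window-size model.

Includes the inverse-exponential model of decoding accuracy as a function of
sliding-window size,

    ACC(T) = a * (1 - exp(-s * (T - i)))

with asymptote ``a`` (%), scaling factor ``s`` (1/s) and x-intercept ``i``
(s), fitted by multistart nonlinear least squares. The window achieving a
fraction q of the asymptote follows in closed form as
``T = i + ln(1/(1-q)) / s``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError
from .features import FLICKER, compute_spectrum
from .io_bids import LabelledTrial
from .task_design import BehaviouralRecord, TrialSpec

# ---------------------------------------------------------------------------
# behaviour


def behavioural_summary(
    records: Sequence[BehaviouralRecord],
    schedules: Sequence[Sequence[TrialSpec]],
    participant_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean accuracy (%) and mean RT (s) per distractor condition.

    Accuracy counts only correct responses (ACC == 1) over all targets; RT is
    averaged over correct targets only. Returns (per-participant table, group
    table); the group table carries across-participant means, SDs and a
    paired t-test between distractor conditions.
    """
    if participant_ids is None:
        participant_ids = [f"sub-{i + 1:02d}" for i in range(len(records))]
    rows = []
    for pid, record, schedule in zip(participant_ids, records, schedules):
        dist = np.array([s.distractor for s in schedule], dtype=object)
        for cond in ("present", "absent"):
            sel = dist == cond
            if not sel.any():
                rows.append(
                    {"participant": pid, "distractor": cond,
                     "accuracy": np.nan, "rt": np.nan}
                )
                continue
            acc = record.acc[sel]
            # RT is defined only for correct responses; any stray value on a
            # miss/incorrect target is ignored, per the container's coding
            rt = record.rt[sel][acc == 1]
            rt = rt[np.isfinite(rt)]
            rows.append(
                {
                    "participant": pid,
                    "distractor": cond,
                    "accuracy": 100.0 * float((acc == 1).mean()),
                    "rt": float(rt.mean()) if rt.size else np.nan,
                }
            )
    per = pd.DataFrame(rows)

    group_rows = []
    wide_acc = per.pivot(index="participant", columns="distractor", values="accuracy")
    wide_rt = per.pivot(index="participant", columns="distractor", values="rt")
    for cond in ("present", "absent"):
        group_rows.append(
            {
                "distractor": cond,
                "accuracy_mean": wide_acc[cond].mean(),
                "accuracy_sd": wide_acc[cond].std(ddof=1),
                "rt_mean": wide_rt[cond].mean(),
                "rt_sd": wide_rt[cond].std(ddof=1),
            }
        )
    group = pd.DataFrame(group_rows)
    if len(wide_acc) > 1:
        t_acc = stats.ttest_rel(wide_acc["present"], wide_acc["absent"])
        group.attrs["t_accuracy"] = (float(t_acc.statistic), float(t_acc.pvalue))
        rt_pairs = wide_rt.dropna()
        if len(rt_pairs) > 1:
            t_rt = stats.ttest_rel(rt_pairs["present"], rt_pairs["absent"])
            group.attrs["t_rt"] = (float(t_rt.statistic), float(t_rt.pvalue))
    return per, group


# ---------------------------------------------------------------------------
# SSVEP amplitudes

#: analysis length for trial-average spectra, s. The longest sub-window of a
#: 15 s trial in which both tags complete integer cycles (6.0 Hz: 84, 7.5 Hz:
#: 105), putting both (and their harmonics) on exact FFT bins. A full 15 s
#: window leaves 7.5 Hz half a cycle short of a bin and leaks ~36% of its
#: amplitude into neighbouring bins.
SSVEP_ANALYSIS_DURATION = 14.0


def ssvep_amplitudes(
    trials: Sequence[LabelledTrial],
    channel_labels: Sequence[str],
    fs: float = 1200.0,
    freqs: Sequence[float] = FLICKER,
    analysis_duration: float = SSVEP_ANALYSIS_DURATION,
) -> pd.DataFrame:
    """Trial-average SSVEP amplitudes per display cell and electrode.

    For each (distractor, pairing, cued frequency) cell the trial time series
    are averaged across trials *before* the FFT (phase-locked steady-state
    responses survive averaging; random-phase activity cancels), the average
    is truncated to ``analysis_duration`` so both tags sit on exact bins, and
    the single-sided amplitude is read at each flicker frequency for each
    electrode. ``cued`` marks whether the read-out frequency was the cued one
    in that cell.
    """
    cells: dict[tuple, list[np.ndarray]] = {}
    n_keep = int(round(analysis_duration * fs))
    for tr in trials:
        key = (tr.spec.distractor, tr.spec.pairing, tr.spec.cued_freq)
        cells.setdefault(key, []).append(tr.data[:, :n_keep])
    rows = []
    for (distractor, pairing, cued_freq), stack in sorted(cells.items()):
        avg = np.mean(stack, axis=0)
        spec_freqs, amp = compute_spectrum(avg, fs=fs, pad_to=0.0)
        for f in freqs:
            bin_idx = int(round(f / (fs / avg.shape[-1])))
            for ci, ch in enumerate(channel_labels):
                rows.append(
                    {
                        "distractor": distractor,
                        "pairing": pairing,
                        "cued_freq": cued_freq,
                        "frequency": f,
                        "cued": f == cued_freq,
                        "electrode": ch,
                        "amplitude": float(amp[ci, bin_idx]),
                        "n_trials": len(stack),
                    }
                )
    return pd.DataFrame(rows)


def attention_effect(summary: pd.DataFrame) -> pd.DataFrame:
    """Cued-minus-uncued amplitude per (distractor, frequency, electrode)."""
    keys = ["distractor", "frequency", "electrode"]
    cued = summary[summary.cued].groupby(keys)["amplitude"].mean()
    uncued = summary[~summary.cued].groupby(keys)["amplitude"].mean()
    out = (cued - uncued).rename("attention_effect").reset_index()
    return out


def grand_mean_amplitudes(summary: pd.DataFrame, distractor: str = "present") -> pd.DataFrame:
    """Electrode- and pairing-averaged amplitude per (frequency, cued)."""
    sel = summary[summary.distractor == distractor]
    return (
        sel.groupby(["frequency", "cued"], as_index=False)["amplitude"].mean()
    )


# ---------------------------------------------------------------------------
# accuracy vs window-size model


def window_model(T: np.ndarray, a: float, s: float, i: float) -> np.ndarray:
    return a * (1.0 - np.exp(-s * (np.asarray(T, dtype=float) - i)))


@dataclass
class WindowModelFit:
    """Inverse-exponential accuracy model parameters and fit diagnostics."""

    a: float          # asymptote, %
    s: float          # scaling factor, 1/s
    i: float          # x-intercept, s
    sse: float
    cov: np.ndarray | None = None

    def predict(self, T: np.ndarray | float) -> np.ndarray:
        return window_model(T, self.a, self.s, self.i)


_STARTS_A = (55.0, 65.0, 75.0)
_STARTS_S = (0.1, 0.5, 2.0)
_STARTS_I = (-1.0, 0.0, 0.2)


def fit_window_model(
    T: Sequence[float],
    ACC: Sequence[float],
    a_bounds: tuple[float, float] = (50.0, 100.0),
) -> WindowModelFit:
    """Least-squares fit of ACC = a(1 - exp(-s(T - i))) with multistart.

    Starts span a grid of plausible asymptotes, rates and intercepts; the
    solution with the lowest residual sum of squares wins. Constant or
    near-constant accuracy curves leave the rate unidentified and raise.
    """
    T = np.asarray(T, dtype=float)
    ACC = np.asarray(ACC, dtype=float)
    if T.size < 3:
        raise ConfigurationError("need at least 3 (window, accuracy) points")
    if np.ptp(ACC) < 1e-9:
        raise ConfigurationError("constant accuracy: rate parameter is unidentified")

    lo = np.array([a_bounds[0], 1e-9, -np.inf])
    hi = np.array([a_bounds[1], np.inf, np.min(T) - 1e-12])

    def residuals(p):
        return window_model(T, *p) - ACC

    best = None
    for a0 in _STARTS_A:
        for s0 in _STARTS_S:
            for i0 in _STARTS_I:
                x0 = np.clip([a0, s0, i0], lo, hi)
                try:
                    sol = optimize.least_squares(
                        residuals, x0, bounds=(lo, hi),
                        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000,
                    )
                except ValueError:
                    continue
                sse = float(2 * sol.cost)
                if sol.success and (best is None or sse < best[0]):
                    best = (sse, sol)
    if best is None:
        raise ConfigurationError("window-model fit failed to converge from any start")
    sse, sol = best
    a, s, i = (float(v) for v in sol.x)

    cov = None
    dof = T.size - 3
    if dof > 0:
        jtj = sol.jac.T @ sol.jac
        if np.linalg.cond(jtj) < 1e12:
            cov = np.linalg.inv(jtj) * sse / dof
    return WindowModelFit(a=a, s=s, i=i, sse=sse, cov=cov)


def window_for_fraction(fit: WindowModelFit, q: float = 0.99) -> float:
    """Window size at which the model reaches a fraction ``q`` of its asymptote."""
    if not 0 < q < 1:
        raise ConfigurationError("q must be in (0, 1)")
    return fit.i + np.log(1.0 / (1.0 - q)) / fit.s


# ---------------------------------------------------------------------------
# grid aggregation


def aggregate(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Group summaries of a multi-participant decoding grid.

    Input is the tidy per-cell frame (already pairing-averaged or not; the
    pairing dimension, when present, is averaged first). Returns group means
    per (classifier, regime, window, variant), the per-participant maximum
    accuracy table (max over windows and variants, per classifier and
    regime), and Bonferroni-corrected paired t-tests of each classifier
    against the z-score baseline within each regime.
    """
    df = results.copy()
    if "pairing" in df.columns:
        keys = ["participant", "classifier", "window", "variant", "regime"]
        df = df.groupby(keys, as_index=False).agg(
            accuracy=("accuracy", "mean"), n_epochs=("n_epochs", "sum")
        )

    group_means = (
        df.groupby(["classifier", "regime", "window", "variant"], as_index=False)
        .agg(accuracy=("accuracy", "mean"), sd=("accuracy", lambda x: x.std(ddof=1)))
    )

    per_part = df.groupby(["participant", "classifier", "regime"], as_index=False)[
        "accuracy"
    ].max()
    max_table = per_part.pivot_table(
        index="participant", columns=["regime", "classifier"], values="accuracy"
    )

    # classifier-average accuracy per participant (across windows and variants)
    means = df.groupby(["participant", "classifier", "regime"], as_index=False)[
        "accuracy"
    ].mean()
    tests = []
    for regime in means.regime.unique():
        sub = means[means.regime == regime].pivot(
            index="participant", columns="classifier", values="accuracy"
        )
        if "zscore" not in sub.columns or len(sub) < 2:
            continue
        others = [c for c in sub.columns if c != "zscore"]
        for c in others:
            t = stats.ttest_rel(sub[c], sub["zscore"])
            tests.append(
                {
                    "regime": regime,
                    "classifier": c,
                    "mean": sub[c].mean(),
                    "t": float(t.statistic),
                    "p": float(t.pvalue),
                    "p_bonferroni": min(1.0, float(t.pvalue) * len(others)),
                }
            )
    return {
        "group_means": group_means,
        "max_table": max_table,
        "tests_vs_zscore": pd.DataFrame(tests),
    }


def accuracy_by_window(results: pd.DataFrame, regime: str = "train_present_cv10") -> pd.DataFrame:
    """Group-mean accuracy per window (averaged over classifiers/variants)."""
    df = results[results.regime == regime]
    per_part = df.groupby(["participant", "window"], as_index=False)["accuracy"].mean()
    return per_part.groupby("window", as_index=False)["accuracy"].mean()
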