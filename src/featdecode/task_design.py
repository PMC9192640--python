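"""Trial schedule, motion-target timing, trigger codes and behavioural scoring.

The task is a cued motion-discrimination task on two intermingled fields of
flickering dots (black and white, frequency-tagged at 6.0 and 7.5 Hz). Each
trial is a 2 s colour cue followed by 15 s of dot motion containing five
500 ms bursts of coherent motion in the cued colour only. Trials are fully
counterbalanced over distractor condition (present/absent), cued colour and
colour-to-frequency pairing; coherent-motion directions are counterbalanced
within each (distractor, pairing) stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: coherent-motion directions, degrees
DIRECTIONS: tuple[int, ...] = (0, 90, 180, 270)
COLOURS: tuple[str, str] = ("black", "white")
DISTRACTORS: tuple[str, str] = ("present", "absent")
#: colour-to-flicker-frequency pairings
PAIRINGS: tuple[str, str] = ("black6_white7.5", "black7.5_white6")
FLICKER_FREQS: tuple[float, float] = (6.0, 7.5)
FEEDBACK_CODE: int = 222

#: mapping of the frame-stream key codes to motion directions (0 = no press)
KEY_TO_DIRECTION: dict[int, int] = {1: 0, 2: 90, 3: 180, 4: 270}

#: trial timing constants (seconds)
CUE_DURATION = 2.0
STIM_DURATION = 15.0
TARGET_DURATION = 0.5
N_TARGETS = 5
MIN_ONSET_AFTER_START = 1.0
MIN_GAP_AFTER_OFFSET = 1.5
MIN_BEFORE_END = 1.5
#: delay between stimulation offset and the feedback trigger (package choice)
FEEDBACK_DELAY = 0.5
#: response frame rate of the display (Hz)
FRAME_RATE = 120.0
#: key presses within this long after a motion onset are attributed to it
RESPONSE_WINDOW = 1.5


def pairing_frequency(pairing: str, colour: str) -> float:
    """Flicker frequency of ``colour`` under the given colour-frequency pairing."""
    if pairing == "black6_white7.5":
        return 6.0 if colour == "black" else 7.5
    if pairing == "black7.5_white6":
        return 7.5 if colour == "black" else 6.0
    raise ConfigurationError(f"unknown pairing {pairing!r}")


@dataclass(frozen=True)
class TrialSpec:
    """Condition labels and motion-target timing for one trial."""

    block: int
    trial: int
    distractor: str          # "present" | "absent"
    cued_colour: str         # "black" | "white"
    pairing: str             # "black6_white7.5" | "black7.5_white6"
    motion_onsets: tuple[float, ...]      # s, within the 15 s stimulation
    motion_directions: tuple[int, ...]    # degrees

    def __post_init__(self) -> None:
        if self.distractor not in DISTRACTORS:
            raise ConfigurationError(f"bad distractor {self.distractor!r}")
        if self.cued_colour not in COLOURS:
            raise ConfigurationError(f"bad colour {self.cued_colour!r}")
        pairing_frequency(self.pairing, self.cued_colour)  # validates pairing
        if len(self.motion_onsets) != len(self.motion_directions):
            raise ConfigurationError("onsets and directions differ in length")
        for d in self.motion_directions:
            if d not in DIRECTIONS:
                raise ConfigurationError(f"bad direction {d}")

    @property
    def cued_freq(self) -> float:
        return pairing_frequency(self.pairing, self.cued_colour)

    @property
    def uncued_colour(self) -> str:
        return "white" if self.cued_colour == "black" else "black"

    @property
    def uncued_freq(self) -> float:
        return pairing_frequency(self.pairing, self.uncued_colour)

    @property
    def condition(self) -> tuple[float, str, str]:
        """(cued flicker frequency, cued colour, distractor) label tuple."""
        return (self.cued_freq, self.cued_colour, self.distractor)


@dataclass
class BehaviouralRecord:
    """Per-trial behavioural matrices in the deposited coding.

    ``acc`` is (trials x targets) with 0 = miss, 1 = correct, 2 = incorrect;
    ``rt`` is the reaction time in seconds, defined (non-NaN) only where
    ``acc == 1``; ``response`` is the frame-wise key-press stream at the
    display frame rate (0 = no key, 1-4 = the four motion directions).
    """

    acc: np.ndarray
    rt: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=int)
        self.rt = np.asarray(self.rt, dtype=float)
        self.response = np.asarray(self.response, dtype=int)
        if self.acc.shape != self.rt.shape:
            raise ConfigurationError("ACC and RT shapes differ")

    def validate(self) -> list[str]:
        """Return a list of semantic warnings (empty when clean)."""
        from .errors import ValidationError

        if not np.isin(self.acc, (0, 1, 2)).all():
            raise ValidationError("ACC contains values outside {0, 1, 2}")
        if not np.isin(self.response, (0, 1, 2, 3, 4)).all():
            raise ValidationError("RESPONSE contains values outside {0..4}")
        warnings = []
        defined = ~np.isnan(self.rt)
        if (defined & (self.acc != 1)).any():
            warnings.append("RT defined on targets without a correct response")
        if (self.rt[defined] <= 0).any():
            warnings.append("non-positive RT values")
        return warnings


@dataclass(frozen=True)
class Event:
    time: float
    code: int
    kind: str  # cue_onset | trial_onset | motion_onset | feedback


@dataclass
class EventStream:
    """Time-ordered 8-bit trigger events."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ev in self.events:
            if not (0 <= ev.code <= 255):
                raise ConfigurationError(f"trigger code {ev.code} outside 0-255")
        times = [ev.time for ev in self.events]
        if any(t1 > t2 for t1, t2 in zip(times, times[1:])):
            raise ConfigurationError("event times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def shifted(self, dt: float) -> "EventStream":
        return EventStream([Event(ev.time + dt, ev.code, ev.kind) for ev in self.events])


def sample_motion_onsets(
    duration: float = STIM_DURATION,
    n_targets: int = N_TARGETS,
    min_after_onset: float = MIN_ONSET_AFTER_START,
    min_gap: float = MIN_GAP_AFTER_OFFSET,
    min_before_end: float = MIN_BEFORE_END,
    target_dur: float = TARGET_DURATION,
    rng: np.random.Generator | int | None = None,
    max_attempts: int = 100_000,
) -> tuple[float, ...]:
    """Sample coherent-motion onset times for one trial by rejection.

    Onsets are drawn uniformly in ``[min_after_onset, duration - min_before_end]``
    and accepted when, after sorting, consecutive onsets are separated by more
    than ``target_dur + min_gap`` (i.e. each burst starts more than ``min_gap``
    after the previous burst's offset). Rejection sampling keeps the marginal
    spacing distribution unbiased.
    """
    rng = np.random.default_rng(rng)
    packed = min_after_onset + n_targets * target_dur + (n_targets - 1) * min_gap + min_before_end
    if packed > duration:
        raise ConfigurationError(
            f"infeasible onset constraints: need {packed:.2f}s but trial is {duration}s"
        )
    lo, hi = min_after_onset, duration - min_before_end
    min_sep = target_dur + min_gap
    # the accept rate can be well below 1% (ordered uniforms rarely leave
    # >2 s gaps), so draw candidate sets in batches
    batch = 256
    attempts = 0
    while attempts < max_attempts:
        cand = np.sort(rng.uniform(lo, hi, size=(batch, n_targets)), axis=1)
        attempts += batch
        if n_targets <= 1:
            ok = np.zeros(batch, dtype=bool)
            ok[0] = True
        else:
            ok = (np.diff(cand, axis=1) > min_sep).all(axis=1)
        hits = np.flatnonzero(ok)
        if hits.size:
            return tuple(float(t) for t in cand[hits[0]])
    raise ConfigurationError("rejection sampling failed to find feasible onsets")


def build_trial_schedule(
    n_blocks: int = 8,
    trials_per_block: int = 20,
    seed: int | None = 0,
) -> list[TrialSpec]:
    """Generate a fully counterbalanced, randomised trial schedule.

    The 8 cells of distractor (present/absent) x cued colour (black/white) x
    colour-frequency pairing each occur equally often; within each
    (distractor, pairing) stratum the four coherent-motion directions occur
    equally often across the stratum's targets.
    """
    n_trials = n_blocks * trials_per_block
    if n_trials % 8 != 0:
        raise ConfigurationError(
            f"{n_trials} trials cannot be split over 8 counterbalancing cells"
        )
    rng = np.random.default_rng(seed)

    cells = [
        (dist, colour, pairing)
        for dist in DISTRACTORS
        for colour in COLOURS
        for pairing in PAIRINGS
    ]
    cell_seq = np.repeat(np.arange(8), n_trials // 8)
    rng.shuffle(cell_seq)

    # direction pools per (distractor, pairing) stratum: each direction appears
    # an equal number of times over all the stratum's targets
    strata = [(d, p) for d in DISTRACTORS for p in PAIRINGS]
    stratum_targets = (n_trials // 4) * N_TARGETS
    pools: dict[tuple[str, str], list[int]] = {}
    for s in strata:
        pool = np.resize(np.array(DIRECTIONS), stratum_targets)
        rng.shuffle(pool)
        pools[s] = list(pool)

    schedule: list[TrialSpec] = []
    for idx, ci in enumerate(cell_seq):
        dist, colour, pairing = cells[ci]
        pool = pools[(dist, pairing)]
        dirs = tuple(int(pool.pop()) for _ in range(N_TARGETS))
        onsets = sample_motion_onsets(rng=rng)
        schedule.append(
            TrialSpec(
                block=idx // trials_per_block + 1,
                trial=idx + 1,
                distractor=dist,
                cued_colour=colour,
                pairing=pairing,
                motion_onsets=onsets,
                motion_directions=dirs,
            )
        )
    return schedule


# ---------------------------------------------------------------------------
# trigger encoding


@dataclass
class TriggerMap:
    """Bijective map from condition tuples to 8-bit trigger codes.

    ``cue_onset`` and ``trial_onset`` are indexed by (cued flicker frequency,
    cued colour, distractor); ``motion_onset`` adds the motion direction as a
    fourth index. The feedback code is fixed at 222.
    """

    cue_onset: dict[tuple[float, str, str], int]
    trial_onset: dict[tuple[float, str, str], int]
    motion_onset: dict[tuple[float, str, str, int], int]
    feedback: int = FEEDBACK_CODE

    def __post_init__(self) -> None:
        codes = (
            list(self.cue_onset.values())
            + list(self.trial_onset.values())
            + list(self.motion_onset.values())
            + [self.feedback]
        )
        if len(set(codes)) != len(codes):
            raise ConfigurationError("trigger code collision in map")
        for c in codes:
            if not (1 <= c <= 255):
                raise ConfigurationError(f"trigger code {c} outside 1-255")
        self._decode = (
            {v: ("cue_onset", k) for k, v in self.cue_onset.items()}
            | {v: ("trial_onset", k) for k, v in self.trial_onset.items()}
            | {v: ("motion_onset", k) for k, v in self.motion_onset.items()}
            | {self.feedback: ("feedback", ())}
        )

    def decode(self, code: int) -> tuple[str, tuple]:
        """Return (event kind, condition tuple) for a trigger code."""
        try:
            return self._decode[int(code)]
        except KeyError:
            raise ConfigurationError(f"unknown trigger code {code}") from None

    def to_json(self, path) -> None:
        """Serialise the code tables (deposited datasets ship their own)."""
        import json
        from pathlib import Path

        def flatten(table):
            return {"|".join(str(k) for k in key): v for key, v in table.items()}

        payload = {
            "cue_onset": flatten(self.cue_onset),
            "trial_onset": flatten(self.trial_onset),
            "motion_onset": flatten(self.motion_onset),
            "feedback": self.feedback,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "TriggerMap":
        """Load a code table config (keys "freq|colour|distractor[|direction]")."""
        import json
        from pathlib import Path

        payload = json.loads(Path(path).read_text(encoding="utf-8"))

        def unflatten(table, with_direction):
            out = {}
            for key, v in table.items():
                parts = key.split("|")
                cond = (float(parts[0]), parts[1], parts[2])
                if with_direction:
                    cond = cond + (int(parts[3]),)
                out[cond] = int(v)
            return out

        return cls(
            cue_onset=unflatten(payload["cue_onset"], False),
            trial_onset=unflatten(payload["trial_onset"], False),
            motion_onset=unflatten(payload["motion_onset"], True),
            feedback=int(payload.get("feedback", FEEDBACK_CODE)),
        )


def canonical_trigger_map() -> TriggerMap:
    """The package's canonical synthetic code assignment.

    Cue onsets 1-8 and trial onsets 11-18 enumerate (frequency, colour,
    distractor); motion onsets 101-132 add direction; feedback is 222. Real
    recordings use deposited values loaded from a JSON config instead.
    """
    conds = [
        (f, c, d) for f in FLICKER_FREQS for c in COLOURS for d in DISTRACTORS
    ]
    cue = {k: i + 1 for i, k in enumerate(conds)}
    trial = {k: i + 11 for i, k in enumerate(conds)}
    motion = {
        (f, c, d, direction): 101 + i
        for i, (f, c, d, direction) in enumerate(
            (f, c, d, direction)
            for f in FLICKER_FREQS
            for c in COLOURS
            for d in DISTRACTORS
            for direction in DIRECTIONS
        )
    }
    return TriggerMap(cue_onset=cue, trial_onset=trial, motion_onset=motion)


def encode_triggers(spec: TrialSpec, trigger_map: TriggerMap, t0: float = 0.0) -> EventStream:
    """Trigger events of one trial, with the cue at time ``t0``.

    Emits one cue-onset, one trial-onset (stimulation start), five
    motion-onset and one feedback event.
    """
    cond = spec.condition
    t_stim = t0 + CUE_DURATION
    events = [Event(t0, trigger_map.cue_onset[cond], "cue_onset"),
              Event(t_stim, trigger_map.trial_onset[cond], "trial_onset")]
    for onset, direction in zip(spec.motion_onsets, spec.motion_directions):
        events.append(
            Event(t_stim + onset, trigger_map.motion_onset[cond + (direction,)], "motion_onset")
        )
    events.append(Event(t_stim + STIM_DURATION + FEEDBACK_DELAY, trigger_map.feedback, "feedback"))
    return EventStream(events)


def score_responses(
    response: np.ndarray,
    spec: TrialSpec,
    window: float = RESPONSE_WINDOW,
    frame_rate: float = FRAME_RATE,
    min_gap: float = MIN_GAP_AFTER_OFFSET,
    target_dur: float = TARGET_DURATION,
) -> tuple[np.ndarray, np.ndarray]:
    """Score one trial's frame-wise key-press stream against its targets.

    ``response`` holds, per display frame, 0 (no key) or a key code 1-4 for
    the four motion directions. The first key-press onset falling in
    ``(onset, onset + window]`` is attributed to that target: a matching
    direction scores 1 (correct, RT = press time - onset), a mismatch scores
    2 (incorrect), no press scores 0 (miss). RT is NaN except on correct
    targets.
    """
    if window > min_gap + target_dur:
        raise ConfigurationError(
            "response window exceeds the inter-target gap; attribution is ambiguous"
        )
    response = np.asarray(response)
    prev = np.concatenate([[0], response[:-1]])
    press_frames = np.flatnonzero((response != 0) & (prev == 0))
    press_times = press_frames / frame_rate
    press_dirs = np.array(
        [KEY_TO_DIRECTION[int(response[i])] for i in press_frames], dtype=int
    )

    n = len(spec.motion_onsets)
    acc = np.zeros(n, dtype=int)
    rt = np.full(n, np.nan)
    for i, (onset, direction) in enumerate(zip(spec.motion_onsets, spec.motion_directions)):
        in_win = np.flatnonzero((press_times > onset) & (press_times <= onset + window))
        if in_win.size == 0:
            continue
        first = in_win[0]
        if press_dirs[first] == direction:
            acc[i] = 1
            rt[i] = press_times[first] - onset
        else:
            acc[i] = 2
    return acc, rt


def schedule_to_table(schedule: Sequence[TrialSpec], frame_rate: float = FRAME_RATE) -> pd.DataFrame:
    """Tabular trial-table view of a schedule (one row per trial).

    Columns mirror the deposited behavioural trial table: BLOCK, TRIAL,
    ATTENTIONCOND (1 = distractor present, 2 = absent), cued/uncued colour
    codes (1 = black, 2 = white), the flicker frequency codes of the black and
    white dots (1 = 6.0 Hz, 2 = 7.5 Hz), and the five target onsets both as
    display-frame indices and in seconds, with their directions.
    """
    rows = []
    for s in schedule:
        row: dict[str, object] = {
            "BLOCK": s.block,
            "TRIAL": s.trial,
            "ATTENTIONCOND": 1 if s.distractor == "present" else 2,
            "COL_ATTD": COLOURS.index(s.cued_colour) + 1,
            "COL_UNATTD": COLOURS.index(s.uncued_colour) + 1,
            "FREQ_BLACK": FLICKER_FREQS.index(pairing_frequency(s.pairing, "black")) + 1,
            "FREQ_WHITE": FLICKER_FREQS.index(pairing_frequency(s.pairing, "white")) + 1,
        }
        for i, (t, d) in enumerate(zip(s.motion_onsets, s.motion_directions), start=1):
            row[f"MOVEFRAME_{i}"] = int(round(t * frame_rate))
            row[f"MOVEONSET_{i}_S"] = t
            row[f"MOVEDIR_{i}"] = d
        rows.append(row)
    return pd.DataFrame(rows)
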