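"""BIDS-EEG dataset I/O: BrainVision recordings, events, triggers, behaviour.

The deposited dataset stores each session as a BrainVision triplet
(.vhdr INI-style header, .eeg raw binary, .vmrk marker file) plus BIDS
sidecars (events.tsv, channels.tsv, *_eeg.json) and a per-participant
behavioural HDF5 container. Readers and writers here are self-contained:
the reader supports multiplexed IEEE_FLOAT_32 and INT_16 (+ per-channel
resolution) binaries and auto-detects the layout from the header; the writer
emits multiplexed IEEE_FLOAT_32.

Event codes are carried redundantly in a dedicated "TRIG" channel as
rectangular voltage pulses from a 0 uV baseline (8-bit range 0-255); the
amplitude of a pulse is the trigger value and its first supra-zero sample
marks the event onset.
"""

from __future__ import annotations

import configparser
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .task_design import (
    BehaviouralRecord,
    Event,
    EventStream,
    STIM_DURATION,
    TrialSpec,
    TriggerMap,
)

TASK_NAME = "FeatAttnDec"
TRIG_LABEL = "TRIG"


@dataclass
class Recording:
    """Continuous multichannel EEG plus its trigger channel.

    ``data`` is (channels x samples) in microvolts; ``trig`` is the
    integer-valued trigger channel (same sample count).
    """

    data: np.ndarray
    trig: np.ndarray
    fs: float
    channel_labels: list[str]
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        self.trig = np.asarray(self.trig)
        if self.data.shape[1] != self.trig.shape[0]:
            raise FormatError("data and trigger channel sample counts differ")
        if len(self.channel_labels) != self.data.shape[0]:
            raise FormatError("channel label count does not match data")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class LabelledTrial:
    """One trial's 15 s stimulation-period EEG with its condition labels."""

    data: np.ndarray      # channels x samples
    spec: TrialSpec
    t0: float             # stimulation-onset time in the recording, s


# ---------------------------------------------------------------------------
# BrainVision


def write_brainvision(recording: Recording, vhdr_path: str | Path) -> Path:
    """Write a recording as a BrainVision triplet (.vhdr/.eeg/.vmrk).

    Data are multiplexed IEEE float32 in microvolts, with the trigger channel
    appended as the last channel under the label "TRIG".
    """
    vhdr_path = Path(vhdr_path)
    stem = vhdr_path.with_suffix("")
    eeg_path, vmrk_path = stem.with_suffix(".eeg"), stem.with_suffix(".vmrk")

    labels = list(recording.channel_labels) + [TRIG_LABEL]
    stacked = np.vstack([recording.data, recording.trig[None, :]]).astype(np.float32)

    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_path.name}",
        f"MarkerFile={vmrk_path.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={len(labels)}",
        f"SamplingInterval={1e6 / recording.fs!r}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, name in enumerate(labels, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    vhdr_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    # column-per-sample (multiplexed): sample-major on disk
    stacked.T.tofile(eeg_path)

    vmrk_path.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n"
        "[Common Infos]\n"
        "Codepage=UTF-8\n"
        f"DataFile={eeg_path.name}\n"
        "[Marker Infos]\n",
        encoding="utf-8",
    )
    return vhdr_path


def _parse_vhdr(vhdr_path: Path) -> configparser.ConfigParser:
    text = vhdr_path.read_text(encoding="utf-8", errors="replace")
    # drop the magic first line (and anything else before the first section)
    body = text[text.index("[") :] if "[" in text else text
    parser = configparser.ConfigParser(
        delimiters=("=",), comment_prefixes=(";",), strict=False, interpolation=None
    )
    parser.optionxform = str  # keep key case
    parser.read_string(body)
    return parser


def read_brainvision(vhdr_path: str | Path) -> Recording:
    """Read a BrainVision recording; the TRIG channel is split out by label.

    Supports multiplexed and vectorized orientations with IEEE_FLOAT_32 or
    INT_16 (scaled by each channel's resolution) binary layouts.
    """
    vhdr_path = Path(vhdr_path)
    if not vhdr_path.exists():
        raise FormatError(f"missing header file {vhdr_path}")
    hdr = _parse_vhdr(vhdr_path)
    try:
        common = hdr["Common Infos"]
        eeg_name = common["DataFile"]
        n_channels = int(common["NumberOfChannels"])
        fs = 1e6 / float(common["SamplingInterval"])
        orientation = common.get("DataOrientation", "MULTIPLEXED").upper()
        binfmt = hdr["Binary Infos"].get("BinaryFormat", "IEEE_FLOAT_32").upper()
        chan_section = hdr["Channel Infos"]
    except (KeyError, ValueError) as exc:
        raise FormatError(f"malformed BrainVision header: {exc}") from exc

    labels, resolutions = [], []
    for i in range(1, n_channels + 1):
        entry = chan_section.get(f"Ch{i}")
        if entry is None:
            raise FormatError(f"missing channel entry Ch{i}")
        parts = entry.split(",")
        labels.append(parts[0])
        res = parts[2] if len(parts) > 2 and parts[2] else "1"
        resolutions.append(float(res))

    eeg_path = vhdr_path.parent / eeg_name
    if not eeg_path.exists():
        raise FormatError(f"header references missing data file {eeg_name}")
    if binfmt == "IEEE_FLOAT_32":
        raw = np.fromfile(eeg_path, dtype="<f4")
    elif binfmt == "INT_16":
        raw = np.fromfile(eeg_path, dtype="<i2")
    else:
        raise FormatError(f"unsupported BinaryFormat={binfmt}")
    if raw.size == 0:
        raise FormatError(f"empty data file {eeg_name}")
    if raw.size % n_channels:
        raise FormatError("data file size is not a multiple of the channel count")

    if orientation == "MULTIPLEXED":
        data = raw.reshape(-1, n_channels).T
    elif orientation == "VECTORIZED":
        data = raw.reshape(n_channels, -1)
    else:
        raise FormatError(f"unsupported DataOrientation={orientation}")
    data = data.astype(np.float64) * np.asarray(resolutions)[:, None]

    if TRIG_LABEL in labels:
        ti = labels.index(TRIG_LABEL)
        trig = data[ti]
        keep = [i for i in range(n_channels) if i != ti]
        data = data[keep]
        labels = [labels[i] for i in keep]
    else:
        trig = np.zeros(data.shape[1])

    pid = vhdr_path.name.split("_")[0] if vhdr_path.name.startswith("sub-") else ""
    return Recording(data=data, trig=trig, fs=fs, channel_labels=labels, participant_id=pid)


# ---------------------------------------------------------------------------
# trigger channel


def parse_trigger_channel(trig: np.ndarray, fs: float) -> EventStream:
    """Recover the event list from a raw trigger channel.

    One event per rising step from the 0 uV baseline; the event code is the
    rounded median of the plateau (robust to filtering ripple) and the event
    time is the first supra-zero sample divided by the sampling rate.
    """
    trig = np.asarray(trig, dtype=float)
    high = trig > 0.5
    rises = np.flatnonzero(high & ~np.concatenate([[False], high[:-1]]))
    falls = np.flatnonzero(~high & np.concatenate([[False], high[:-1]]))
    events = []
    for r in rises:
        nxt = falls[falls > r]
        end = nxt[0] if nxt.size else trig.size
        code = float(np.median(trig[r:end]))
        rounded = int(round(code))
        if code < 0 or rounded > 255:
            raise ValidationError(f"trigger value {code} outside 0-255 at sample {r}")
        events.append(Event(time=r / fs, code=rounded, kind="pulse"))
    return EventStream(events)


def _pairing_from(freq: float, colour: str) -> str:
    if (colour == "black") == (freq == 6.0):
        return "black6_white7.5"
    return "black7.5_white6"


def decode_trials(
    events: EventStream,
    trigger_map: TriggerMap,
    recording: Recording,
    trials_per_block: int = 20,
) -> list[LabelledTrial]:
    """Group a session's events into labelled 15 s stimulation epochs.

    Each trial must present a cue-onset and trial-onset code agreeing on the
    (frequency, colour, distractor) condition, five motion-onset codes (whose
    fourth index gives the direction) and the feedback code.
    """
    fs = recording.fs
    n_stim = int(round(STIM_DURATION * fs))
    trials: list[LabelledTrial] = []
    state: dict | None = None
    for ev in events:
        kind, cond = trigger_map.decode(ev.code)
        if kind == "cue_onset":
            state = {"cond": cond, "onsets": [], "dirs": []}
        elif state is None:
            raise ValidationError(f"event code {ev.code} before any cue onset")
        elif kind == "trial_onset":
            if cond != state["cond"]:
                raise ValidationError(
                    f"trial {len(trials) + 1}: cue condition {state['cond']} "
                    f"does not match trial-onset condition {cond}"
                )
            state["t0"] = ev.time
        elif kind == "motion_onset":
            if cond[:3] != state["cond"]:
                raise ValidationError(
                    f"trial {len(trials) + 1}: motion condition mismatch"
                )
            state["onsets"].append(ev.time - state["t0"])
            state["dirs"].append(cond[3])
        elif kind == "feedback":
            freq, colour, distractor = state["cond"]
            idx = len(trials)
            spec = TrialSpec(
                block=idx // trials_per_block + 1,
                trial=idx + 1,
                distractor=distractor,
                cued_colour=colour,
                pairing=_pairing_from(freq, colour),
                motion_onsets=tuple(state["onsets"]),
                motion_directions=tuple(state["dirs"]),
            )
            i0 = int(round(state["t0"] * fs))
            trials.append(
                LabelledTrial(data=recording.data[:, i0 : i0 + n_stim], spec=spec, t0=state["t0"])
            )
            state = None
    return trials


# ---------------------------------------------------------------------------
# BIDS sidecars


def write_events_tsv(events: EventStream, path: str | Path, pulse_duration: float = 0.1) -> None:
    df = pd.DataFrame(
        {
            "onset": [ev.time for ev in events],
            "duration": pulse_duration,
            "value": [ev.code for ev in events],
            "trial_type": [ev.kind for ev in events],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events_tsv(path: str | Path) -> EventStream:
    df = pd.read_csv(path, sep="\t")
    kinds = df["trial_type"] if "trial_type" in df else ["pulse"] * len(df)
    return EventStream(
        [Event(float(t), int(v), str(k)) for t, v, k in zip(df["onset"], df["value"], kinds)]
    )


def write_channels_tsv(recording: Recording, path: str | Path) -> None:
    labels = list(recording.channel_labels) + [TRIG_LABEL]
    df = pd.DataFrame(
        {
            "name": labels,
            "type": ["EEG"] * len(recording.channel_labels) + ["TRIG"],
            "units": "µV",
            "sampling_frequency": recording.fs,
            "status": "good",
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_eeg_json(recording: Recording, path: str | Path) -> None:
    meta = {
        "TaskName": TASK_NAME,
        "SamplingFrequency": recording.fs,
        "PowerLineFrequency": 50,
        "EEGChannelCount": len(recording.channel_labels),
        "TriggerChannelCount": 1,
        "EEGReference": "earclip",
        "SoftwareFilters": "n/a",
        "HardwareFilters": {
            "BandPass": {"low_cutoff_Hz": 1, "high_cutoff_Hz": 100},
            "Notch": {"band_Hz": [48, 52]},
        },
        "RecordingDuration": recording.n_samples / recording.fs,
    }
    Path(path).write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# behavioural container (HDF5)


def write_behaviour(
    trial_table: pd.DataFrame, record: BehaviouralRecord, path: str | Path
) -> None:
    """Write the behavioural container: TRIAL_TABLE columns, RESPONSE, ACC, RT."""
    with h5py.File(path, "w") as f:
        g = f.create_group("TRIAL_TABLE")
        for col in trial_table.columns:
            g.create_dataset(col, data=trial_table[col].to_numpy())
        f.create_dataset("RESPONSE", data=record.response.astype(np.int8))
        f.create_dataset("ACC", data=record.acc.astype(np.int8))
        f.create_dataset("RT", data=record.rt)


def read_behaviour(path: str | Path) -> tuple[pd.DataFrame, BehaviouralRecord]:
    """Read the behavioural container, validating the deposited coding.

    Raises :class:`ValidationError` on enum violations (e.g. ACC values
    outside {0, 1, 2}); semantic oddities such as RTs on non-correct targets
    are reported as warnings.
    """
    with h5py.File(path, "r") as f:
        for name in ("TRIAL_TABLE", "RESPONSE", "ACC", "RT"):
            if name not in f:
                raise FormatError(f"behavioural container missing dataset {name!r}")
        table = pd.DataFrame({col: f["TRIAL_TABLE"][col][()] for col in f["TRIAL_TABLE"]})
        record = BehaviouralRecord(
            acc=f["ACC"][()], rt=f["RT"][()], response=f["RESPONSE"][()]
        )
    for msg in record.validate():
        warnings.warn(msg, stacklevel=2)
    return table, record


# ---------------------------------------------------------------------------
# participant-level tree


def participant_paths(root: str | Path, participant_id: str) -> dict[str, Path]:
    root = Path(root)
    eeg_dir = root / participant_id / "eeg"
    beh_dir = root / participant_id / "beh"
    base = f"{participant_id}_task-{TASK_NAME}"
    return {
        "eeg_dir": eeg_dir,
        "beh_dir": beh_dir,
        "vhdr": eeg_dir / f"{base}_eeg.vhdr",
        "eeg": eeg_dir / f"{base}_eeg.eeg",
        "vmrk": eeg_dir / f"{base}_eeg.vmrk",
        "json": eeg_dir / f"{base}_eeg.json",
        "events": eeg_dir / f"{base}_events.tsv",
        "channels": eeg_dir / f"{base}_channels.tsv",
        "behaviour": beh_dir / f"{base}_beh.h5",
    }


def write_participant(
    root: str | Path,
    recording: Recording,
    events: EventStream,
    trial_table: pd.DataFrame,
    behaviour: BehaviouralRecord,
) -> dict[str, Path]:
    paths = participant_paths(root, recording.participant_id)
    paths["eeg_dir"].mkdir(parents=True, exist_ok=True)
    paths["beh_dir"].mkdir(parents=True, exist_ok=True)
    write_brainvision(recording, paths["vhdr"])
    write_events_tsv(events, paths["events"])
    write_channels_tsv(recording, paths["channels"])
    write_eeg_json(recording, paths["json"])
    write_behaviour(trial_table, behaviour, paths["behaviour"])
    return paths


def validate_bids_tree(root: str | Path) -> list[str]:
    """Structural check of a written dataset; returns the participant ids.

    Raises :class:`FormatError` if the dataset description or any of a
    participant's six EEG files / behavioural container is missing.
    """
    root = Path(root)
    problems = []
    if not (root / "dataset_description.json").exists():
        problems.append("missing dataset_description.json")
    subs = sorted(p.name for p in root.glob("sub-*") if p.is_dir())
    if not subs:
        problems.append("no sub-* participant folders")
    for sub in subs:
        paths = participant_paths(root, sub)
        for key in ("vhdr", "eeg", "vmrk", "json", "events", "channels", "behaviour"):
            if not paths[key].exists():
                problems.append(f"{sub}: missing {paths[key].name}")
    if problems:
        raise FormatError("; ".join(problems))
    return subs
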