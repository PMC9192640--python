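#!/usr/bin/env python
"""Simulate a frequency-tagged attention study and deposit it as BIDS-EEG.

Writes sub-*/eeg BrainVision triplets + sidecars and sub-*/beh behavioural
containers under --out (default scratch/bids_sim), for the downstream
decoding and summary scripts.
"""

import argparse
from pathlib import Path

from featdecode import synthetic_data as sd

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--n-participants", type=int, default=4)
ap.add_argument("--out", type=Path, default=Path("scratch/bids_sim"))
ap.add_argument("--overwrite", action="store_true")
args = ap.parse_args()

cfg = sd.SimulationConfig(n_participants=args.n_participants, seed=args.seed)
participants = sd.simulate_study(cfg)
root = sd.write_bids_dataset(participants, args.out, overwrite=args.overwrite)

n_trials = len(participants[0].schedule)
dur = participants[0].recording.n_samples / cfg.fs
print(f"wrote {len(participants)} participants to {root}")
print(f"  {n_trials} trials each, {dur:.0f} s of {cfg.fs:.0f} Hz EEG per session")
print(f"  SSVEP amplitudes (uV): {cfg.ssvep_amp}")
print(f"  noise {cfg.noise_scale} uV (1/f^{cfg.noise_exponent}), alpha {cfg.alpha_amp} uV")
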