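#!/usr/bin/env python
"""Behavioural performance on the motion-discrimination task.

Summarises accuracy (% correct of the five coherent-motion targets per
trial) and mean RT on correct targets, split by distractor condition, per
participant and at the group level with a paired t-test between conditions.
"""

import argparse
from pathlib import Path

from _load import load_dataset
from featdecode import evaluation as ev, task_design as td

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--bids", type=Path, default=Path("scratch/bids_sim"))
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

dataset = load_dataset(args.bids)
records = [beh for _, beh, _ in dataset.values()]
schedules = [[t.spec for t in trials] for trials, _, _ in dataset.values()]

per, group = ev.behavioural_summary(records, schedules, participant_ids=list(dataset))
per.to_csv(args.out / "behaviour_per_participant.tsv", sep="\t", index=False)
group.to_csv(args.out / "behaviour_group.tsv", sep="\t", index=False)

for _, row in group.iterrows():
    print(
        f"distractor {row.distractor}: accuracy {row.accuracy_mean:.2f}% "
        f"(SD {row.accuracy_sd:.2f}), RT {row.rt_mean:.3f} s (SD {row.rt_sd:.3f})"
    )
if "t_accuracy" in group.attrs:
    t, p = group.attrs["t_accuracy"]
    print(f"accuracy, present vs absent: t = {t:.2f}, p = {p:.2g}")
if "t_rt" in group.attrs:
    t, p = group.attrs["t_rt"]
    print(f"RT, present vs absent: t = {t:.2f}, p = {p:.2g}")
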