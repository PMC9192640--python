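"""Shared loader for the analysis drivers: read a BIDS tree back into
labelled trials and behavioural records."""

from pathlib import Path

from featdecode import io_bids, task_design as td


def load_dataset(root: Path):
    """Return {participant_id: (trials, behaviour, trial_table)}."""
    sub_ids = io_bids.validate_bids_tree(root)
    tmap = td.canonical_trigger_map()
    out = {}
    for sub in sub_ids:
        paths = io_bids.participant_paths(root, sub)
        rec = io_bids.read_brainvision(paths["vhdr"])
        events = io_bids.parse_trigger_channel(rec.trig, rec.fs)
        trials = io_bids.decode_trials(events, tmap, rec)
        table, beh = io_bids.read_behaviour(paths["behaviour"])
        out[sub] = (trials, beh, table)
    return out
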