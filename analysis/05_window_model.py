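#!/usr/bin/env python
"""Fit ACC = a(1 - exp(-s(T - i))) to accuracy as a function of window size.

Reads the decoding grid written by 02_decode_attention.py, averages accuracy
per window across participants (present-trained CV), fits the
inverse-exponential model by multistart least squares per classifier, and
reports the asymptote and the window reaching 99% of it. With only five
windows up to 4 s the asymptote can be weakly identified (it may run to the
100% bound when the curve is still rising); the fit diagnostics are saved
alongside the parameters.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from featdecode import evaluation as ev

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--grid", type=Path, default=Path("results/decoding_grid.tsv"))
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

grid = pd.read_csv(args.grid, sep="\t")
fits = {}
for clf in sorted(grid.classifier.unique()):
    curve = ev.accuracy_by_window(grid[grid.classifier == clf])
    try:
        fit = ev.fit_window_model(curve.window.to_numpy(), curve.accuracy.to_numpy())
    except Exception as exc:
        print(f"{clf}: fit failed ({exc})")
        continue
    w99 = ev.window_for_fraction(fit, 0.99)
    fits[clf] = {"a": fit.a, "s": fit.s, "i": fit.i, "sse": fit.sse,
                 "window_99pct_s": w99,
                 "curve": dict(zip(curve.window, curve.accuracy))}
    print(
        f"{clf}: asymptote {fit.a:.2f}%, rate {fit.s:.3f}/s, intercept "
        f"{fit.i:.3f} s -> 99% of asymptote at {w99:.2f} s (SSE {fit.sse:.3f})"
    )

(args.out / "window_model.json").write_text(json.dumps(fits, indent=2) + "\n")
print(f"wrote {args.out / 'window_model.json'}")
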