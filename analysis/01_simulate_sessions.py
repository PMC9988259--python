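#!/usr/bin/env python
"""Simulate a demo batch of cue-conflict recalibration sessions.

Eight sessions (alternating Delta+ / Delta-) with two simultaneously recorded
VIP-like neurons each, written as CSV session directories under
scratch/demo/sessions/ (bulky, regenerated on demand).  Later numbered
scripts analyze exactly these files and write their tables under results/.
"""

import argparse
from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from recalib import pipeline

CONFIG = {"n_sessions": 8, "area": "VIP-like", "neurons_per_session": 2, "n_boot": 200}
OUT = Path(__file__).resolve().parents[1] / "scratch" / "demo"

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()
    paths = pipeline.simulate_stage(CONFIG, args.seed, OUT)
    n_trials = sum(1 for _ in open(paths[0] / "trials.csv")) - 1
    print(f"wrote {len(paths)} sessions under {OUT / 'sessions'}")
    print(f"each session: {n_trials} trials (pre / Delta-ramp / post), 2 neurons")
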