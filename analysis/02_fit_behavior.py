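#!/usr/bin/env python
"""Fit psychometric curves per session and cue; measure perceptual PSE shifts.

Reads the sessions written by 01_simulate_sessions.py, fits lapse-free and
lapse-bounded cumulative Gaussians to the single-cue pre- and post-block
choices, and writes results/behavior_shifts.csv plus the per-group summary
(results/behavior_summary.csv).  Expected pattern: vestibular and visual
shifts have opposite signs, flipping with the Delta direction.
"""

from pathlib import Path
import sys

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from recalib import psychometrics, session_io

ROOT = Path(__file__).resolve().parents[1] / "results"
SESSIONS = Path(__file__).resolve().parents[1] / "scratch" / "demo" / "sessions"

if __name__ == "__main__":
    sessions = [
        session_io.read_session(p) for p in sorted((SESSIONS).iterdir())
    ]
    shifts = pd.concat(
        [psychometrics.session_behavior_shifts(s) for s in sessions], ignore_index=True
    )
    summary = psychometrics.behavioral_summary(shifts)
    session_io.write_results({"behavior_shifts": shifts, "behavior_summary": summary}, ROOT)
    print(summary[["group", "n", "mean_shift_deg", "sem_shift_deg", "p"]].to_string(index=False))
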