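#!/usr/bin/env python
"""Pool neuronal and perceptual shifts: correlations and model comparison.

Merges results/behavior_shifts.csv and results/neuron_shifts.csv into
per-(session, cue) shift records, computes the Pearson correlation between
neuronal and perceptual PSE shifts per cue (screened records, both Delta
signs in one cloud), and, when at least two monkeys are present, compares a
pooled regression against a by-monkey random-slope mixed model via AIC/BIC.
Writes results/group_stats.csv.
"""

from pathlib import Path
import sys

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from recalib import group_stats, session_io

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    behavior = pd.read_csv(ROOT / "behavior_shifts.csv")
    neurons = pd.read_csv(ROOT / "neuron_shifts.csv")
    records = neurons.merge(
        behavior[["session_id", "cue", "perceptual_shift_deg"]], on=["session_id", "cue"]
    )
    rows = []
    for cue, grp in records.groupby("cue", sort=True):
        row = {"cue": cue}
        try:
            row.update(group_stats.neuronal_perceptual_correlation(grp))
        except ValueError as e:
            row["note"] = str(e)
        try:
            row.update(group_stats.mixed_model_comparison(grp))
        except ValueError:
            pass
        rows.append(row)
    out = pd.DataFrame(rows)
    session_io.write_results({"group_stats": out}, ROOT)
    print(out.to_string(index=False))
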