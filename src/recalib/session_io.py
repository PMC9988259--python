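"""Read/write sessions and result tables as diff-able delimited text.

A session directory holds ``trials.csv`` (one row per trial), ``spikes.csv``
(long format: neuron, trial, bin start, count) and ``meta.json`` (schema
version, time grid, paradigm config, and -- for simulated sessions -- the
generative truth used by recovery tests).  Floats are written at full
``repr`` precision so a round-trip is exact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .synthetic_data import (
    BLOCKS,
    TRIAL_COLUMNS,
    BehaviorProfile,
    NeuronProfile,
    ParadigmConfig,
    SessionData,
)

__all__ = ["write_session", "read_session", "write_results", "SchemaError"]

SCHEMA_VERSION = "1"
_MODALITIES = ("vestibular", "visual", "combined")
_CHOICES = ("left", "right", "none")


class SchemaError(ValueError):
    """A session file violates the expected schema; names the offending field."""


def _float_fmt(x) -> str:
    return "" if pd.isna(x) else repr(float(x))


def write_session(session: SessionData, path: str | Path) -> Path:
    """Write one session to ``path`` (created if needed); returns the path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    trials = session.trials.copy()
    for col in ("heading_deg", "vest_heading_deg", "vis_heading_deg", "delta_deg"):
        trials[col] = trials[col].map(_float_fmt)
    trials.to_csv(path / "trials.csv", index=False)

    edges = np.asarray(session.bin_edges_s, dtype=float)
    rows = []
    starts = edges[:-1]
    for nid in sorted(session.spikes):
        mat = session.spikes[nid]
        tids = session.trials["trial_id"].to_numpy()
        rows.append(
            pd.DataFrame(
                {
                    "neuron_id": nid,
                    "trial_id": np.repeat(tids, len(starts)),
                    "bin_start_s": [repr(float(s)) for s in np.tile(starts, len(tids))],
                    "count": mat.reshape(-1).astype(np.int64),
                }
            )
        )
    spikes = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["neuron_id", "trial_id", "bin_start_s", "count"])
    )
    spikes.to_csv(path / "spikes.csv", index=False)

    meta = {
        "schema_version": SCHEMA_VERSION,
        "monkey_id": session.monkey_id,
        "session_id": session.session_id,
        "area": session.area,
        "bin_width_s": float(edges[1] - edges[0]) if edges.size > 1 else None,
        "grid_start_s": float(edges[0]),
        "grid_end_s": float(edges[-1]),
        "n_bins": int(edges.size - 1),
        "config": dataclasses.asdict(session.config),
        "behavior": session.behavior.to_dict() if session.behavior is not None else None,
        "neurons": {nid: prof.to_dict() for nid, prof in session.neurons.items()},
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def _check_vocab(series: pd.Series, allowed, field: str) -> None:
    bad = set(series.unique()) - set(allowed)
    if bad:
        raise SchemaError(f"{field}: unexpected values {sorted(bad)!r}")


def read_session(path: str | Path) -> SessionData:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    meta_file = path / "meta.json"
    if not meta_file.exists():
        raise SchemaError("meta.json: missing")
    meta = json.loads(meta_file.read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(f"schema_version: expected {SCHEMA_VERSION!r}")

    trials = pd.read_csv(path / "trials.csv", dtype={"choice": str})
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise SchemaError(", ".join(sorted(missing)))
    trials = trials[list(TRIAL_COLUMNS)]
    for col in ("heading_deg", "vest_heading_deg", "vis_heading_deg", "delta_deg"):
        trials[col] = pd.to_numeric(trials[col])
    if not np.isfinite(trials["heading_deg"]).all():
        raise SchemaError("heading_deg: non-finite values")
    _check_vocab(trials["block"], BLOCKS, "block")
    _check_vocab(trials["modality"], _MODALITIES, "modality")
    _check_vocab(trials["choice"], _CHOICES, "choice")
    trials = trials.astype({"trial_id": int, "rewarded": bool})

    n_bins = int(meta["n_bins"])
    edges = np.asarray(
        [meta["grid_start_s"] + k * meta["bin_width_s"] for k in range(n_bins + 1)]
    )
    spikes_df = pd.read_csv(path / "spikes.csv")
    spikes: dict[str, np.ndarray] = {}
    tid_order = trials["trial_id"].to_numpy()
    for nid, grp in spikes_df.groupby("neuron_id", sort=True):
        if len(grp) != len(trials) * n_bins:
            raise SchemaError(f"spikes[{nid}]: ragged grid")
        counts = grp["count"].to_numpy()
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise SchemaError(f"spikes[{nid}].count: nonnegative integers required")
        mat = counts.reshape(len(trials), n_bins)
        # rows were written in trial order; verify alignment
        written_tids = grp["trial_id"].to_numpy()[::n_bins]
        if not np.array_equal(written_tids, tid_order):
            order = np.argsort(written_tids)
            mat = mat[order][np.argsort(np.argsort(tid_order))]
        spikes[str(nid)] = mat.astype(np.int64)

    cfg = ParadigmConfig(
        **{**meta["config"], "headings_deg": tuple(meta["config"]["headings_deg"])}
    )
    behavior = BehaviorProfile(**meta["behavior"]) if meta.get("behavior") else None
    neurons = {nid: NeuronProfile(**d) for nid, d in (meta.get("neurons") or {}).items()}
    return SessionData(
        trials=trials,
        spikes=spikes,
        bin_edges_s=edges,
        config=cfg,
        behavior=behavior,
        neurons=neurons,
        monkey_id=meta.get("monkey_id", "sim"),
        session_id=meta.get("session_id", "s000"),
        area=meta.get("area", ""),
    )


def write_results(tables: Mapping[str, pd.DataFrame], path: str | Path) -> dict[str, Path]:
    """Write named result tables, one CSV per table, deterministic column order."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    seen: set[str] = set()
    out: dict[str, Path] = {}
    for name, df in tables.items():
        key = name.lower()
        if key in seen:
            raise ValueError(f"duplicate table name {name!r}")
        seen.add(key)
        f = path / f"{name}.csv"
        df.to_csv(f, index=False)
        out[name] = f
    return out
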