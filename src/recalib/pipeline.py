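"""End-to-end experiment runner: simulate -> fit -> decompose -> pool.

One run emulates a batch of recording sessions from one area profile: each
session gets its own generative observer (drawn around the study's mean
cue-conflict shifts), a small population of simultaneously recorded neurons,
and the full three-block trial schedule.  Stages write delimited result
tables plus a JSON manifest; a fixed root seed is fanned out to per-stage
child seeds so two runs with the same config and seed produce byte-identical
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import choice_analysis, group_stats, neurometrics, psychometrics, session_io
from .synthetic_data import (
    BehaviorProfile,
    ParadigmConfig,
    make_area_population,
    sample_session_behavior,
    simulate_session,
)

__all__ = ["DEFAULT_CONFIG", "run_experiment", "simulate_stage", "load_config"]

log = logging.getLogger("recalib")

DEFAULT_CONFIG: dict = {
    "n_sessions": 6,
    "area": "VIP-like",
    "neurons_per_session": 2,
    "delta_signs": "alternate",  # 'alternate', '+', or '-'
    "monkeys": ["D", "K"],
    "n_boot": 200,
    "lapse_fit": "free",
    "paradigm": {},  # ParadigmConfig field overrides
    # optional fixed generative observer; None -> per-session draws around
    # the study conditions.  Fields as BehaviorProfile.from_shifts:
    # {pse_pre, shift: {vestibular, visual}, sigma, lapse}
    "behavior": None,
}


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML/JSON config file over the defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        import yaml

        user = yaml.safe_load(Path(path).read_text()) or {}
        for k, v in user.items():
            if k == "paradigm" and isinstance(v, Mapping):
                cfg["paradigm"].update(v)
            else:
                cfg[k] = v
    return cfg


def _config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _session_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _delta_sign(cfg: Mapping, i: int) -> str:
    mode = cfg.get("delta_signs", "alternate")
    if mode in ("+", "-"):
        return mode
    return "+" if i % 2 == 0 else "-"


def simulate_stage(cfg: Mapping, seed: int, out_dir: Path) -> list[Path]:
    """Simulate all sessions and write them under ``out_dir/sessions``."""
    paths = []
    seeds = _session_seeds(seed, int(cfg["n_sessions"]))
    monkeys = list(cfg.get("monkeys") or ["D"])
    for i, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        dsign = _delta_sign(cfg, i)
        paradigm = ParadigmConfig(
            **{
                **cfg.get("paradigm", {}),
                "delta_max_deg": abs(
                    cfg.get("paradigm", {}).get("delta_max_deg", 10.0)
                ) * (1 if dsign == "+" else -1),
                "rng_seed": s,
            }
        )
        if cfg.get("behavior"):
            behavior = BehaviorProfile.from_shifts(**cfg["behavior"])
        else:
            behavior = sample_session_behavior(dsign, rng)
        neurons = make_area_population(cfg["area"], int(cfg["neurons_per_session"]), behavior, rng)
        session = simulate_session(
            paradigm,
            behavior,
            neurons,
            rng=rng,
            monkey_id=monkeys[i % len(monkeys)],
            session_id=f"s{i:03d}",
            area=str(cfg["area"]),
        )
        p = session_io.write_session(session, out_dir / "sessions" / session.session_id)
        log.info("simulated session %s (%d trials, %d neurons)", session.session_id,
                 len(session.trials), len(session.spikes))
        paths.append(p)
    return paths


def _load_sessions(out_dir: Path):
    root = Path(out_dir) / "sessions"
    return [session_io.read_session(p) for p in sorted(root.iterdir()) if p.is_dir()]


def run_experiment(config: Mapping | str | Path | None, seed: int, out_dir: str | Path) -> dict:
    """Run all stages and return the manifest (also written to manifest.json)."""
    cfg = load_config(config) if not isinstance(config, Mapping) else {**DEFAULT_CONFIG, **config}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "simulate"
    try:
        simulate_stage(cfg, seed, out_dir)
        sessions = _load_sessions(out_dir)

        stage = "fit-behavior"
        behavior = pd.concat(
            [psychometrics.session_behavior_shifts(s, lapse=cfg["lapse_fit"]) for s in sessions],
            ignore_index=True,
        )
        try:
            summary = psychometrics.behavioral_summary(behavior)
        except ValueError as e:
            log.warning("behavioral summary unavailable: %s", e)
            summary = pd.DataFrame(
                columns=["group", "cue", "delta_sign", "n", "mean_shift_deg",
                         "sem_shift_deg", "t", "p", "flag"]
            )

        stage = "fit-neurons"
        boot_seeds = _session_seeds(seed + 1, len(sessions))
        neuron_rows = []
        for s, bs in zip(sessions, boot_seeds):
            neuron_rows.append(
                neurometrics.analyze_session_neurons(
                    s, n_boot=int(cfg["n_boot"]), rng=np.random.default_rng(bs)
                ).assign(area=s.area)
            )
        neurons = pd.concat(neuron_rows, ignore_index=True)
        n_pass = int(neurons["passed_screen"].sum())
        log.info("screened neurons: %d/%d passed", n_pass, len(neurons))

        stage = "choice-analysis"
        partials = pd.concat(
            [choice_analysis.session_partial_correlations(s) for s in sessions],
            ignore_index=True,
        )
        try:
            partial_tests = choice_analysis.compare_pre_post_partials(partials)
        except ValueError as e:
            log.warning("pre/post partial-correlation tests unavailable: %s", e)
            partial_tests = pd.DataFrame(
                columns=["cue", "quantity", "n", "mean_diff", "t", "df", "p"]
            )
        baselines = pd.concat(
            [choice_analysis.session_baselines(s) for s in sessions], ignore_index=True
        )
        base_cmp = choice_analysis.baseline_fr_comparison(
            baselines["baseline_pre_hz"], baselines["baseline_post_hz"]
        )

        stage = "group"
        records = neurons.merge(
            behavior[["session_id", "cue", "perceptual_shift_deg"]],
            on=["session_id", "cue"],
        )
        group_rows = []
        for cue, grp in records.groupby("cue", sort=True):
            try:
                corr = group_stats.neuronal_perceptual_correlation(grp)
            except ValueError as e:
                corr = {"r": np.nan, "p": np.nan, "n": 0}
                log.warning("correlation unavailable for cue %s: %s", cue, e)
            row = {"area": cfg["area"], "cue": cue, **corr}
            try:
                row.update(group_stats.mixed_model_comparison(grp))
            except ValueError:
                pass
            group_rows.append(row)
        group = pd.DataFrame(group_rows)

        tables = {
            "behavior_shifts": behavior,
            "behavior_summary": summary,
            "neuron_shifts": neurons,
            "partials": partials,
            "partials_tests": partial_tests,
            "baselines": baselines,
            "group_stats": group,
        }
        files = session_io.write_results(tables, out_dir)
        files["baseline_comparison"] = out_dir / "baseline_comparison.json"
        files["baseline_comparison"].write_text(json.dumps(base_cmp, indent=1))
    except Exception:
        log.exception("stage %r failed; partial outputs kept in %s", stage, out_dir)
        raise

    manifest = {
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "seed": int(seed),
        "package_version": _version(),
        "outputs": {
            name: {
                "path": str(p),
                "sha256": hashlib.sha256(Path(p).read_bytes()).hexdigest(),
            }
            for name, p in files.items()
        },
        "n_neurons_screened": n_pass,
        "elapsed_s": round(time.time() - t0, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("recalib")
    except PackageNotFoundError:
        return "0.0.dev"
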