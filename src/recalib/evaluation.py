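"""Validation experiments: parameter recovery and calibration of every stage.

Each function simulates data under the generative study conditions, runs the
corresponding analysis exactly as the pipeline would, and returns summary
metrics.  The experiments double as the package's acceptance checks: ROC
oracle equivalence, psychometric and neurometric parameter recovery, the
behavioral sign pattern of cue-conflict recalibration, the per-area
neuronal-perceptual correlation signatures, the post-recalibration
choice-signal reduction, screening calibration on untuned neurons, and the
within-stimulus time course of neuronal recalibration.

Problem sizes default to what one desk-scale replication needs for stable
statistics (e.g. 200 behavioral sessions, 40 sessions per area, 1000 untuned
neurons); all randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import group_stats, neurometrics as nm, psychometrics as psy
from .choice_analysis import partial_correlations
from .synthetic_data import (
    BehaviorProfile,
    NeuronProfile,
    ParadigmConfig,
    make_area_population,
    sample_session_behavior,
    simulate_session,
)

__all__ = [
    "roc_oracle_check",
    "psychometric_recovery",
    "neurometric_shift_recovery",
    "behavioral_sign_pattern",
    "area_correlation_signatures",
    "choice_signal_reduction",
    "screening_calibration",
    "time_course_profile",
]


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# --------------------------------------------------------------------------- #
# 1. ROC sweep vs closed-form count oracle
# --------------------------------------------------------------------------- #


def roc_oracle_check(seed: int = 0, n_instances: int = 1000) -> dict:
    """Compare the criterion-sweep AUC with the count oracle on random z sets.

    Instances span n in [5, 200] with arbitrary location/scale, including
    heavily tied (rounded) and reference-tied (exact zeros) cases.  The
    oracle is ``(#{z > 0} + 0.5 * #{z = 0}) / n``.
    """
    rng = np.random.default_rng(seed)
    errs = np.empty(n_instances)
    for i in range(n_instances):
        n = int(rng.integers(5, 201))
        z = rng.normal(rng.uniform(-1, 1), rng.uniform(0.3, 2.0), size=n)
        if rng.random() < 0.3:
            z = np.round(z, 1)  # heavy ties
        if rng.random() < 0.3:
            z[rng.integers(0, n, size=max(1, n // 10))] = 0.0  # reference ties
        sweep = nm.auc_vs_reference(z)
        oracle = ((z > 0).sum() + 0.5 * (z == 0).sum()) / n
        errs[i] = abs(sweep - oracle)
    return {"max_abs_err": float(errs.max()), "mean_abs_err": float(errs.mean()), "n": n_instances}


# --------------------------------------------------------------------------- #
# 2. psychometric recovery
# --------------------------------------------------------------------------- #


def psychometric_recovery(
    seed: int = 0,
    n_sessions: int = 200,
    reps: int = 20,
    mu_deg: float = 1.5,
    sigma_deg: float = 4.0,
    shift_deg: float = 1.5,
) -> dict:
    """Recover a known observer (mu, sigma) and a generative PSE step.

    Each session has ``reps`` repetitions of the ten standard headings per
    cue and block; the generative observer has no lapse and the fits pin the
    lapse at zero to match.  Reports the mean bias of the fitted pre-block
    PSE and the mean recovered post-pre shift (vestibular cue).
    """
    mus, shifts = [], []
    for rng in _spawn(seed, n_sessions):
        beh = BehaviorProfile.from_shifts(
            pse_pre=mu_deg, shift={"vestibular": shift_deg, "visual": shift_deg},
            sigma=sigma_deg, lapse=0.0,
        )
        cfg = ParadigmConfig(reps_pre=reps, reps_post_single=reps)
        sess = simulate_session(cfg, beh, rng=rng)
        t = sess.trials
        fits = {}
        for block in ("pre", "post"):
            sel = (t["block"] == block) & (t["modality"] == "vestibular")
            fits[block] = psy.fit_psychometric(
                t.loc[sel, "heading_deg"], t.loc[sel, "choice"], lapse="zero"
            )
        mus.append(fits["pre"].pse_deg)
        shifts.append(psy.pse_shift(fits["pre"], fits["post"]))
    mus, shifts = np.asarray(mus), np.asarray(shifts)
    return {
        "mu_bias_deg": float(np.nanmean(mus) - mu_deg),
        "shift_mean_deg": float(np.nanmean(shifts)),
        "shift_err_deg": float(np.nanmean(shifts) - shift_deg),
        "n": n_sessions,
    }


# --------------------------------------------------------------------------- #
# 3. neurometric shift recovery
# --------------------------------------------------------------------------- #


def neurometric_shift_recovery(
    seed: int = 0,
    n_neurons: int = 100,
    delta_deg: float = 3.0,
    reps: int = 10,
    n_boot: int = 100,
) -> dict:
    """Recover an injected tuning-curve shift from reference-ROC neurometrics.

    ``n_neurons`` default-profile Poisson neurons (steep linear tuning) get a
    post-block tuning shift of +-``delta_deg``; behavior is unshifted.
    Reports the mean recovered neuronal shift per sign over screened neurons.
    """
    rngs = _spawn(seed, 2 * n_neurons)
    out = {"n": n_neurons}
    for sign in (+1.0, -1.0):
        shifts = []
        for i in range(n_neurons):
            rng = rngs[i if sign > 0 else n_neurons + i]
            beh = BehaviorProfile.from_shifts(shift=0.0, lapse=0.0)
            prof = NeuronProfile(
                tuning_shift_deg={
                    "vestibular": {"pre": 0.0, "post": sign * delta_deg},
                    "visual": {"pre": 0.0, "post": 0.0},
                }
            )
            cfg = ParadigmConfig(reps_pre=reps, reps_post_single=reps)
            sess = simulate_session(cfg, beh, [prof], rng=rng)
            rec = nm.analyze_session_neuron(sess, "n000", "vestibular", n_boot=n_boot, rng=rng)
            if rec["passed_screen"]:
                shifts.append(rec["neuronal_shift_deg"])
        key = "pos" if sign > 0 else "neg"
        out[f"mean_shift_{key}_deg"] = float(np.mean(shifts))
        out[f"err_{key}_deg"] = float(np.mean(shifts) - sign * delta_deg)
        out[f"n_screened_{key}"] = len(shifts)
    return out


# --------------------------------------------------------------------------- #
# 4. behavioral sign pattern under cue conflict
# --------------------------------------------------------------------------- #


def behavioral_sign_pattern(seed: int = 0, n_sessions: int = 50) -> dict:
    """Mean perceptual shifts per cue under Delta+ and Delta- conditions.

    Sessions are simulated at the study's generative conditions (vestibular
    shift larger than and opposite to visual); per (cue, Delta sign) the mean
    shift and the paired post-vs-pre t-test come from the population summary.
    """
    rows = []
    rngs = _spawn(seed, 2 * n_sessions)
    for j, dsign in enumerate(("+", "-")):
        for i in range(n_sessions):
            rng = rngs[j * n_sessions + i]
            beh = sample_session_behavior(dsign, rng)
            cfg = ParadigmConfig(delta_max_deg=10.0 if dsign == "+" else -10.0)
            sess = simulate_session(cfg, beh, rng=rng, session_id=f"s{j}_{i:03d}")
            rows.append(psy.session_behavior_shifts(sess))
    shifts = pd.concat(rows, ignore_index=True)
    summary = psy.behavioral_summary(shifts)
    out = {"n_sessions_per_sign": n_sessions}
    for _, r in summary.iterrows():
        if r["delta_sign"] in ("+", "-"):
            tag = f"{'vest' if r['cue'] == 'vestibular' else 'vis'}_{'pos' if r['delta_sign'] == '+' else 'neg'}"
            out[f"mean_{tag}_deg"] = r["mean_shift_deg"]
            out[f"p_{tag}"] = r["p"]
    pooled = summary[summary["group"].isin(["vestibular/pooled", "visual/pooled"])]
    for _, r in pooled.iterrows():
        out[f"pooled_{'vest' if r['cue'] == 'vestibular' else 'vis'}_deg"] = r["mean_shift_deg"]
    return out


# --------------------------------------------------------------------------- #
# 5. per-area correlation signatures
# --------------------------------------------------------------------------- #


def _simulate_area_batch(
    area: str,
    n_sessions: int,
    seed: int,
    n_boot: int = 100,
    neurons_per_session: int = 2,
    lapse_fit: str = "zero",
):
    """Simulate a mixed Delta+/Delta- session batch and analyze it end to end."""
    beh_rows, neu_rows = [], []
    for i, rng in enumerate(_spawn(seed, n_sessions)):
        dsign = "+" if i % 2 == 0 else "-"
        beh = sample_session_behavior(dsign, rng)
        neurons = make_area_population(area, neurons_per_session, beh, rng)
        cfg = ParadigmConfig(delta_max_deg=10.0 if dsign == "+" else -10.0)
        sess = simulate_session(
            cfg, beh, neurons, rng=rng, session_id=f"s{i:03d}",
            monkey_id="D" if i % 4 < 2 else "K", area=area,
        )
        beh_rows.append(psy.session_behavior_shifts(sess, lapse=lapse_fit))
        neu_rows.append(nm.analyze_session_neurons(sess, n_boot=n_boot, rng=rng))
    behavior = pd.concat(beh_rows, ignore_index=True)
    neurons = pd.concat(neu_rows, ignore_index=True)
    records = neurons.merge(
        behavior[["session_id", "cue", "perceptual_shift_deg"]], on=["session_id", "cue"]
    )
    return records


def area_correlation_signatures(
    seed: int = 0, n_sessions: int = 40, n_boot: int = 100
) -> dict:
    """Neuronal-vs-perceptual shift correlations for the three area profiles.

    MSTd-like neurons track each cue's own perceptual shift (both r > 0);
    PIVC-like neurons track the vestibular shift and are essentially blind to
    the visual cue (most fail the tuning screen); VIP-like neurons track the
    vestibular shift for *both* cues, so the visual-cue correlation is
    negative.
    """
    out: dict = {"n_sessions": n_sessions}
    for k, area in enumerate(("MSTd-like", "PIVC-like", "VIP-like")):
        records = _simulate_area_batch(area, n_sessions, seed + 7919 * k, n_boot=n_boot)
        tag = area.split("-")[0].lower()
        for cue in ("vestibular", "visual"):
            sub = records[records["cue"] == cue]
            ctag = "vest" if cue == "vestibular" else "vis"
            if area == "PIVC-like" and cue == "visual":
                fail = 1.0 - sub["passed_screen"].mean()
                out["pivc_vis_screen_fail_frac"] = float(fail)
                continue
            corr = group_stats.neuronal_perceptual_correlation(sub)
            out[f"r_{tag}_{ctag}"] = corr["r"]
            out[f"p_{tag}_{ctag}"] = corr["p"]
            out[f"n_{tag}_{ctag}"] = corr["n"]
    return out


# --------------------------------------------------------------------------- #
# 6. choice-signal reduction (VIP-like)
# --------------------------------------------------------------------------- #


def choice_signal_reduction(
    seed: int = 0, n_replicates: int = 100, n_neurons: int = 50
) -> dict:
    """Power/calibration of the paired pre/post test on squared partials.

    Each replicate simulates a VIP-like population (post-block choice gain
    halved by construction) in one session and runs paired t-tests across
    neurons on R_c^2 and R_h^2 (vestibular cue).  Reports the fraction of
    replicates detecting the R_c^2 decrease and the KS uniformity p-value of
    the R_h^2 test's p-values (heading signals are unchanged, so these
    should be null).
    """
    p_c, p_h, mean_dc = [], [], []
    for rng in _spawn(seed, n_replicates):
        rc2 = {"pre": [], "post": []}
        rh2 = {"pre": [], "post": []}
        # one neuron per session, as in the recordings
        for _ in range(n_neurons):
            beh = sample_session_behavior("+", rng)
            neurons = make_area_population("VIP-like", 1, beh, rng)
            sess = simulate_session(ParadigmConfig(), beh, neurons, rng=rng)
            t = sess.trials
            h = t["heading_deg"].to_numpy(dtype=float)
            ch = t["choice"].to_numpy()
            fr = nm.window_firing_rates(sess.spikes["n000"], sess.bin_edges_s, (0.0, 1.0))
            for b in ("pre", "post"):
                sel = (
                    (t["modality"] == "vestibular") & (t["block"] == b) & (t["choice"] != "none")
                ).to_numpy()
                res = partial_correlations(fr[sel], h[sel], ch[sel])
                rc2[b].append(res.r_c_sq)
                rh2[b].append(res.r_h_sq)
        t_c, pc = stats.ttest_rel(rc2["post"], rc2["pre"])
        _, ph = stats.ttest_rel(rh2["post"], rh2["pre"])
        # one-sided detection of a *decrease* in choice variance
        p_c.append(pc / 2 if t_c < 0 else 1 - pc / 2)
        p_h.append(ph)
        mean_dc.append(np.mean(rc2["post"]) - np.mean(rc2["pre"]))
    p_c, p_h = np.asarray(p_c), np.asarray(p_h)
    ks = stats.kstest(p_h, "uniform")
    return {
        "detect_frac_rc2": float((p_c < 0.05).mean()),
        "mean_rc2_change": float(np.mean(mean_dc)),
        "ks_p_rh2": float(ks.pvalue),
        "n_replicates": n_replicates,
        "n_neurons": n_neurons,
    }


# --------------------------------------------------------------------------- #
# 7. screening calibration on untuned neurons
# --------------------------------------------------------------------------- #


def screening_calibration(
    seed: int = 0, n_neurons: int = 1000, n_boot: int = 100, n_sessions: int = 10
) -> dict:
    """False-positive rate of the tuning screen and exclusion power of the
    bootstrap-SD screen for completely untuned (flat Poisson) neurons."""
    per_sess = n_neurons // n_sessions
    tuned_p = []
    excluded = 0
    for rng in _spawn(seed, n_sessions):
        beh = sample_session_behavior("+", rng)
        profs = [
            NeuronProfile(slope_hz_per_deg=0.0, choice_gain_hz=0.0) for _ in range(per_sess)
        ]
        sess = simulate_session(ParadigmConfig(), beh, profs, rng=rng)
        t = sess.trials
        h = t["heading_deg"].to_numpy(dtype=float)
        masks = {
            b: ((t["modality"] == "vestibular") & (t["block"] == b)).to_numpy()
            for b in ("pre", "post")
        }
        for nid in sess.spikes:
            fr = nm.trial_firing_rates(sess.spikes[nid], sess.bin_edges_s, t["block"])
            vals = fr.baseline_subtracted_hz
            tun_pre = nm.tuning_regression(vals[masks["pre"]], h[masks["pre"]])
            tuned_p.append(tun_pre.p_value)
            ref = nm.reference_stats(fr.fr_hz[masks["pre"]])
            sd_pre = nm.bootstrap_pse_sd(
                fr.fr_hz[masks["pre"]], h[masks["pre"]], ref, tun_pre.preferred_side,
                n_boot=n_boot, rng=rng,
            )
            if sd_pre >= nm.BOOTSTRAP_SD_SCREEN_DEG:
                excluded += 1
                continue
            sd_post = nm.bootstrap_pse_sd(
                fr.fr_hz[masks["post"]], h[masks["post"]], ref, tun_pre.preferred_side,
                n_boot=n_boot, rng=rng,
            )
            if sd_post >= nm.BOOTSTRAP_SD_SCREEN_DEG:
                excluded += 1
    n = len(tuned_p)
    return {
        "tuning_false_positive_frac": float((np.asarray(tuned_p) < 0.05).mean()),
        "bootstrap_excluded_frac": float(excluded / n),
        "n": n,
    }


# --------------------------------------------------------------------------- #
# 8. within-stimulus time course
# --------------------------------------------------------------------------- #


def time_course_profile(
    seed: int = 0, n_sessions: int = 25, reps: int = 15
) -> dict:
    """Sliding-window neuronal-perceptual correlations for velocity-locked vs
    sustained populations.

    For each temporal mode, sessions carry one well-tuned vestibular neuron
    whose tuning shift tracks the session's perceptual shift; the per-window
    Pearson correlation across sessions traces where in the stimulus the
    recalibrated signal lives.  Velocity-locked responses should peak near
    the velocity peak (0.5 s) and vanish late; sustained responses should
    stay correlated past stimulus offset (> 1.0 s).
    """
    out: dict = {"n_sessions": n_sessions, "window_centers_s": list(nm.SLIDING_WINDOW_CENTERS_S)}
    for k, mode in enumerate(("velocity", "sustained")):
        percept, windows = [], []
        for i, rng in enumerate(_spawn(seed + 104729 * k, n_sessions)):
            dsign = "+" if i % 2 == 0 else "-"
            beh = sample_session_behavior(dsign, rng)
            shift = beh.perceptual_shift("vestibular") + float(rng.normal(0.0, 0.4))
            prof = NeuronProfile(
                slope_hz_per_deg=2.5,
                tuning_shift_deg={
                    "vestibular": {"pre": 0.0, "post": shift},
                    "visual": {"pre": 0.0, "post": shift},
                },
                temporal_mode=mode,
            )
            cfg = ParadigmConfig(
                reps_pre=reps, reps_post_single=reps,
                delta_max_deg=10.0 if dsign == "+" else -10.0,
            )
            sess = simulate_session(cfg, beh, [prof], rng=rng, session_id=f"s{i:03d}")
            t = sess.trials
            fits = {}
            for block in ("pre", "post"):
                sel = (t["block"] == block) & (t["modality"] == "vestibular")
                fits[block] = psy.fit_psychometric(
                    t.loc[sel, "heading_deg"], t.loc[sel, "choice"], lapse="zero"
                )
            percept.append(psy.pse_shift(fits["pre"], fits["post"]))
            windows.append(nm.sliding_window_shifts(sess, "n000", "vestibular"))
        percept = np.asarray(percept)
        win = pd.concat(windows, ignore_index=True)
        rs, ps = [], []
        min_n = max(10, n_sessions // 3)  # a correlation over a handful of
        # converged fits is meaningless; windows without signal drop to r = 0
        for c in nm.SLIDING_WINDOW_CENTERS_S:
            y = win.loc[win["window_center_s"] == c, "shift_deg"].to_numpy()
            keep = np.isfinite(y) & np.isfinite(percept)
            if keep.sum() >= min_n and np.ptp(y[keep]) > 0:
                r, p = stats.pearsonr(percept[keep], y[keep])
            else:
                r, p = 0.0, 1.0
            rs.append(float(r))
            ps.append(float(p))
        tag = "velocity" if mode == "velocity" else "sustained"
        rs_arr = np.asarray(rs)
        out[f"r_by_window_{tag}"] = rs
        out[f"p_by_window_{tag}"] = ps
        out[f"peak_center_{tag}_s"] = float(nm.SLIDING_WINDOW_CENTERS_S[int(np.argmax(np.abs(rs_arr)))])
        late = [p for c, p in zip(nm.SLIDING_WINDOW_CENTERS_S, ps) if c > 1.0]
        late_r = [r for c, r in zip(nm.SLIDING_WINDOW_CENTERS_S, rs) if c > 1.0]
        out[f"late_min_p_{tag}"] = float(min(late))
        out[f"late_max_abs_r_{tag}"] = float(max(abs(r) for r in late_r))
    return out
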