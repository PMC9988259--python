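"""Heading/choice partial-correlation decomposition of trial-by-trial FRs.

For one (neuron, cue, block), firing rates over the stimulus window are
decomposed with Pearson partial correlations: R_h = corr(FR, heading | choice)
and R_c = corr(FR, choice | heading), choice coded -1 (left) / +1 (right).
The squared values quantify the unique variance explained by heading and by
choice; comparing them post vs pre recalibration (paired t-tests across
neurons) tests whether choice signals change with recalibration, the
dissociation characteristic of higher-level area VIP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PartialCorrResult",
    "partial_correlations",
    "choice_conditioned_tuning",
    "compare_pre_post_partials",
    "baseline_fr_comparison",
    "session_partial_correlations",
    "session_baselines",
]

CHOICE_CODE = {"left": -1.0, "right": 1.0}


@dataclass(frozen=True)
class PartialCorrResult:
    """Partial correlations of FR with heading (R_h) and choice (R_c)."""

    r_h: float
    r_c: float
    p_h: float
    p_c: float
    n_trials: int

    @property
    def r_h_sq(self) -> float:
        return self.r_h**2

    @property
    def r_c_sq(self) -> float:
        return self.r_c**2


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / den) if den > 0 else np.nan


def _partial_p(r: float, n: int) -> float:
    # t-transform with n - 3 df (one conditioning variable)
    df = n - 3
    if not np.isfinite(r) or df <= 0 or abs(r) >= 1.0:
        return np.nan if not np.isfinite(r) else 0.0 if abs(r) >= 1.0 else np.nan
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def partial_correlations(
    fr: np.ndarray, headings: np.ndarray, choices: np.ndarray
) -> PartialCorrResult:
    """Pearson partial correlations of FR with heading given choice and vice versa.

    ``choices`` may be 'left'/'right' labels or numeric codes; positive values
    of R_h (R_c) mean larger FRs for rightward headings (choices).
    """
    fr = np.asarray(fr, float)
    h = np.asarray(headings, float)
    c = np.asarray(choices)
    if c.dtype.kind in "UO":
        c = np.array([CHOICE_CODE[str(x)] for x in c])
    c = c.astype(float)
    n = fr.size
    if n < 10:
        raise ValueError("need >=10 trials for partial correlations")
    if np.unique(c).size < 2:
        raise ValueError("both choices must be represented")
    r_fh = _pearson(fr, h)
    r_fc = _pearson(fr, c)
    r_hc = _pearson(h, c)
    den_h = np.sqrt((1 - r_fc**2) * (1 - r_hc**2))
    den_c = np.sqrt((1 - r_fh**2) * (1 - r_hc**2))
    r_h = (r_fh - r_fc * r_hc) / den_h if den_h > 0 else np.nan
    r_c = (r_fc - r_fh * r_hc) / den_c if den_c > 0 else np.nan
    return PartialCorrResult(
        r_h=float(r_h),
        r_c=float(r_c),
        p_h=_partial_p(r_h, n),
        p_c=_partial_p(r_c, n),
        n_trials=int(n),
    )


def choice_conditioned_tuning(
    fr: np.ndarray,
    headings: np.ndarray,
    choices: np.ndarray,
    min_count: int = 3,
) -> pd.DataFrame:
    """Mean FR per (heading, choice) plus the overall (unconditioned) curve.

    Cells with fewer than ``min_count`` trials are masked (NaN mean, count
    kept).  The overall curve is the count-weighted mean of the conditioned
    cells, i.e. it equals the plain per-heading mean exactly.
    """
    fr = np.asarray(fr, float)
    h = np.asarray(headings, float)
    c = np.asarray(choices).astype(str)
    df = pd.DataFrame({"heading_deg": h, "choice": c, "fr_hz": fr})
    cells = (
        df.groupby(["heading_deg", "choice"])["fr_hz"]
        .agg(mean_fr_hz="mean", n="count")
        .reset_index()
    )
    cells["masked"] = cells["n"] < min_count
    cells.loc[cells["masked"], "mean_fr_hz"] = np.nan
    overall = (
        df.groupby("heading_deg")["fr_hz"].agg(mean_fr_hz="mean", n="count").reset_index()
    )
    overall["choice"] = "all"
    overall["masked"] = False
    return pd.concat([cells, overall[cells.columns]], ignore_index=True)


def compare_pre_post_partials(partials: pd.DataFrame) -> pd.DataFrame:
    """Paired pre/post tests of squared partial correlations across neurons.

    ``partials`` needs columns neuron_id, cue, block, r_h, r_c.  Returns one
    row per (cue, quantity in {r_h_sq, r_c_sq}) with the two-sided paired
    t-test of post vs pre and the mean difference.
    """
    partials = partials.copy()
    if "session_id" in partials.columns:
        partials["neuron_id"] = (
            partials["session_id"].astype(str) + "/" + partials["neuron_id"].astype(str)
        )
    rows = []
    for cue, grp in partials.groupby("cue", sort=True):
        wide = grp.pivot(index="neuron_id", columns="block", values=["r_h", "r_c"]).dropna()
        if len(wide) < 5:
            raise ValueError(f"cue {cue!r}: need >=5 neurons with both blocks")
        for quantity, col in (("r_h_sq", "r_h"), ("r_c_sq", "r_c")):
            pre = wide[(col, "pre")].to_numpy() ** 2
            post = wide[(col, "post")].to_numpy() ** 2
            t, p = stats.ttest_rel(post, pre)
            rows.append(
                {
                    "cue": cue,
                    "quantity": quantity,
                    "n": len(wide),
                    "mean_diff": float((post - pre).mean()),
                    "t": float(t),
                    "df": len(wide) - 1,
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)


def session_partial_correlations(session, baseline_subtracted: bool = False) -> pd.DataFrame:
    """Partial correlations for every (neuron, cue, block) of one session.

    FRs are taken over the entire stimulus duration, raw by default.  Only
    single-cue trials with a choice enter.  Neurons/blocks where one choice is
    absent are skipped.
    """
    from .neurometrics import trial_firing_rates

    trials = session.trials
    rows = []
    for nid in sorted(session.spikes):
        fr = trial_firing_rates(session.spikes[nid], session.bin_edges_s, trials["block"])
        values = fr.baseline_subtracted_hz if baseline_subtracted else fr.fr_hz
        for cue in ("vestibular", "visual"):
            for block in ("pre", "post"):
                sel = (
                    (trials["modality"] == cue)
                    & (trials["block"] == block)
                    & (trials["choice"] != "none")
                ).to_numpy()
                try:
                    res = partial_correlations(
                        values[sel],
                        trials.loc[sel, "heading_deg"],
                        trials.loc[sel, "choice"],
                    )
                except ValueError:
                    continue
                rows.append(
                    {
                        "session_id": session.session_id,
                        "neuron_id": nid,
                        "cue": cue,
                        "block": block,
                        "r_h": res.r_h,
                        "r_c": res.r_c,
                        "p_h": res.p_h,
                        "p_c": res.p_c,
                        "r_h_sq": res.r_h_sq,
                        "r_c_sq": res.r_c_sq,
                        "n_trials": res.n_trials,
                    }
                )
    return pd.DataFrame(rows)


def session_baselines(session) -> pd.DataFrame:
    """Per-neuron baseline FRs (1 s before onset) in the pre and post blocks."""
    from .neurometrics import trial_firing_rates

    rows = []
    for nid in sorted(session.spikes):
        fr = trial_firing_rates(session.spikes[nid], session.bin_edges_s, session.trials["block"])
        rows.append(
            {
                "session_id": session.session_id,
                "neuron_id": nid,
                "baseline_pre_hz": fr.baseline_hz.get("pre", np.nan),
                "baseline_post_hz": fr.baseline_hz.get("post", np.nan),
            }
        )
    return pd.DataFrame(rows)


def baseline_fr_comparison(baseline_pre: np.ndarray, baseline_post: np.ndarray) -> dict:
    """Paired t-test of post vs pre baseline FRs across neurons, with 95% CI."""
    pre = np.asarray(baseline_pre, float)
    post = np.asarray(baseline_post, float)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("need >=2 paired baselines")
    diff = post - pre
    t, p = stats.ttest_rel(post, pre)
    sem = diff.std(ddof=1) / np.sqrt(diff.size)
    half = stats.t.ppf(0.975, diff.size - 1) * sem
    return {
        "n": int(pre.size),
        "mean_diff_hz": float(diff.mean()),
        "ci95_hz": (float(diff.mean() - half), float(diff.mean() + half)),
        "t": float(t),
        "p": float(p),
    }
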