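"""Behavioral psychometric fits and perceptual PSE shifts.

The proportion of rightward choices as a function of signed heading is fit
with a lapse-contaminated cumulative Gaussian,

    P(right | h) = lambda/2 + (1 - lambda) * Phi((h - mu) / sigma),

by binomial maximum likelihood.  ``mu`` is the PSE (point of subjective
equality, the heading perceived as straight ahead) and ``sigma`` the
psychophysical threshold.  Recalibration is quantified per session and cue as

    PSE_shift = PSE_post - PSE_pre,

so a rightward shift of the psychometric curve (positive value) corresponds
to a leftward perceptual shift.  Fits are computed either with the lapse free
on [0, 0.1] or pinned at zero; shifts must compare like with like.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr

from .group_stats import pool_signed_shifts
from .synthetic_data import SessionData

__all__ = [
    "PsychometricFit",
    "fit_psychometric",
    "pse_shift",
    "session_behavior_shifts",
    "behavioral_summary",
]

_LAPSE_MAX = 0.1


@dataclass(frozen=True)
class PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit of one cue x block."""

    pse_deg: float
    threshold_deg: float
    lapse: float
    n_trials: int
    headings_deg: np.ndarray
    n_per_heading: np.ndarray
    p_right: np.ndarray
    log_likelihood: float
    converged: bool


def _nll(params: np.ndarray, h: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    mu, log_sigma, lam = params
    sigma = np.exp(log_sigma)
    p = lam / 2.0 + (1.0 - lam) * ndtr((h - mu) / sigma)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def fit_psychometric(
    headings: Sequence[float],
    choices: Sequence[str],
    lapse: Literal["free", "zero"] = "free",
) -> PsychometricFit:
    """Fit P(rightward | heading) for one cue and block.

    Parameters
    ----------
    headings, choices:
        Per-trial signed headings (degrees) and ``'left'``/``'right'`` labels.
    lapse:
        ``'free'`` estimates a symmetric lapse on [0, 0.1]; ``'zero'`` pins it.

    The optimizer restarts from five deterministic (mu, sigma)
    initializations; ties are broken by log-likelihood, then smaller sigma.
    """
    h_all = np.asarray(headings, dtype=float)
    c_all = np.asarray(choices)
    if h_all.shape != c_all.shape:
        raise ValueError("headings and choices must align")
    right = c_all == "right"
    hs, inv = np.unique(h_all, return_inverse=True)
    n = np.bincount(inv)
    k = np.bincount(inv, weights=right.astype(float))
    p_obs = k / n

    ok = hs.size >= 2 and 0 < right.sum() < right.size
    if not ok:
        return PsychometricFit(
            np.nan, np.nan, 0.0, int(h_all.size), hs, n, p_obs, np.nan, False
        )

    span = max(hs.max() - hs.min(), 1.0)
    mu0 = float(np.interp(0.5, p_obs[np.argsort(p_obs)], hs[np.argsort(p_obs)]))
    inits = [
        (mu0, span / 8.0),
        (0.0, span / 8.0),
        (0.0, span / 2.0),
        (-span / 4.0, span / 4.0),
        (span / 4.0, span / 4.0),
    ]
    lam_bounds = (0.0, 0.0) if lapse == "zero" else (0.0, _LAPSE_MAX)
    best = None
    for mu_i, sig_i in inits:
        res = optimize.minimize(
            _nll,
            x0=np.array([mu_i, np.log(sig_i), min(0.02, lam_bounds[1])]),
            args=(hs, k, n),
            method="L-BFGS-B",
            bounds=[(-90.0, 90.0), (np.log(1e-2), np.log(500.0)), lam_bounds],
        )
        cand = (res.fun, np.exp(res.x[1]), res)
        if best is None or cand[:2] < best[:2]:
            best = cand
    res = best[2]
    mu, sigma, lam = res.x[0], float(np.exp(res.x[1])), res.x[2]
    converged = bool(res.success and np.isfinite(mu) and abs(mu) < 90.0 and sigma < 400.0)
    return PsychometricFit(
        pse_deg=float(mu),
        threshold_deg=sigma,
        lapse=float(lam),
        n_trials=int(h_all.size),
        headings_deg=hs,
        n_per_heading=n,
        p_right=p_obs,
        log_likelihood=-float(res.fun),
        converged=converged,
    )


def pse_shift(fit_pre: PsychometricFit, fit_post: PsychometricFit) -> float:
    """Perceptual recalibration: post-block PSE minus pre-block PSE (degrees)."""
    if not (fit_pre.converged and fit_post.converged):
        return float("nan")
    return fit_post.pse_deg - fit_pre.pse_deg


def session_behavior_shifts(
    session: SessionData, lapse: Literal["free", "zero"] = "free"
) -> pd.DataFrame:
    """Per-cue psychometric fits and PSE shifts for one session.

    Only single-cue trials enter the per-cue fits; combined post-block trials
    (which exist to maintain recalibration) are excluded.
    """
    rows = []
    t = session.trials
    for cue in ("vestibular", "visual"):
        fits = {}
        for block in ("pre", "post"):
            sel = (t["block"] == block) & (t["modality"] == cue)
            fits[block] = fit_psychometric(
                t.loc[sel, "heading_deg"], t.loc[sel, "choice"], lapse=lapse
            )
        rows.append(
            {
                "session_id": session.session_id,
                "monkey_id": session.monkey_id,
                "cue": cue,
                "delta_sign": session.config.delta_sign,
                "pse_pre_deg": fits["pre"].pse_deg,
                "pse_post_deg": fits["post"].pse_deg,
                "sigma_pre_deg": fits["pre"].threshold_deg,
                "sigma_post_deg": fits["post"].threshold_deg,
                "perceptual_shift_deg": pse_shift(fits["pre"], fits["post"]),
                "converged": fits["pre"].converged and fits["post"].converged,
            }
        )
    return pd.DataFrame(rows)


def behavioral_summary(shifts: pd.DataFrame) -> pd.DataFrame:
    """Population summary of perceptual shifts per (cue, Delta sign).

    For each group: mean shift, SEM, and the paired t-test of post- vs
    pre-recalibration PSEs across sessions.  Appends one row per cue with the
    sign-flip pooled magnitudes (conflict-reducing direction positive) and, as
    a ``vest_vs_vis`` row, the paired comparison of pooled vestibular vs
    visual magnitudes across sessions present for both cues.
    """
    req = {"cue", "delta_sign", "pse_pre_deg", "pse_post_deg", "perceptual_shift_deg"}
    if not req <= set(shifts.columns):
        raise ValueError(f"missing columns: {sorted(req - set(shifts.columns))}")
    rows = []
    for (cue, dsign), grp in shifts.groupby(["cue", "delta_sign"], sort=True):
        n = len(grp)
        if n < 2:
            raise ValueError(f"group ({cue}, {dsign}) needs >=2 sessions")
        vals = grp["perceptual_shift_deg"].to_numpy()
        degenerate = np.allclose(vals, vals[0])
        if degenerate:
            t_stat, p = np.nan, np.nan
        else:
            t_stat, p = stats.ttest_rel(grp["pse_post_deg"], grp["pse_pre_deg"])
        rows.append(
            {
                "group": f"{cue}/delta{dsign}",
                "cue": cue,
                "delta_sign": dsign,
                "n": n,
                "mean_shift_deg": float(vals.mean()),
                "sem_shift_deg": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                "t": float(t_stat) if np.isfinite(t_stat) else np.nan,
                "p": float(p) if np.isfinite(p) else np.nan,
                "flag": "degenerate" if degenerate else "",
            }
        )
    out = pd.DataFrame(rows)

    pooled = {}
    for cue in shifts["cue"].unique():
        pooled[cue] = pool_signed_shifts(shifts, cue, value_col="perceptual_shift_deg")
        rows_p = pooled[cue]
        out.loc[len(out)] = {
            "group": f"{cue}/pooled",
            "cue": cue,
            "delta_sign": "both",
            "n": len(rows_p),
            "mean_shift_deg": float(rows_p["pooled_shift_deg"].mean()),
            "sem_shift_deg": float(rows_p["pooled_shift_deg"].std(ddof=1) / np.sqrt(len(rows_p))),
            "t": np.nan,
            "p": np.nan,
            "flag": "",
        }
    if set(pooled) >= {"vestibular", "visual"}:
        merged = pooled["vestibular"].merge(
            pooled["visual"], on="session_id", suffixes=("_vest", "_vis")
        )
        if len(merged) >= 2:
            t_stat, p = stats.ttest_rel(
                merged["pooled_shift_deg_vest"], merged["pooled_shift_deg_vis"]
            )
            out.loc[len(out)] = {
                "group": "vest_vs_vis",
                "cue": "both",
                "delta_sign": "both",
                "n": len(merged),
                "mean_shift_deg": float(
                    (merged["pooled_shift_deg_vest"] - merged["pooled_shift_deg_vis"]).mean()
                ),
                "sem_shift_deg": np.nan,
                "t": float(t_stat),
                "p": float(p),
                "flag": "",
            }
    return out
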