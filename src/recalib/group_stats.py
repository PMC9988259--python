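"""Population-level statistics over per-session shift records.

A shift record pairs, for one session and cue, the perceptual PSE shift with
the neuronal (neurometric) PSE shift of a simultaneously recorded neuron,
annotated with area, monkey and the sign of the cue discrepancy Delta.

Sign-flip pooling maps shifts onto a common "conflict-reducing direction
positive" axis: under Delta+ the vestibular cue is offset rightward, so
conflict-reducing vestibular shifts are positive and visual ones negative;
under Delta- both flip.  Pooling therefore flips vestibular shifts from
Delta- sessions and visual shifts from Delta+ sessions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "pool_signed_shifts",
    "neuronal_perceptual_correlation",
    "mixed_model_comparison",
]


def pool_signed_shifts(
    records: pd.DataFrame, cue: str, value_col: str = "perceptual_shift_deg"
) -> pd.DataFrame:
    """Pool one cue's shifts across Delta signs onto the conflict-reducing axis.

    Returns a frame with ``session_id`` and ``pooled_shift_deg`` where positive
    means recalibration in the direction that reduces the cue conflict.
    """
    if cue not in ("vestibular", "visual"):
        raise ValueError(f"unknown cue {cue!r}")
    sub = records[records["cue"] == cue]
    flip_sign = "-" if cue == "vestibular" else "+"
    sign = np.where(sub["delta_sign"].to_numpy() == flip_sign, -1.0, 1.0)
    out = pd.DataFrame(
        {
            "session_id": sub.get("session_id", pd.RangeIndex(len(sub))),
            "pooled_shift_deg": sign * sub[value_col].to_numpy(dtype=float),
        }
    )
    return out.reset_index(drop=True)


def neuronal_perceptual_correlation(records: pd.DataFrame) -> dict:
    """Pearson correlation between neuronal and perceptual PSE shifts.

    Raw signed shifts are used (both Delta signs in one cloud, pooled across
    monkeys), as in the per-area scatter analyses.  Only records flagged as
    having passed the neuron screen enter.
    """
    sub = records
    if "passed_screen" in records.columns:
        sub = records[records["passed_screen"].astype(bool)]
    x = sub["perceptual_shift_deg"].to_numpy(dtype=float)
    y = sub["neuronal_shift_deg"].to_numpy(dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need >=3 screened records for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in shifts")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(x.size)}


def mixed_model_comparison(records: pd.DataFrame) -> dict:
    """Pooled regression vs linear mixed model of neuronal on perceptual shifts.

    The pooled model ignores monkey identity; the LMM allows by-monkey random
    intercepts and slopes.  Both are refit by maximum likelihood for the
    AIC/BIC comparison (REML likelihoods are not comparable across models).
    The LMM is declared preferred only if it wins on both AIC and BIC.  A
    singular random-slope fit falls back to random intercepts only (flagged).
    """
    sub = records
    if "passed_screen" in records.columns:
        sub = records[records["passed_screen"].astype(bool)]
    sub = sub.dropna(subset=["perceptual_shift_deg", "neuronal_shift_deg"])
    monkeys = sub["monkey_id"].unique()
    if len(monkeys) < 2 or sub.groupby("monkey_id").size().min() < 3:
        raise ValueError("need >=2 monkeys with >=3 records each")
    df = sub.rename(
        columns={"perceptual_shift_deg": "x", "neuronal_shift_deg": "y"}
    )[["x", "y", "monkey_id"]].reset_index(drop=True)

    pooled = smf.ols("y ~ x", data=df).fit()
    flag = ""
    lmm = None
    import warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm("y ~ x", data=df, groups=df["monkey_id"], re_formula="~x")
        lmm = None
        for method in (None, "powell", "nm"):
            try:
                kw = {} if method is None else {"method": method, "maxiter": 2000}
                cand = model.fit(reml=False, **kw)
            except Exception:
                continue
            ok = cand.converged and np.all(np.isfinite(np.asarray(cand.params))) and np.all(
                np.isfinite(np.asarray(cand.cov_re))
            )
            if ok and (lmm is None or cand.aic < lmm.aic):
                lmm = cand
        if lmm is None:
            flag = "random_slope_singular"
            lmm = smf.mixedlm("y ~ x", data=df, groups=df["monkey_id"]).fit(reml=False)

        # REML for the reported fixed effect; the ML fit above feeds AIC/BIC
        try:
            reml_slope = float(
                smf.mixedlm(
                    "y ~ x", data=df, groups=df["monkey_id"],
                    re_formula=None if flag else "~x",
                ).fit(reml=True).params["x"]
            )
        except Exception:
            reml_slope = float(lmm.params["x"])

    # statsmodels MixedLM.aic uses ML loglike when fit with reml=False
    result = {
        "pooled_slope": float(pooled.params["x"]),
        "pooled_aic": float(pooled.aic),
        "pooled_bic": float(pooled.bic),
        "lmm_fixed_slope_reml": reml_slope,
        "lmm_fixed_slope": float(lmm.params["x"]),
        "lmm_aic": float(lmm.aic),
        "lmm_bic": float(lmm.bic),
        "n": int(len(df)),
        "n_monkeys": int(len(monkeys)),
        "flag": flag,
    }
    result["lmm_preferred"] = bool(
        result["lmm_aic"] < result["pooled_aic"] and result["lmm_bic"] < result["pooled_bic"]
    )
    return result
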