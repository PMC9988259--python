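"""Reference-anchored ROC neurometrics and neuronal PSE shifts.

Firing rates (FRs) are computed over the stimulus window (t = 0-1 s by
default); baseline FRs over the 1 s before stimulus onset, per block.  A
neuron counts as *tuned* to a cue when the linear regression of its FRs on
heading (over the narrow +-16 deg range) has a significant slope (p < 0.05);
the preferred side is the sign of the pre-recalibration slope.

Neurometric curves are anchored to a fixed reference: all FRs (pre and post
block alike) are z-scored with the *pre-recalibration* mean and SD of that
cue's FRs.  For each heading, a criterion sweeps the z-range in 100 equal
steps; plotting P(z > criterion) against whether z = 0 (the pre-recal mean)
exceeds the same criterion yields an ROC curve whose area is the probability
that an ideal observer discriminates that heading's responses from the
reference toward the preferred side.  Mapping areas to P(rightward) and
fitting a cumulative Gaussian over headings gives the neurometric PSE; its
bootstrap SD (trial resampling within heading) provides the <10 deg
reliability screen.  Neuronal shifts are post minus pre neurometric PSEs,
the same convention as perceptual shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._cumgauss import fit_cum_gauss_batch
from .synthetic_data import SessionData

__all__ = [
    "FiringRates",
    "TuningFit",
    "NeurometricFit",
    "ScreenResult",
    "trial_firing_rates",
    "window_firing_rates",
    "tuning_regression",
    "reference_stats",
    "auc_vs_reference",
    "build_neurometric",
    "bootstrap_pse_sd",
    "screen_neuron",
    "neuronal_shift",
    "sliding_window_shifts",
    "analyze_session_neuron",
    "analyze_session_neurons",
    "SLIDING_WINDOW_CENTERS_S",
]

STIMULUS_WINDOW_S = (0.0, 1.0)
BASELINE_WINDOW_S = (-1.0, 0.0)
BOOTSTRAP_SD_SCREEN_DEG = 10.0
TUNING_ALPHA = 0.05
#: Sliding-window analysis: 200 ms windows in 100 ms increments, centers
#: from 0.1 s to 1.2 s after stimulus onset (before the choice saccade).
SLIDING_WINDOW_CENTERS_S = tuple(np.round(0.1 * k, 1) for k in range(1, 13))


# --------------------------------------------------------------------------- #
# firing rates and tuning
# --------------------------------------------------------------------------- #


def _window_bins(bin_edges: np.ndarray, window: tuple[float, float]) -> slice:
    t0, t1 = window
    eps = 1e-9
    if t0 < bin_edges[0] - eps or t1 > bin_edges[-1] + eps or t1 <= t0:
        raise ValueError(f"window {window} outside time grid")
    i0 = int(np.argmin(np.abs(bin_edges - t0)))
    i1 = int(np.argmin(np.abs(bin_edges - t1)))
    if abs(bin_edges[i0] - t0) > eps or abs(bin_edges[i1] - t1) > eps:
        raise ValueError(f"window {window} not aligned to bin edges")
    return slice(i0, i1)


def window_firing_rates(
    spikes: np.ndarray, bin_edges: np.ndarray, window: tuple[float, float]
) -> np.ndarray:
    """Per-trial firing rate (spikes/s): counts in the window over its length."""
    sl = _window_bins(np.asarray(bin_edges, float), window)
    dur = bin_edges[sl.stop] - bin_edges[sl.start]
    return spikes[:, sl].sum(axis=1) / dur


@dataclass
class FiringRates:
    """Per-trial FRs over one window, with per-block baseline FRs."""

    fr_hz: np.ndarray
    blocks: np.ndarray
    window_s: tuple[float, float]
    baseline_hz: dict[str, float] = field(default_factory=dict)

    @property
    def baseline_subtracted_hz(self) -> np.ndarray:
        base = np.array([self.baseline_hz.get(b, 0.0) for b in self.blocks])
        return self.fr_hz - base


def trial_firing_rates(
    spikes: np.ndarray,
    bin_edges: np.ndarray,
    blocks: Sequence[str],
    window: tuple[float, float] = STIMULUS_WINDOW_S,
    baseline_window: tuple[float, float] = BASELINE_WINDOW_S,
) -> FiringRates:
    """Stimulus-window FRs for every trial plus per-block baseline FRs.

    The baseline for a block is the mean FR over ``baseline_window`` across
    all of that block's trials; baseline-subtracted values are available via
    :attr:`FiringRates.baseline_subtracted_hz`.
    """
    blocks = np.asarray(blocks)
    fr = window_firing_rates(spikes, bin_edges, window)
    base_fr = window_firing_rates(spikes, bin_edges, baseline_window)
    baseline = {str(b): float(base_fr[blocks == b].mean()) for b in np.unique(blocks)}
    return FiringRates(fr_hz=fr, blocks=blocks, window_s=tuple(window), baseline_hz=baseline)


@dataclass(frozen=True)
class TuningFit:
    """OLS regression of FR on heading over the narrow stimulus range."""

    slope: float
    intercept: float
    p_value: float
    preferred_side: str  # 'left' or 'right', from the slope sign

    @property
    def tuned(self) -> bool:
        return bool(self.p_value < TUNING_ALPHA)


def tuning_regression(fr: np.ndarray, headings: np.ndarray) -> TuningFit:
    """Linear heading tuning with a two-sided slope p-value."""
    fr = np.asarray(fr, float)
    headings = np.asarray(headings, float)
    if np.unique(headings).size < 3:
        raise ValueError("need >=3 distinct headings for a tuning regression")
    res = stats.linregress(headings, fr)
    side = "right" if res.slope >= 0 else "left"
    return TuningFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        preferred_side=side,
    )


# --------------------------------------------------------------------------- #
# reference-anchored ROC
# --------------------------------------------------------------------------- #


def reference_stats(fr_pre: np.ndarray) -> tuple[float, float]:
    """Pre-recalibration mean and SD of one cue's FRs, pooled across headings.

    These anchor the z-scoring of both blocks' FRs; pooling across headings is
    what makes z = 0 (the pre-recalibration mean) a meaningful reference.
    """
    fr_pre = np.asarray(fr_pre, float)
    return float(fr_pre.mean()), float(fr_pre.std(ddof=1))


def auc_vs_reference(zscores: np.ndarray, n_criteria: int = 100) -> float:
    """Area under the criterion-sweep ROC of z-scores against the reference.

    A criterion moves in ``n_criteria`` equal steps across the z range
    (extended to include the reference z = 0, which is always a criterion).
    Each criterion contributes the point (I(0 > c), P(z > c)); as the
    criterion passes *through* the reference both coordinates jump, so the
    path carries the two one-sided limit points (0, P(z > 0)) and
    (1, P(z >= 0)) there.  The trapezoid area of the path (with the
    conventional (0,0)/(1,1) anchors) is then independent of the grid
    resolution at the only abscissa transition, and equals the probability
    that an ideal observer calls the responses larger than the reference
    (ties split evenly).
    """
    z = np.asarray(zscores, float)
    if z.size == 0:
        raise ValueError("empty z-score input")
    lo = min(z.min(), 0.0)
    hi = max(z.max(), 0.0)
    crit = np.union1d(np.linspace(lo, hi, n_criteria), [0.0])[::-1]  # descending
    x_path = [0.0]
    y_path = [0.0]
    for c in crit:
        if c > 0.0:
            x_path.append(0.0)
            y_path.append(float((z > c).mean()))
        elif c == 0.0:
            x_path.append(0.0)
            y_path.append(float((z > 0.0).mean()))
            x_path.append(1.0)
            y_path.append(float((z >= 0.0).mean()))
        else:
            x_path.append(1.0)
            y_path.append(float((z > c).mean()))
    x_path.append(1.0)
    y_path.append(1.0)
    return float(np.trapezoid(y_path, x_path))


def _auc_batch(z: np.ndarray, n_criteria: int = 100) -> np.ndarray:
    """Vectorized fast path for :func:`auc_vs_reference` over rows of ``z``.

    The sweep path's abscissa changes only while the criterion passes the
    reference, where the path carries both one-sided limits, so the area
    collapses to ``P(z > 0) + P(z = 0) / 2`` per row.
    """
    z = np.atleast_2d(np.asarray(z, float))
    return (z > 0.0).mean(axis=1) + 0.5 * (z == 0.0).mean(axis=1)


@dataclass
class NeurometricFit:
    """Neurometric curve for one cue x block, anchored to pre-recal reference."""

    reference_mean: float
    reference_sd: float
    headings_deg: np.ndarray
    n_per_heading: np.ndarray
    auc: np.ndarray
    p_right: np.ndarray
    pse_deg: float
    sigma_deg: float
    preferred_side: str
    converged: bool
    bootstrap_sd_pse: float = np.nan


def build_neurometric(
    fr: np.ndarray,
    headings: np.ndarray,
    reference: tuple[float, float],
    preferred_side: str,
    n_criteria: int = 100,
) -> NeurometricFit:
    """Neurometric curve and PSE from one block's FRs.

    ``reference`` is the (mean, SD) of the same cue's pre-block FRs;
    ``preferred_side`` comes from the pre-block tuning slope and is reused
    for the post block so that shifts keep a consistent sign.
    """
    mean, sd = reference
    headings = np.asarray(headings, float)
    hs = np.unique(headings)
    n = np.array([(headings == h).sum() for h in hs])
    if sd <= 0 or not np.isfinite(sd):
        nanh = np.full(hs.size, np.nan)
        return NeurometricFit(mean, sd, hs, n, nanh, nanh, np.nan, np.nan, preferred_side, False)
    z = (np.asarray(fr, float) - mean) / sd
    auc = np.array([auc_vs_reference(z[headings == h], n_criteria) for h in hs])
    p_right = auc if preferred_side == "right" else 1.0 - auc
    mu, sigma, ok = fit_cum_gauss_batch(hs, p_right[None, :], weights=n.astype(float))
    return NeurometricFit(
        reference_mean=mean,
        reference_sd=sd,
        headings_deg=hs,
        n_per_heading=n,
        auc=auc,
        p_right=p_right,
        pse_deg=float(mu[0]),
        sigma_deg=float(sigma[0]),
        preferred_side=preferred_side,
        converged=bool(ok[0]),
    )


def bootstrap_pse_sd(
    fr: np.ndarray,
    headings: np.ndarray,
    reference: tuple[float, float],
    preferred_side: str,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    n_criteria: int = 100,
    max_nonconverged_frac: float = 0.2,
) -> float:
    """Bootstrap SD of the neurometric PSE (reliability of the estimate).

    Trials are resampled with replacement within each heading (preserving the
    design balance) and the neurometric PSE refit ``n_boot`` times.
    Non-converged refits are dropped; if more than ``max_nonconverged_frac``
    drop, the SD is +inf, i.e. the neuron fails the reliability screen.
    """
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50")
    rng = np.random.default_rng() if rng is None else rng
    mean, sd = reference
    if sd <= 0 or not np.isfinite(sd):
        return float("inf")
    headings = np.asarray(headings, float)
    z = (np.asarray(fr, float) - mean) / sd
    hs = np.unique(headings)
    n = np.array([(headings == h).sum() for h in hs])
    p_right = np.empty((n_boot, hs.size))
    for j, h in enumerate(hs):
        zh = z[headings == h]
        idx = rng.integers(0, zh.size, size=(n_boot, zh.size))
        auc = _auc_batch(zh[idx], n_criteria)
        p_right[:, j] = auc if preferred_side == "right" else 1.0 - auc
    mu, _, ok = fit_cum_gauss_batch(hs, p_right, weights=n.astype(float))
    if (~ok).mean() > max_nonconverged_frac:
        return float("inf")
    mus = mu[ok]
    if mus.size < 2:
        return float("inf")
    return float(mus.std(ddof=1))


# --------------------------------------------------------------------------- #
# screening and shifts
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ScreenResult:
    """Inclusion screen for one (neuron, cue)."""

    tuned_pre: bool
    tuned_post: bool
    bootstrap_sd_pre: float
    bootstrap_sd_post: float

    @property
    def passed(self) -> bool:
        return (self.tuned_pre or self.tuned_post) and (
            self.bootstrap_sd_pre < BOOTSTRAP_SD_SCREEN_DEG
            and self.bootstrap_sd_post < BOOTSTRAP_SD_SCREEN_DEG
        )


def screen_neuron(
    tuning_pre: TuningFit,
    tuning_post: TuningFit,
    sd_pre: float,
    sd_post: float,
) -> ScreenResult:
    """Apply both inclusion criteria: significant tuning (either block) and
    reliable neurometric PSEs (bootstrap SD < 10 deg in both blocks)."""
    return ScreenResult(
        tuned_pre=tuning_pre.tuned,
        tuned_post=tuning_post.tuned,
        bootstrap_sd_pre=float(sd_pre),
        bootstrap_sd_post=float(sd_post),
    )


def neuronal_shift(
    fit_pre: NeurometricFit,
    fit_post: NeurometricFit,
    screen: ScreenResult | None = None,
) -> float:
    """Neuronal recalibration: post minus pre neurometric PSE (degrees)."""
    if screen is not None and not screen.passed:
        raise ValueError("neuron did not pass the inclusion screen")
    if not (fit_pre.converged and fit_post.converged):
        return float("nan")
    return fit_post.pse_deg - fit_pre.pse_deg


# --------------------------------------------------------------------------- #
# session-level drivers
# --------------------------------------------------------------------------- #


def _single_cue_mask(trials: pd.DataFrame, cue: str, block: str) -> np.ndarray:
    return ((trials["modality"] == cue) & (trials["block"] == block)).to_numpy()


def analyze_session_neuron(
    session: SessionData,
    neuron_id: str,
    cue: str,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    tuning_on_baseline_subtracted: bool = True,
    window: tuple[float, float] = STIMULUS_WINDOW_S,
) -> dict:
    """Full-window neurometric analysis of one (neuron, cue).

    Returns a record with tuning p-values, neurometric PSEs pre/post,
    bootstrap SDs, the screen outcome and the neuronal shift (NaN when the
    screen fails).  Tuning regressions use baseline-subtracted FRs by
    default; neurometrics always use raw FRs (the z-scoring supplies its own
    reference).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    spikes = session.spikes[neuron_id]
    trials = session.trials
    fr = trial_firing_rates(spikes, session.bin_edges_s, trials["block"], window=window)
    values = fr.baseline_subtracted_hz if tuning_on_baseline_subtracted else fr.fr_hz

    masks = {b: _single_cue_mask(trials, cue, b) for b in ("pre", "post")}
    h = trials["heading_deg"].to_numpy(dtype=float)
    tun = {b: tuning_regression(values[masks[b]], h[masks[b]]) for b in ("pre", "post")}
    ref = reference_stats(fr.fr_hz[masks["pre"]])
    side = tun["pre"].preferred_side

    fits, sds = {}, {}
    for b in ("pre", "post"):
        fits[b] = build_neurometric(fr.fr_hz[masks[b]], h[masks[b]], ref, side)
        sds[b] = bootstrap_pse_sd(fr.fr_hz[masks[b]], h[masks[b]], ref, side, n_boot, rng)
    screen = screen_neuron(tun["pre"], tun["post"], sds["pre"], sds["post"])
    shift = neuronal_shift(fits["pre"], fits["post"]) if screen.passed else float("nan")
    return {
        "session_id": session.session_id,
        "monkey_id": session.monkey_id,
        "neuron_id": neuron_id,
        "cue": cue,
        "delta_sign": session.config.delta_sign,
        "slope_pre": tun["pre"].slope,
        "p_tuning_pre": tun["pre"].p_value,
        "p_tuning_post": tun["post"].p_value,
        "preferred_side": side,
        "pse_pre_deg": fits["pre"].pse_deg,
        "pse_post_deg": fits["post"].pse_deg,
        "bootstrap_sd_pre_deg": sds["pre"],
        "bootstrap_sd_post_deg": sds["post"],
        "passed_screen": screen.passed,
        "neuronal_shift_deg": shift,
    }


def analyze_session_neurons(
    session: SessionData,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    cues: Sequence[str] = ("vestibular", "visual"),
) -> pd.DataFrame:
    """Apply :func:`analyze_session_neuron` to every neuron and cue."""
    rng = np.random.default_rng(0) if rng is None else rng
    rows = [
        analyze_session_neuron(session, nid, cue, n_boot=n_boot, rng=rng)
        for nid in sorted(session.spikes)
        for cue in cues
    ]
    return pd.DataFrame(rows)


def sliding_window_shifts(
    session: SessionData,
    neuron_id: str,
    cue: str,
    centers_s: Sequence[float] = SLIDING_WINDOW_CENTERS_S,
    half_width_s: float = 0.1,
) -> pd.DataFrame:
    """Time-resolved neuronal shifts in 200 ms windows stepped by 100 ms.

    For each window the reference stats are recomputed from the pre block in
    that same window; the preferred side is fixed from the full-window
    pre-block tuning.  Returns one row per window center with the pre/post
    neurometric PSEs and their difference.
    """
    spikes = session.spikes[neuron_id]
    trials = session.trials
    h = trials["heading_deg"].to_numpy(dtype=float)
    masks = {b: _single_cue_mask(trials, cue, b) for b in ("pre", "post")}
    fr_full = trial_firing_rates(spikes, session.bin_edges_s, trials["block"])
    side = tuning_regression(
        fr_full.baseline_subtracted_hz[masks["pre"]], h[masks["pre"]]
    ).preferred_side

    rows = []
    for c in centers_s:
        window = (round(c - half_width_s, 9), round(c + half_width_s, 9))
        fr = window_firing_rates(spikes, session.bin_edges_s, window)
        ref = reference_stats(fr[masks["pre"]])
        fit_pre = build_neurometric(fr[masks["pre"]], h[masks["pre"]], ref, side)
        fit_post = build_neurometric(fr[masks["post"]], h[masks["post"]], ref, side)
        ok = fit_pre.converged and fit_post.converged
        rows.append(
            {
                "session_id": session.session_id,
                "neuron_id": neuron_id,
                "cue": cue,
                "window_center_s": float(c),
                "pse_pre_deg": fit_pre.pse_deg,
                "pse_post_deg": fit_post.pse_deg,
                "shift_deg": fit_post.pse_deg - fit_pre.pse_deg if ok else np.nan,
                "converged": ok,
            }
        )
    return pd.DataFrame(rows)
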