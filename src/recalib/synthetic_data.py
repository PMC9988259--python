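"""Synthetic sessions of the three-block cue-conflict recalibration paradigm.

One experimental session consists of:

* a **pre** block of randomly interleaved vestibular-only and visual-only
  heading-discrimination trials over ten signed, log-spaced headings;
* a **recalibration** block of combined-cue trials in which a systematic
  vestibular-visual discrepancy Delta is ramped up in fixed steps and then
  held at its maximum (the two cues are offset to opposite sides by Delta/2;
  no choice is required, fixation alone is rewarded);
* a **post** block in which single-cue trials (used to measure the
  recalibration aftereffect) are interleaved with combined-cue trials at the
  maximum Delta that maintain the recalibrated state.

Choices follow per-cue, per-block cumulative-Gaussian observers, and spike
counts follow heading-tuned, choice-coupled rates modulated by the stimulus
velocity profile (optionally with a sustained, leaky-integrated time course).
Recalibration is generative: perceptual PSEs and neuronal tuning centers step
between the pre and post blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import ndtr

from .stimulus import StimulusProfile, DEFAULT_STIMULUS

__all__ = [
    "ParadigmConfig",
    "BehaviorProfile",
    "NeuronProfile",
    "Trial",
    "SessionData",
    "build_trial_schedule",
    "simulate_choice",
    "simulate_choices",
    "simulate_spike_counts",
    "make_area_population",
    "simulate_session",
    "sample_session_behavior",
    "trials_to_frame",
    "default_time_grid",
    "AREAS",
    "CUES",
    "BLOCKS",
]

CUES = ("vestibular", "visual")
BLOCKS = ("pre", "recal", "post")
AREAS = ("MSTd-like", "PIVC-like", "VIP-like")

#: Default headings: signed, log-spaced, symmetric about straight ahead.
DEFAULT_HEADINGS = (-16.0, -8.0, -4.0, -2.0, -1.0, 1.0, 2.0, 4.0, 8.0, 16.0)


# --------------------------------------------------------------------------- #
# configuration dataclasses
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ParadigmConfig:
    """Trial-schedule parameters for one session.

    ``delta_max_deg`` is signed: positive (Delta+) offsets the vestibular cue
    rightward and the visual cue leftward, negative the reverse.
    """

    headings_deg: tuple[float, ...] = DEFAULT_HEADINGS
    reps_pre: int = 10
    delta_max_deg: float = 10.0
    delta_ramp_step_deg: float = 2.0
    reps_per_ramp_increment: int = 8
    reps_max_delta: int = 12
    reps_post_single: int = 10
    reps_post_combined: int = 4
    reward_p_correct: float = 0.95
    reward_p_stochastic: float = 0.70
    rng_seed: int = 0

    def __post_init__(self) -> None:
        h = np.asarray(self.headings_deg, dtype=float)
        if h.size < 2 or np.any(h == 0):
            raise ValueError("headings must be nonzero")
        if not np.allclose(np.sort(h), np.sort(-h)):
            raise ValueError("headings must be symmetric about 0")
        if self.delta_max_deg == 0:
            raise ValueError("delta_max_deg must be nonzero")
        step, dmax = self.delta_ramp_step_deg, abs(self.delta_max_deg)
        if step <= 0 or abs(round(dmax / step) - dmax / step) > 1e-9:
            raise ValueError("delta_ramp_step_deg must divide |delta_max_deg|")
        for name in ("reward_p_correct", "reward_p_stochastic"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "reps_pre",
            "reps_per_ramp_increment",
            "reps_max_delta",
            "reps_post_single",
            "reps_post_combined",
        ):
            if getattr(self, name) < 0 or (name in ("reps_pre",) and getattr(self, name) == 0):
                raise ValueError(f"{name} must be nonnegative (reps_pre positive)")

    @property
    def delta_sign(self) -> str:
        return "+" if self.delta_max_deg > 0 else "-"

    @property
    def ramp_deltas_deg(self) -> tuple[float, ...]:
        """Signed Delta sequence of the ramp, ending at ``delta_max_deg``."""
        n = int(round(abs(self.delta_max_deg) / self.delta_ramp_step_deg))
        sign = 1.0 if self.delta_max_deg > 0 else -1.0
        return tuple(sign * self.delta_ramp_step_deg * k for k in range(1, n + 1))


def _cue_block_map(value, cues=CUES, blocks=("pre", "post")) -> dict:
    """Broadcast a scalar/nested mapping to a {cue: {block: float}} dict."""
    if isinstance(value, Mapping):
        return {c: {b: float(value[c][b]) for b in blocks} for c in cues}
    return {c: {b: float(value) for b in blocks} for c in cues}


@dataclass
class BehaviorProfile:
    """Generative behavioral observer: per (cue, block) PSE and threshold.

    ``pse_deg`` / ``sigma_deg`` map cue -> block -> degrees.  ``lapse`` is a
    symmetric lapse probability.  On combined-cue trials the effective heading
    is ``w * h_vest + (1 - w) * h_vis`` with ``w = combined_weight_vest``, and
    the combined PSE/threshold derive from the single-cue profiles under the
    same weighting.
    """

    pse_deg: dict = field(default_factory=lambda: _cue_block_map(0.0))
    sigma_deg: dict = field(default_factory=lambda: _cue_block_map(4.0))
    lapse: float = 0.02
    combined_weight_vest: float = 0.6

    def __post_init__(self) -> None:
        self.pse_deg = _cue_block_map(self.pse_deg)
        self.sigma_deg = _cue_block_map(self.sigma_deg)
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse must be in [0, 0.1]")
        if not 0.0 <= self.combined_weight_vest <= 1.0:
            raise ValueError("combined_weight_vest must be in [0, 1]")
        for c in CUES:
            for b in ("pre", "post"):
                if self.sigma_deg[c][b] < 0:
                    raise ValueError("sigma_deg must be nonnegative")

    @classmethod
    def from_shifts(
        cls,
        pse_pre: Mapping[str, float] | float = 0.0,
        shift: Mapping[str, float] | float = 0.0,
        sigma: Mapping[str, float] | float = 4.0,
        lapse: float = 0.02,
        combined_weight_vest: float = 0.6,
    ) -> "BehaviorProfile":
        """Build a profile from pre-block PSEs and generative post-pre shifts."""
        def get(m, c):
            return float(m[c]) if isinstance(m, Mapping) else float(m)

        pse = {c: {"pre": get(pse_pre, c), "post": get(pse_pre, c) + get(shift, c)} for c in CUES}
        sig = {c: {"pre": get(sigma, c), "post": get(sigma, c)} for c in CUES}
        return cls(pse_deg=pse, sigma_deg=sig, lapse=lapse, combined_weight_vest=combined_weight_vest)

    def perceptual_shift(self, cue: str) -> float:
        return self.pse_deg[cue]["post"] - self.pse_deg[cue]["pre"]

    def combined_params(self, block: str) -> tuple[float, float]:
        """(PSE, sigma) of the weighted-average combined-cue observer."""
        w = self.combined_weight_vest
        pse = w * self.pse_deg["vestibular"][block] + (1 - w) * self.pse_deg["visual"][block]
        sig = float(
            np.hypot(w * self.sigma_deg["vestibular"][block], (1 - w) * self.sigma_deg["visual"][block])
        )
        return pse, sig

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class NeuronProfile:
    """Generative single-neuron model.

    Bin rate: ``baseline + [slope_cue * (h_cue - tuning_shift[cue][block])
    + choice_gain[cue][block] * C] * m(t)`` with ``C in {-1, +1}`` (0 when no
    choice is made), ``m(t)`` the normalized stimulus velocity
    (``temporal_mode='velocity'``) or its leaky integral with time constant
    ``sustain_tau_s`` (``'sustained'``, persisting past stimulus offset).
    Rates are clipped at zero before count draws.
    """

    baseline_hz: float = 20.0
    slope_hz_per_deg: dict = field(default_factory=lambda: {c: 2.0 for c in CUES})
    tuning_shift_deg: dict = field(default_factory=lambda: _cue_block_map(0.0))
    choice_gain_hz: dict = field(default_factory=lambda: _cue_block_map(0.0))
    temporal_mode: Literal["velocity", "sustained"] = "velocity"
    sustain_tau_s: float = 0.5
    noise_model: Literal["poisson", "gaussian"] = "poisson"
    gaussian_sd_hz: float = 3.0

    def __post_init__(self) -> None:
        self.slope_hz_per_deg = {c: float(self.slope_hz_per_deg[c]) for c in CUES} if isinstance(
            self.slope_hz_per_deg, Mapping
        ) else {c: float(self.slope_hz_per_deg) for c in CUES}
        self.tuning_shift_deg = _cue_block_map(self.tuning_shift_deg)
        self.choice_gain_hz = _cue_block_map(self.choice_gain_hz)
        if self.baseline_hz < 0:
            raise ValueError("baseline_hz must be nonnegative")
        if self.sustain_tau_s <= 0:
            raise ValueError("sustain_tau_s must be positive")
        if self.temporal_mode not in ("velocity", "sustained"):
            raise ValueError(f"unknown temporal_mode {self.temporal_mode!r}")
        if self.noise_model not in ("poisson", "gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Trial:
    """One behavioral trial; single-cue trials carry exactly one cue heading."""

    trial_id: int
    block: str
    modality: str
    heading_deg: float
    vest_heading_deg: float
    vis_heading_deg: float
    delta_deg: float
    choice: str = "none"
    rewarded: bool = False


TRIAL_COLUMNS = (
    "trial_id",
    "block",
    "modality",
    "heading_deg",
    "vest_heading_deg",
    "vis_heading_deg",
    "delta_deg",
    "choice",
    "rewarded",
)


def trials_to_frame(trials: Sequence[Trial]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(t) for t in trials], columns=list(TRIAL_COLUMNS))
    return df.astype({"trial_id": int, "rewarded": bool})


@dataclass
class SessionData:
    """One simulated session: trial table, per-neuron spike-count matrices, truth."""

    trials: pd.DataFrame
    spikes: dict[str, np.ndarray]  # neuron_id -> (n_trials, n_bins) counts
    bin_edges_s: np.ndarray
    config: ParadigmConfig
    behavior: BehaviorProfile | None = None
    neurons: dict[str, NeuronProfile] = field(default_factory=dict)
    monkey_id: str = "sim"
    session_id: str = "s000"
    area: str = ""

    @property
    def bin_width_s(self) -> float:
        return float(self.bin_edges_s[1] - self.bin_edges_s[0])

    def __post_init__(self) -> None:
        n = len(self.trials)
        for nid, mat in self.spikes.items():
            if mat.shape != (n, len(self.bin_edges_s) - 1):
                raise ValueError(f"spike matrix {nid!r} misaligned with trials/grid")


def default_time_grid(start_s: float = -1.0, end_s: float = 1.3, bin_s: float = 0.1) -> np.ndarray:
    """Bin edges spanning baseline and stimulus epochs (default 23 bins of 100 ms)."""
    n = int(round((end_s - start_s) / bin_s))
    return start_s + bin_s * np.arange(n + 1)


# --------------------------------------------------------------------------- #
# schedule
# --------------------------------------------------------------------------- #


def _single_cue_trial(tid: int, block: str, cue: str, h: float) -> Trial:
    return Trial(
        trial_id=tid,
        block=block,
        modality=cue,
        heading_deg=h,
        vest_heading_deg=h if cue == "vestibular" else np.nan,
        vis_heading_deg=h if cue == "visual" else np.nan,
        delta_deg=0.0,
    )


def _combined_trial(tid: int, block: str, mid: float, delta: float) -> Trial:
    return Trial(
        trial_id=tid,
        block=block,
        modality="combined",
        heading_deg=mid,
        vest_heading_deg=mid + delta / 2.0,
        vis_heading_deg=mid - delta / 2.0,
        delta_deg=delta,
    )


def build_trial_schedule(cfg: ParadigmConfig, rng: np.random.Generator) -> list[Trial]:
    """Build the full three-block trial sequence for one session.

    Pre: ``reps_pre`` repetitions of every (cue, heading), randomly interleaved.
    Recalibration: combined trials whose |Delta| ramps up by
    ``delta_ramp_step_deg`` (``reps_per_ramp_increment`` trials per increment,
    headings cycled in shuffled order) and is then held at the maximum for an
    additional ``reps_max_delta`` trials; no choices are collected.
    Post: ``reps_post_single`` single-cue repetitions per (cue, heading)
    interleaved with ``reps_post_combined`` combined repetitions per heading at
    the maximum Delta.
    """
    headings = np.asarray(cfg.headings_deg, dtype=float)
    trials: list[Trial] = []
    tid = 0

    # pre block: single-cue, fully interleaved
    pre: list[tuple[str, float]] = [
        (cue, h) for cue in CUES for h in headings for _ in range(cfg.reps_pre)
    ]
    rng.shuffle(pre)
    for cue, h in pre:
        trials.append(_single_cue_trial(tid, "pre", cue, float(h)))
        tid += 1

    # recalibration block: Delta ramp then hold; headings cycled in shuffled order
    def draw_headings(n: int) -> np.ndarray:
        reps = int(np.ceil(n / headings.size))
        pool = np.concatenate([rng.permutation(headings) for _ in range(reps)])
        return pool[:n]

    ramp = cfg.ramp_deltas_deg
    for i, delta in enumerate(ramp):
        n = cfg.reps_per_ramp_increment + (cfg.reps_max_delta if i == len(ramp) - 1 else 0)
        for mid in draw_headings(n):
            trials.append(_combined_trial(tid, "recal", float(mid), float(delta)))
            tid += 1

    # post block: single-cue probes interleaved with max-Delta combined trials
    post: list[Trial] = []
    for cue in CUES:
        for h in headings:
            for _ in range(cfg.reps_post_single):
                post.append(_single_cue_trial(-1, "post", cue, float(h)))
    for mid in headings:
        for _ in range(cfg.reps_post_combined):
            post.append(_combined_trial(-1, "post", float(mid), cfg.delta_max_deg))
    order = rng.permutation(len(post))
    for k in order:
        t = post[k]
        t.trial_id = tid
        trials.append(t)
        tid += 1
    return trials


# --------------------------------------------------------------------------- #
# choices and rewards
# --------------------------------------------------------------------------- #


def _p_right(h_eff: float | np.ndarray, pse: float | np.ndarray, sigma, lapse) -> np.ndarray:
    """Lapse-contaminated cumulative-Gaussian P(rightward); step limit at sigma=0."""
    h_eff, pse, sigma = np.asarray(h_eff, float), np.asarray(pse, float), np.asarray(sigma, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        core = np.where(
            sigma > 0,
            ndtr((h_eff - pse) / np.where(sigma > 0, sigma, 1.0)),
            np.where(h_eff > pse, 1.0, np.where(h_eff < pse, 0.0, 0.5)),
        )
    return lapse / 2.0 + (1.0 - lapse) * core


def simulate_choice(trial: Trial, behavior: BehaviorProfile, rng: np.random.Generator) -> str:
    """Draw a left/right choice for one trial from the generative observer."""
    if trial.block == "recal":
        raise ValueError("recalibration-block trials do not collect choices")
    block = trial.block
    if trial.modality == "combined":
        w = behavior.combined_weight_vest
        h_eff = w * trial.vest_heading_deg + (1 - w) * trial.vis_heading_deg
        pse, sigma = behavior.combined_params(block)
    else:
        h_eff = trial.heading_deg
        pse = behavior.pse_deg[trial.modality][block]
        sigma = behavior.sigma_deg[trial.modality][block]
    p = float(_p_right(h_eff, pse, sigma, behavior.lapse))
    return "right" if rng.random() < p else "left"


def _reward_rule(trial: Trial, cfg: ParadigmConfig) -> str:
    """Reward regime for a trial: 'fixation', 'deterministic' or 'stochastic'.

    Post-block single-cue trials are rewarded deterministically only when the
    implied other-cue heading (offset by the full Delta) falls on the same
    side of straight ahead; otherwise reward is stochastic, so as not to give
    feedback that would counteract the recalibrated percept.  Combined post
    trials are deterministic only when both cue headings share a side.
    """
    if trial.block == "recal":
        return "fixation"
    if trial.block == "pre":
        return "deterministic"
    delta = cfg.delta_max_deg
    if trial.modality == "combined":
        same = np.sign(trial.vest_heading_deg) == np.sign(trial.vis_heading_deg)
        return "deterministic" if same and trial.vest_heading_deg != 0 else "stochastic"
    h = trial.heading_deg
    other = h - delta if trial.modality == "vestibular" else h + delta
    same = np.sign(h) == np.sign(other) and other != 0
    return "deterministic" if same else "stochastic"


def _assign_reward(trial: Trial, cfg: ParadigmConfig, rng: np.random.Generator) -> bool:
    rule = _reward_rule(trial, cfg)
    if rule == "fixation":
        return True
    if rule == "stochastic":
        return bool(rng.random() < cfg.reward_p_stochastic)
    correct = (trial.choice == "right") == (trial.heading_deg > 0)
    return bool(correct and rng.random() < cfg.reward_p_correct)


def simulate_choices(
    trials: Iterable[Trial], behavior: BehaviorProfile, cfg: ParadigmConfig, rng: np.random.Generator
) -> None:
    """Fill ``choice`` and ``rewarded`` in place for a full schedule."""
    for t in trials:
        if t.block == "recal":
            t.choice = "none"
            t.rewarded = True
            continue
        t.choice = simulate_choice(t, behavior, rng)
        t.rewarded = _assign_reward(t, cfg, rng)


# --------------------------------------------------------------------------- #
# spike counts
# --------------------------------------------------------------------------- #


_TEMPORAL_GAIN_CACHE: dict = {}


def temporal_gain(
    neuron: NeuronProfile, bin_edges: np.ndarray, stim: StimulusProfile = DEFAULT_STIMULUS
) -> np.ndarray:
    """Per-bin temporal gain m(t), averaged within bins; unit peak.

    ``velocity`` mode follows the normalized Gaussian velocity profile;
    ``sustained`` mode is the velocity profile leaky-integrated with time
    constant ``sustain_tau_s`` (rise during the stimulus, exponential decay
    persisting past offset), normalized to unit peak.
    """
    key = (
        neuron.temporal_mode,
        round(neuron.sustain_tau_s, 9),
        bin_edges.tobytes(),
        (stim.duration_s, stim.displacement_m, stim.peak_velocity_mps),
    )
    cached = _TEMPORAL_GAIN_CACHE.get(key)
    if cached is not None:
        return cached
    fine = 1e-3
    t = np.arange(bin_edges[0], bin_edges[-1], fine) + fine / 2.0
    v = stim.velocity_modulation(t)
    if neuron.temporal_mode == "velocity":
        m = v
    else:
        decay = np.exp(-fine / neuron.sustain_tau_s)
        m = lfilter([fine / neuron.sustain_tau_s], [1.0, -decay], v)
        m = m / max(m.max(), 1e-12)
    idx = np.clip(np.searchsorted(bin_edges, t, side="right") - 1, 0, len(bin_edges) - 2)
    sums = np.bincount(idx, weights=m, minlength=len(bin_edges) - 1)
    counts = np.bincount(idx, minlength=len(bin_edges) - 1)
    out = sums / np.maximum(counts, 1)
    _TEMPORAL_GAIN_CACHE[key] = out
    return out


def _trial_drive(trials: pd.DataFrame, neuron: NeuronProfile) -> np.ndarray:
    """Heading + choice drive (spikes/s at unit temporal gain) per trial."""
    block = trials["block"].to_numpy()
    # generative step: recalibrated tuning applies from the recal block onward
    bkey = np.where(block == "pre", "pre", "post")
    choice_sign = np.where(
        trials["choice"].to_numpy() == "right", 1.0, np.where(trials["choice"].to_numpy() == "left", -1.0, 0.0)
    )
    drive = np.zeros(len(trials))
    cue_cols = {"vestibular": "vest_heading_deg", "visual": "vis_heading_deg"}
    n_cues = np.zeros(len(trials))
    gain = np.zeros(len(trials))
    for cue, col in cue_cols.items():
        h = trials[col].to_numpy(dtype=float)
        present = np.isfinite(h)
        shift = np.array([neuron.tuning_shift_deg[cue][b] for b in bkey])
        g = np.array([neuron.choice_gain_hz[cue][b] for b in bkey])
        drive += np.where(present, neuron.slope_hz_per_deg[cue] * (h - shift), 0.0)
        gain += np.where(present, g, 0.0)
        n_cues += present
    gain = gain / np.maximum(n_cues, 1)  # combined trials: average of cue gains
    return drive + gain * choice_sign


def simulate_spike_counts(
    trials: pd.DataFrame | Sequence[Trial],
    neuron: NeuronProfile,
    bin_edges: np.ndarray,
    rng: np.random.Generator,
    stim: StimulusProfile = DEFAULT_STIMULUS,
) -> np.ndarray:
    """Draw the (n_trials, n_bins) spike-count matrix for one neuron.

    The bin rate is ``clip(baseline + drive * m(t), 0)`` with the heading and
    choice drive of :class:`NeuronProfile`; counts are Poisson by default, or
    zero-truncated rounded Gaussian with SD ``gaussian_sd_hz`` (per 1 s)
    for analytic cross-checks.
    """
    if not isinstance(trials, pd.DataFrame):
        trials = trials_to_frame(trials)
    bin_edges = np.asarray(bin_edges, dtype=float)
    widths = np.diff(bin_edges)
    if np.any(widths <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if bin_edges[0] > -1.0 or bin_edges[-1] < 1.0:
        raise ValueError("time grid must cover the baseline and stimulus epochs")
    m = temporal_gain(neuron, bin_edges, stim)  # (n_bins,)
    drive = _trial_drive(trials, neuron)  # (n_trials,)
    rate = np.clip(neuron.baseline_hz + drive[:, None] * m[None, :], 0.0, None)
    lam = rate * widths[None, :]
    if neuron.noise_model == "poisson":
        return rng.poisson(lam).astype(np.int64)
    sd = neuron.gaussian_sd_hz * widths[None, :]
    draws = rng.normal(lam, np.broadcast_to(sd, lam.shape))
    return np.clip(np.rint(draws), 0, None).astype(np.int64)


# --------------------------------------------------------------------------- #
# area populations
# --------------------------------------------------------------------------- #

#: Area-profile hyperparameters: typical tuning-slope magnitudes (spikes/s/deg),
#: choice gains (spikes/s), temporal mode, and jitter of tuning shifts around
#: the perceptual shifts they track (degrees).
_AREA_PARAMS = {
    "MSTd-like": dict(
        slope_mean={"vestibular": 1.5, "visual": 2.0},
        track={"vestibular": "vestibular", "visual": "visual"},
        gain_pre=2.0,
        gain_post=2.0,
        temporal_mode="velocity",
    ),
    "PIVC-like": dict(
        slope_mean={"vestibular": 2.0, "visual": 0.0},
        track={"vestibular": "vestibular", "visual": None},
        gain_pre=2.0,
        gain_post=2.0,
        temporal_mode="velocity",
    ),
    "VIP-like": dict(
        slope_mean={"vestibular": 2.0, "visual": 2.0},
        track={"vestibular": "vestibular", "visual": "vestibular"},
        gain_pre=6.0,
        gain_post=3.0,
        temporal_mode="sustained",
    ),
}

#: SD (spikes/s/deg) of the residual visual slope in PIVC-like neurons --
#: kept below tuning-screen detectability at session trial counts.
_PIVC_VISUAL_SLOPE_SD = 0.01

#: SD (degrees) of per-neuron jitter of tuning shifts around perceptual shifts.
_TUNING_SHIFT_JITTER_SD = 0.4


def make_area_population(
    area: str,
    n: int,
    behavior: BehaviorProfile,
    rng: np.random.Generator,
    noise_model: str = "poisson",
) -> list[NeuronProfile]:
    """Draw ``n`` neuron profiles with the tuning-shift signature of one area.

    MSTd-like neurons shift each cue's tuning with that cue's perceptual
    shift; PIVC-like neurons shift vestibular tuning with the vestibular
    perceptual shift and are essentially untuned to the visual cue; VIP-like
    neurons shift *both* cues' tuning with the vestibular perceptual shift
    (visual tuning therefore moves contrary to the visual perceptual shift),
    lose choice gain after recalibration, and have sustained responses.
    """
    if area not in _AREA_PARAMS:
        raise ValueError(f"unknown area {area!r}; expected one of {AREAS}")
    pars = _AREA_PARAMS[area]
    out: list[NeuronProfile] = []
    for _ in range(n):
        slopes = {}
        for cue in CUES:
            mean = pars["slope_mean"][cue]
            if mean == 0.0:
                slopes[cue] = float(rng.normal(0.0, _PIVC_VISUAL_SLOPE_SD))
            else:
                mag = float(mean * rng.lognormal(0.0, 0.25))
                slopes[cue] = mag * (1.0 if rng.random() < 0.5 else -1.0)
        shifts = {}
        for cue in CUES:
            src = pars["track"][cue]
            if src is None:
                shifts[cue] = {"pre": 0.0, "post": 0.0}
            else:
                post = behavior.perceptual_shift(src) + float(
                    rng.normal(0.0, _TUNING_SHIFT_JITTER_SD)
                )
                shifts[cue] = {"pre": 0.0, "post": post}
        gains = {
            cue: {"pre": float(pars["gain_pre"]), "post": float(pars["gain_post"])} for cue in CUES
        }
        out.append(
            NeuronProfile(
                baseline_hz=float(rng.lognormal(np.log(20.0), 0.3)),
                slope_hz_per_deg=slopes,
                tuning_shift_deg=shifts,
                choice_gain_hz=gains,
                temporal_mode=pars["temporal_mode"],
                noise_model=noise_model,
            )
        )
    return out


# --------------------------------------------------------------------------- #
# whole sessions
# --------------------------------------------------------------------------- #

#: Study conditions for batch simulation: mean Delta+ perceptual shifts
#: (degrees; vestibular rightward, visual leftward, vestibular larger), the
#: between-session SD of the shared recalibration strength, and residual
#: per-cue session variability.  Sessions vary mostly in how strongly they
#: recalibrate overall, which couples the two cues' shifts (anti-correlated
#: across a mixed Delta+/Delta- batch) and yields an across-session shift
#: dispersion of ~2 deg for the vestibular cue.
DEFAULT_SHIFT_MEANS = {"vestibular": 1.5, "visual": -0.9}
DEFAULT_STRENGTH_SD = 0.8
DEFAULT_SHIFT_RESID_SD = {"vestibular": 0.6, "visual": 0.5}
DEFAULT_SIGMA_DEG = {"vestibular": 4.0, "visual": 3.0}


def sample_session_behavior(
    delta_sign: str,
    rng: np.random.Generator,
    shift_means: Mapping[str, float] = DEFAULT_SHIFT_MEANS,
    strength_sd: float = DEFAULT_STRENGTH_SD,
    shift_resid_sd: Mapping[str, float] = DEFAULT_SHIFT_RESID_SD,
    sigma_deg: Mapping[str, float] = DEFAULT_SIGMA_DEG,
    pse_pre_sd: float = 0.8,
    lapse: float = 0.02,
) -> BehaviorProfile:
    """Draw one session's generative observer under the cue-conflict conditions.

    ``shift_means`` are stated for the Delta+ discrepancy (vestibular cue
    offset rightward); a Delta- session mirrors both signs.  A shared
    per-session recalibration strength (mean 1, SD ``strength_sd``) scales
    both cues' shifts; residual per-cue noise is added on top.
    """
    flip = 1.0 if delta_sign == "+" else -1.0
    strength = float(rng.normal(1.0, strength_sd))
    pse_pre = {c: float(rng.normal(0.0, pse_pre_sd)) for c in CUES}
    shift = {
        c: flip * (strength * shift_means[c] + float(rng.normal(0.0, shift_resid_sd[c])))
        for c in CUES
    }
    return BehaviorProfile.from_shifts(pse_pre=pse_pre, shift=shift, sigma=dict(sigma_deg), lapse=lapse)


def simulate_session(
    cfg: ParadigmConfig,
    behavior: BehaviorProfile,
    neurons: Mapping[str, NeuronProfile] | Sequence[NeuronProfile] = (),
    rng: np.random.Generator | None = None,
    bin_edges: np.ndarray | None = None,
    stim: StimulusProfile = DEFAULT_STIMULUS,
    monkey_id: str = "sim",
    session_id: str = "s000",
    area: str = "",
) -> SessionData:
    """Simulate a full session: schedule, choices/rewards, then spike counts."""
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    bin_edges = default_time_grid() if bin_edges is None else np.asarray(bin_edges, float)
    trials = build_trial_schedule(cfg, rng)
    simulate_choices(trials, behavior, cfg, rng)
    frame = trials_to_frame(trials)
    if not isinstance(neurons, Mapping):
        neurons = {f"n{i:03d}": p for i, p in enumerate(neurons)}
    spikes = {
        nid: simulate_spike_counts(frame, prof, bin_edges, rng, stim)
        for nid, prof in neurons.items()
    }
    return SessionData(
        trials=frame,
        spikes=spikes,
        bin_edges_s=bin_edges,
        config=cfg,
        behavior=behavior,
        neurons=dict(neurons),
        monkey_id=monkey_id,
        session_id=session_id,
        area=area,
    )
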