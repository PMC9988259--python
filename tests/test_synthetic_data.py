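"""Trial schedules, choice generation, spike counts and area populations."""

import numpy as np
import pytest
from scipy.special import ndtr

import recalib as rc
from recalib.synthetic_data import (
    _reward_rule,
    build_trial_schedule,
    temporal_gain,
    trials_to_frame,
    default_time_grid,
)


class TestSchedule:
    def test_block_composition_matches_config(self, small_config, rng):
        trials = build_trial_schedule(small_config, rng)
        df = trials_to_frame(trials)
        pre = df[df.block == "pre"]
        assert len(pre) == small_config.reps_pre * 2 * 10
        # per (cue, heading) repetition counts are exact
        counts = pre.groupby(["modality", "heading_deg"]).size()
        assert (counts == small_config.reps_pre).all()
        recal = df[df.block == "recal"]
        n_steps = int(10 / 2)
        assert len(recal) == (
            small_config.reps_per_ramp_increment * n_steps + small_config.reps_max_delta
        )
        assert (recal.modality == "combined").all()
        post = df[df.block == "post"]
        n_single = small_config.reps_post_single * 2 * 10
        n_comb = small_config.reps_post_combined * 10
        assert len(post) == n_single + n_comb

    def test_ramp_sequence_and_hold(self, rng):
        cfg = rc.ParadigmConfig(
            delta_max_deg=10.0,
            delta_ramp_step_deg=2.0,
            reps_per_ramp_increment=8,
            reps_max_delta=12,
        )
        trials = build_trial_schedule(cfg, rng)
        deltas = [t.delta_deg for t in trials if t.block == "recal"]
        # |Delta| blocks {2,4,6,8} x 8 then 10 x (8+12), in order
        expected = [d for step in (2.0, 4.0, 6.0, 8.0) for d in [step] * 8] + [10.0] * 20
        assert deltas == expected

    def test_combined_offsets_split_delta(self, rng):
        cfg = rc.ParadigmConfig(delta_max_deg=10.0)
        df = trials_to_frame(build_trial_schedule(cfg, rng))
        comb = df[df.modality == "combined"]
        np.testing.assert_allclose(comb.vest_heading_deg - comb.vis_heading_deg, comb.delta_deg)
        np.testing.assert_allclose(
            (comb.vest_heading_deg + comb.vis_heading_deg) / 2, comb.heading_deg
        )
        # heading 0 at max Delta: vest +5, vis -5
        row = comb[(comb.heading_deg == 0.0) & (comb.delta_deg == 10.0)]
        if len(row):
            assert (row.vest_heading_deg == 5.0).all() and (row.vis_heading_deg == -5.0).all()

    def test_single_cue_trials_have_one_heading_and_zero_delta(self, small_config, rng):
        df = trials_to_frame(build_trial_schedule(small_config, rng))
        single = df[df.modality != "combined"]
        assert (single.delta_deg == 0).all()
        assert (single.vest_heading_deg.notna() ^ single.vis_heading_deg.notna()).all()

    def test_ramp_step_must_divide_delta_max(self):
        with pytest.raises(ValueError):
            rc.ParadigmConfig(delta_max_deg=10.0, delta_ramp_step_deg=3.0)

    def test_headings_must_be_symmetric_and_nonzero(self):
        with pytest.raises(ValueError):
            rc.ParadigmConfig(headings_deg=(0.0, 1.0, -1.0))
        with pytest.raises(ValueError):
            rc.ParadigmConfig(headings_deg=(-2.0, 1.0))

    def test_same_seed_reproduces_identical_session(self, small_config):
        beh = rc.sample_session_behavior("+", np.random.default_rng(5))
        neuron = rc.NeuronProfile()
        s1 = rc.simulate_session(small_config, beh, [neuron], rng=np.random.default_rng(9))
        s2 = rc.simulate_session(small_config, beh, [neuron], rng=np.random.default_rng(9))
        assert s1.trials.equals(s2.trials)
        np.testing.assert_array_equal(s1.spikes["n000"], s2.spikes["n000"])


class TestChoices:
    def test_probability_right_at_pse_is_half(self):
        beh = rc.BehaviorProfile.from_shifts(pse_pre=2.0, shift=0.0, sigma=4.0, lapse=0.0)
        from recalib.synthetic_data import _p_right

        assert _p_right(2.0, 2.0, 4.0, 0.0) == pytest.approx(0.5)

    def test_zero_threshold_is_step_function(self, rng):
        beh = rc.BehaviorProfile.from_shifts(pse_pre=0.0, shift=0.0, sigma=0.0, lapse=0.0)
        t = rc.Trial(0, "pre", "vestibular", 4.0, 4.0, np.nan, 0.0)
        assert all(rc.simulate_choice(t, beh, rng) == "right" for _ in range(20))

    def test_choice_frequency_matches_analytic_probability(self, rng):
        # PSE=1, sigma=4, h=0 -> P(right) = Phi(-0.25) = 0.4013
        beh = rc.BehaviorProfile.from_shifts(pse_pre=1.0, shift=0.0, sigma=4.0, lapse=0.0)
        t = rc.Trial(0, "pre", "vestibular", 0.0, 0.0, np.nan, 0.0)
        n = 100_000
        hits = sum(rc.simulate_choice(t, beh, rng) == "right" for _ in range(n))
        assert hits / n == pytest.approx(ndtr(-0.25), abs=0.005)

    def test_recal_block_collects_no_choices(self, demo_session):
        recal = demo_session.trials[demo_session.trials.block == "recal"]
        assert (recal.choice == "none").all() and recal.rewarded.all()

    def test_post_block_reward_rules(self):
        cfg = rc.ParadigmConfig(delta_max_deg=10.0)
        mk = lambda cue, h: rc.Trial(0, "post", cue, h, h if cue == "vestibular" else np.nan,
                                     h if cue == "visual" else np.nan, 0.0)
        # vestibular +16: implied visual heading +6, same side -> deterministic
        assert _reward_rule(mk("vestibular", 16.0), cfg) == "deterministic"
        # vestibular +4: implied visual -6, conflicting -> stochastic
        assert _reward_rule(mk("vestibular", 4.0), cfg) == "stochastic"
        # visual -4: implied vestibular +6 -> stochastic ; visual -16 -> deterministic
        assert _reward_rule(mk("visual", -4.0), cfg) == "stochastic"
        assert _reward_rule(mk("visual", -16.0), cfg) == "deterministic"

    def test_combined_choice_uses_weighted_heading(self, rng):
        beh = rc.BehaviorProfile.from_shifts(pse_pre=0.0, shift=0.0, sigma=0.0, lapse=0.0)
        beh.combined_weight_vest = 1.0
        # vest heading +5, vis heading -15: with all weight on vest -> right
        t = rc.Trial(0, "post", "combined", -5.0, 5.0, -15.0, 20.0)
        assert rc.simulate_choice(t, beh, rng) == "right"


class TestSpikes:
    def test_untuned_neuron_fr_equals_baseline(self, small_config, rng):
        beh = rc.BehaviorProfile.from_shifts(lapse=0.0)
        prof = rc.NeuronProfile(baseline_hz=15.0, slope_hz_per_deg=0.0, choice_gain_hz=0.0)
        sess = rc.simulate_session(small_config, beh, [prof], rng=rng)
        from recalib.neurometrics import window_firing_rates

        fr = window_firing_rates(sess.spikes["n000"], sess.bin_edges_s, (0.0, 1.0))
        assert fr.mean() == pytest.approx(15.0, rel=0.05)

    def test_prestimulus_rate_is_baseline_for_any_heading(self, tuned_session):
        from recalib.neurometrics import window_firing_rates

        fr = window_firing_rates(tuned_session.spikes["n000"], tuned_session.bin_edges_s, (-1.0, 0.0))
        prof = tuned_session.neurons["n000"]
        t = tuned_session.trials
        by_heading = [
            fr[(t.heading_deg == h).to_numpy()].mean() for h in (-16.0, 16.0)
        ]
        for m in by_heading:
            assert m == pytest.approx(prof.baseline_hz, rel=0.1)

    def test_stimulus_window_mean_matches_analytic_rate(self):
        # slope 1 Hz/deg, h=8, baseline 10, velocity mode:
        # FR = 10 + 8 * mean(v(t))/v_peak over [0,1] s
        prof = rc.NeuronProfile(baseline_hz=10.0, slope_hz_per_deg=1.0, choice_gain_hz=0.0)
        edges = default_time_grid()
        trials = trials_to_frame(
            [rc.Trial(i, "pre", "vestibular", 8.0, 8.0, np.nan, 0.0, "right", False)
             for i in range(10_000)]
        )
        rng = np.random.default_rng(3)
        counts = rc.simulate_spike_counts(trials, prof, edges, rng)
        from recalib.neurometrics import window_firing_rates

        fr = window_firing_rates(counts, edges, (0.0, 1.0))
        m_bar = 0.13 / 0.41  # integral of v/v_peak over the 1 s stimulus
        expect = 10.0 + 8.0 * m_bar
        assert fr.mean() == pytest.approx(expect, abs=3 * np.sqrt(expect / 10_000))

    def test_sustained_gain_persists_past_offset(self):
        edges = default_time_grid()
        vel = temporal_gain(rc.NeuronProfile(temporal_mode="velocity"), edges)
        sus = temporal_gain(rc.NeuronProfile(temporal_mode="sustained", sustain_tau_s=0.5), edges)
        late = slice(np.searchsorted(edges, 1.0), None)  # bins after stimulus offset
        assert vel[late].max() < 0.05
        assert sus[late].max() > 0.4

    def test_gaussian_noise_model_matches_mean(self, rng):
        prof = rc.NeuronProfile(baseline_hz=30.0, slope_hz_per_deg=0.0, choice_gain_hz=0.0,
                                noise_model="gaussian", gaussian_sd_hz=4.0)
        edges = default_time_grid()
        trials = trials_to_frame(
            [rc.Trial(i, "pre", "vestibular", 1.0, 1.0, np.nan, 0.0, "left", False)
             for i in range(2000)]
        )
        counts = rc.simulate_spike_counts(trials, prof, edges, rng)
        assert counts.min() >= 0
        from recalib.neurometrics import window_firing_rates

        assert window_firing_rates(counts, edges, (0.0, 1.0)).mean() == pytest.approx(30.0, rel=0.03)


class TestAreaPopulations:
    def test_unknown_area_rejected(self, rng):
        with pytest.raises(ValueError):
            rc.make_area_population("V1-like", 3, rc.BehaviorProfile(), rng)

    def test_mstd_zero_perceptual_shift_centers_tuning_at_zero(self, rng):
        beh = rc.BehaviorProfile.from_shifts(shift=0.0)
        pop = rc.make_area_population("MSTd-like", 200, beh, rng)
        shifts = np.array(
            [p.tuning_shift_deg[c]["post"] for p in pop for c in ("vestibular", "visual")]
        )
        assert abs(shifts.mean()) < 0.1
        assert (np.array([p.tuning_shift_deg["vestibular"]["pre"] for p in pop]) == 0).all()

    def test_vip_both_cues_track_vestibular_shift(self, rng):
        beh = rc.BehaviorProfile.from_shifts(shift={"vestibular": 1.5, "visual": -0.9})
        pop = rc.make_area_population("VIP-like", 200, beh, rng)
        vest = np.array([p.tuning_shift_deg["vestibular"]["post"] for p in pop])
        vis = np.array([p.tuning_shift_deg["visual"]["post"] for p in pop])
        assert vest.mean() == pytest.approx(1.5, abs=0.15)
        assert vis.mean() == pytest.approx(1.5, abs=0.15)  # contrary to visual percept
        gains = [p.choice_gain_hz["vestibular"] for p in pop]
        assert all(g["post"] < g["pre"] for g in gains)
        assert all(p.temporal_mode == "sustained" for p in pop)

    def test_pivc_visual_slopes_are_negligible(self, rng):
        beh = rc.BehaviorProfile.from_shifts(shift={"vestibular": 1.5, "visual": -0.9})
        pop = rc.make_area_population("PIVC-like", 100, beh, rng)
        vis_slopes = np.abs([p.slope_hz_per_deg["visual"] for p in pop])
        assert np.median(vis_slopes) < 0.05
        vest_slopes = np.abs([p.slope_hz_per_deg["vestibular"] for p in pop])
        assert np.median(vest_slopes) > 1.0
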