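"""Firing rates, tuning regressions, reference-ROC neurometrics and screening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

import recalib as rc
from recalib import neurometrics as nm

HEADINGS = np.array([-16.0, -8.0, -4.0, -2.0, -1.0, 1.0, 2.0, 4.0, 8.0, 16.0])


def _linear_neuron_fr(slope, shift, noise_sd, reps, rng, baseline=30.0):
    h = np.repeat(HEADINGS, reps)
    fr = baseline + slope * (h - shift) + rng.normal(0, noise_sd, h.size)
    return h, fr


class TestFiringRates:
    def test_counts_over_window_length(self):
        edges = np.array([-1.0, 0.0, 1.0])
        spikes = np.array([[3, 20]])
        assert nm.window_firing_rates(spikes, edges, (0.0, 1.0))[0] == 20.0
        assert nm.window_firing_rates(spikes, edges, (-1.0, 0.0))[0] == 3.0

    def test_misaligned_window_rejected(self, demo_session):
        with pytest.raises(ValueError, match="aligned"):
            nm.window_firing_rates(
                demo_session.spikes["n000"], demo_session.bin_edges_s, (0.03, 1.0)
            )
        with pytest.raises(ValueError, match="outside"):
            nm.window_firing_rates(
                demo_session.spikes["n000"], demo_session.bin_edges_s, (0.0, 2.0)
            )

    def test_baseline_subtraction_centers_flat_neuron(self, rng):
        beh = rc.BehaviorProfile.from_shifts(lapse=0.0)
        prof = rc.NeuronProfile(baseline_hz=25.0, slope_hz_per_deg=0.0, choice_gain_hz=0.0)
        sess = rc.simulate_session(rc.ParadigmConfig(), beh, [prof], rng=rng)
        fr = nm.trial_firing_rates(sess.spikes["n000"], sess.bin_edges_s, sess.trials["block"])
        assert abs(fr.baseline_subtracted_hz.mean()) < 0.5
        assert fr.baseline_hz["pre"] == pytest.approx(25.0, rel=0.05)


class TestTuning:
    def test_exact_linear_tuning(self):
        fr = 2.0 * np.repeat(HEADINGS, 3)
        fit = nm.tuning_regression(fr, np.repeat(HEADINGS, 3))
        assert fit.slope == pytest.approx(2.0)
        assert fit.p_value < 1e-10 and fit.tuned
        assert fit.preferred_side == "right"

    def test_negative_slope_prefers_left(self, rng):
        h, fr = _linear_neuron_fr(-1.5, 0.0, 1.0, 5, rng)
        assert nm.tuning_regression(fr, h).preferred_side == "left"

    def test_degenerate_headings_rejected(self):
        with pytest.raises(ValueError):
            nm.tuning_regression(np.ones(10), np.ones(10))


class TestAUC:
    def test_all_above_reference(self):
        assert nm.auc_vs_reference(np.array([0.5, 1.0, 2.0])) == pytest.approx(1.0)

    def test_symmetric_pair(self):
        assert nm.auc_vs_reference(np.array([-1.0, 1.0])) == pytest.approx(0.5)

    def test_hand_computed_example(self):
        # {-1, 0.5, 2}: two of three exceed the reference
        assert nm.auc_vs_reference(np.array([-1.0, 0.5, 2.0])) == pytest.approx(2 / 3, abs=0.02)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            nm.auc_vs_reference(np.array([]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        z=st.lists(
            st.one_of(
                st.floats(-5, 5, allow_nan=False, width=32),
                st.sampled_from([0.0, 0.5, -0.5]),  # force ties incl. reference ties
            ),
            min_size=2,
            max_size=60,
        )
    )
    def test_sweep_matches_count_oracle_and_sklearn(self, z):
        z = np.asarray(z, float)
        sweep = nm.auc_vs_reference(z)
        oracle = ((z > 0).sum() + 0.5 * (z == 0).sum()) / z.size
        assert sweep == pytest.approx(oracle, abs=0.02)
        # independent route: rank-based AUC of z against the single reference 0
        sk = roc_auc_score(np.r_[np.ones(z.size), 0.0], np.r_[z, 0.0])
        assert sweep == pytest.approx(sk, abs=0.02)

    def test_batch_fast_path_equals_sweep(self, rng):
        z = rng.normal(0.2, 1.0, size=(30, 17))
        z[5, :3] = 0.0
        batch = nm._auc_batch(z)
        ref = np.array([nm.auc_vs_reference(row) for row in z])
        np.testing.assert_allclose(batch, ref, atol=1e-12)


class TestNeurometric:
    def test_symmetric_tuned_neuron_has_zero_pse(self, rng):
        h, fr = _linear_neuron_fr(2.0, 0.0, 2.0, 50, rng)
        ref = nm.reference_stats(fr)
        fit = nm.build_neurometric(fr, h, ref, "right")
        assert fit.converged
        assert fit.pse_deg == pytest.approx(0.0, abs=0.6)

    def test_monotone_p_right_for_noiseless_positive_slope(self):
        h = np.repeat(HEADINGS, 4)
        fr = 30.0 + 2.0 * h
        ref = nm.reference_stats(fr)
        fit = nm.build_neurometric(fr, h, ref, "right")
        assert (np.diff(fit.p_right) >= 0).all()

    def test_label_symmetry(self, rng):
        h, fr = _linear_neuron_fr(2.0, 3.0, 2.0, 20, rng)
        ref = nm.reference_stats(fr)
        f_right = nm.build_neurometric(fr, h, ref, "right")
        f_left = nm.build_neurometric(fr, -h, ref, "left")
        assert f_left.pse_deg == pytest.approx(-f_right.pse_deg, abs=1e-6)

    def test_reference_anchoring_offset_moves_pse_by_k_over_slope(self, rng):
        slope, k = 2.0, 2.0
        h, fr_pre = _linear_neuron_fr(slope, 0.0, 1.0, 60, rng)
        ref = nm.reference_stats(fr_pre)
        pse_pre = nm.build_neurometric(fr_pre, h, ref, "right").pse_deg
        pse_shifted = nm.build_neurometric(fr_pre + k, h, ref, "right").pse_deg
        assert pse_shifted - pse_pre == pytest.approx(-k / slope, abs=0.25)

    def test_degenerate_reference_sd_flagged(self):
        h = np.repeat(HEADINGS, 2)
        fit = nm.build_neurometric(np.ones(h.size), h, (1.0, 0.0), "right")
        assert not fit.converged

    def test_injected_shift_recovered_on_average(self, rng):
        shifts = []
        for _ in range(25):
            h, fr_pre = _linear_neuron_fr(2.0, 0.0, 4.0, 10, rng)
            _, fr_post = _linear_neuron_fr(2.0, 3.0, 4.0, 10, rng)
            ref = nm.reference_stats(fr_pre)
            f0 = nm.build_neurometric(fr_pre, h, ref, "right")
            f1 = nm.build_neurometric(fr_post, h, ref, "right")
            shifts.append(nm.neuronal_shift(f0, f1))
        assert np.nanmean(shifts) == pytest.approx(3.0, abs=0.6)


class TestBootstrapAndScreen:
    def test_small_bootstrap_rejected(self, rng):
        h, fr = _linear_neuron_fr(2.0, 0.0, 2.0, 5, rng)
        with pytest.raises(ValueError, match="n_boot"):
            nm.bootstrap_pse_sd(fr, h, nm.reference_stats(fr), "right", n_boot=10, rng=rng)

    def test_steep_noiseless_tuning_gives_tiny_sd(self, rng):
        h, fr = _linear_neuron_fr(3.0, 0.0, 0.5, 10, rng)
        sd = nm.bootstrap_pse_sd(fr, h, nm.reference_stats(fr), "right", n_boot=100, rng=rng)
        assert sd < 1.0

    def test_untuned_neuron_fails_reliability_screen(self, rng):
        fails = 0
        for _ in range(10):
            h = np.repeat(HEADINGS, 10)
            fr = rng.normal(20.0, 4.0, h.size)  # no heading dependence
            sd = nm.bootstrap_pse_sd(fr, h, nm.reference_stats(fr), "right", n_boot=100, rng=rng)
            fails += sd >= nm.BOOTSTRAP_SD_SCREEN_DEG
        assert fails >= 9

    def test_more_trials_reduce_bootstrap_sd(self, rng):
        sds = {}
        for reps in (8, 32):
            h, fr = _linear_neuron_fr(1.0, 0.0, 6.0, reps, rng)
            sds[reps] = np.median(
                [
                    nm.bootstrap_pse_sd(fr, h, nm.reference_stats(fr), "right", n_boot=100, rng=rng)
                    for _ in range(5)
                ]
            )
        assert sds[32] < sds[8]

    def test_screen_rule_truth_table(self):
        tuned = nm.TuningFit(1.0, 0.0, 0.04, "right")
        untuned = nm.TuningFit(0.1, 0.0, 0.3, "right")
        assert nm.screen_neuron(tuned, untuned, 3.0, 5.0).passed
        assert nm.screen_neuron(untuned, tuned, 3.0, 5.0).passed
        assert not nm.screen_neuron(tuned, tuned, 3.0, 12.0).passed  # SD >= 10 deg
        assert not nm.screen_neuron(untuned, untuned, 3.0, 5.0).passed

    def test_unscreened_neuron_refused(self, rng):
        h, fr = _linear_neuron_fr(2.0, 0.0, 2.0, 10, rng)
        ref = nm.reference_stats(fr)
        fit = nm.build_neurometric(fr, h, ref, "right")
        failed = nm.screen_neuron(
            nm.TuningFit(0.0, 0.0, 0.9, "right"), nm.TuningFit(0.0, 0.0, 0.9, "right"), 2.0, 2.0
        )
        with pytest.raises(ValueError, match="screen"):
            nm.neuronal_shift(fit, fit, failed)

    def test_shift_arithmetic(self, rng):
        h, fr = _linear_neuron_fr(2.0, 0.0, 2.0, 10, rng)
        ref = nm.reference_stats(fr)
        f = nm.build_neurometric(fr, h, ref, "right")
        assert nm.neuronal_shift(f, f) == 0.0


class TestSlidingWindows:
    def test_twelve_window_centers(self, tuned_session):
        out = nm.sliding_window_shifts(tuned_session, "n000", "vestibular")
        assert len(out) == 12
        np.testing.assert_allclose(out.window_center_s, 0.1 * np.arange(1, 13))

    def test_midstimulus_windows_carry_the_shift(self, tuned_session):
        out = nm.sliding_window_shifts(tuned_session, "n000", "vestibular")
        mid = out[out.window_center_s.isin([0.4, 0.5, 0.6])]
        assert mid.converged.all()
        assert mid.shift_deg.mean() == pytest.approx(1.5, abs=1.2)

    def test_session_analysis_record_schema(self, tuned_session, rng):
        rec = nm.analyze_session_neuron(tuned_session, "n000", "vestibular", n_boot=100, rng=rng)
        assert rec["passed_screen"]
        assert rec["neuronal_shift_deg"] == pytest.approx(1.5, abs=1.5)
        assert rec["preferred_side"] in ("left", "right")
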