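"""Generator tests: timelines, rate kernels, thinning, licks, eye traces."""

import numpy as np
import pytest
from scipy.integrate import quad

from sc_attention import synthetic_data as syn
from sc_attention.types import CohortSpec, RateKernelParams, TrialEvents


def _trial(t0=0.0, cue=1.0, two=2.0, chg=4.0, side="contra", change=True):
    return TrialEvents("s", 0, side, t0, cue, two, chg, 30, change)


class TestTrialTimeline:
    def test_epoch_durations_within_task_ranges(self, expert_trials):
        for tr in expert_trials:
            assert 0.2 <= tr.t_cue_on - tr.t_noise_on <= 0.3
            assert 0.36 <= tr.t_twopatch_on - tr.t_cue_on <= 1.55
            assert 0.84 <= tr.t_change_on - tr.t_twopatch_on <= 3.6

    def test_half_change_trials_for_catch_trial_cohorts(self, expert_trials):
        n_change = sum(tr.is_change for tr in expert_trials)
        assert n_change == len(expert_trials) // 2

    def test_intermediate_cohort_all_change(self):
        spec = CohortSpec("intermediate", 1, 50, False, "ramping")
        trials = syn.simulate_trial_timeline(spec, 0)
        assert all(tr.is_change for tr in trials)

    def test_cue_sides_balanced_in_blocks(self, expert_trials):
        sides = [tr.cue_side for tr in expert_trials]
        n_contra = sides.count("contra")
        assert abs(n_contra - len(sides) / 2) <= 10  # one block of slack
        # interleaved blocks: runs of a constant side of the block length
        runs = 1 + sum(s1 != s0 for s0, s1 in zip(sides, sides[1:]))
        assert runs == len(sides) // 10

    def test_single_trial_ordered(self):
        spec = CohortSpec("naive", 1, 1, True, "early_peak")
        (tr,) = syn.simulate_trial_timeline(spec, 5)
        assert tr.t_noise_on < tr.t_cue_on < tr.t_twopatch_on < tr.t_change_on

    def test_seed_determinism(self, expert_spec):
        a = syn.simulate_trial_timeline(expert_spec, 7)
        b = syn.simulate_trial_timeline(expert_spec, 7)
        c = syn.simulate_trial_timeline(expert_spec, 8)
        assert [t.t_change_on for t in a] == [t.t_change_on for t in b]
        assert [t.t_change_on for t in a] != [t.t_change_on for t in c]

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec("expert", 0, 100, True, "change_locked")
        with pytest.raises(ValueError):
            CohortSpec("intermediate", 1, 100, True, "ramping")
        with pytest.raises(ValueError):
            CohortSpec("expert", 1, 100, True, "licking_hard")


class TestRateModel:
    def test_rate_is_baseline_before_cue(self, default_params):
        tr = _trial()
        t = np.array([0.2, 0.9, 1.0 + default_params.latency_ms / 1000.0])
        r = syn.event_locked_rate(t, tr, default_params, "expert", "superficial")
        assert np.allclose(r, default_params.baseline_hz)

    def test_zero_amplitudes_give_constant_baseline(self):
        p = RateKernelParams(cue_amp_hz=0, change_amp_hz=0, delay_contra_bias_hz=0)
        tr = _trial()
        t = np.linspace(0, 5, 500)
        r = syn.event_locked_rate(t, tr, p, "expert", "deep")
        assert np.allclose(r, p.baseline_hz)

    def test_kernel_area_matches_quadrature(self, default_params):
        amp = 17.0
        area, err = quad(
            lambda t: amp * syn.transient_kernel(t, default_params), 0, 10, limit=200
        )
        expected = syn.kernel_area(amp, default_params)
        assert abs(area - expected) / expected < 1e-6

    def test_kernel_peak_is_amplitude(self, default_params):
        t = np.linspace(0, 1, 200001)
        peak = syn.transient_kernel(t, default_params).max()
        assert peak == pytest.approx(1.0, abs=1e-6)

    def test_delay_bias_only_on_contra_delay(self, default_params):
        contra = _trial(side="contra")
        ipsi = _trial(side="ipsi")
        t = np.array([3.0])  # inside the 2-patch delay epoch
        r_c = syn.event_locked_rate(t, contra, default_params, "expert", "deep")
        r_i = syn.event_locked_rate(t, ipsi, default_params, "expert", "deep")
        gain = syn.DEFAULT_GAIN_TABLE[("expert", "deep")]["delay"]
        assert r_c[0] - r_i[0] == pytest.approx(gain * default_params.delay_contra_bias_hz)


class TestThinning:
    def test_zero_rate_empty(self):
        out = syn.sample_inhomogeneous_poisson(lambda t: 0 * t, 0, 100, 1.0, 0)
        assert len(out) == 0

    def test_reversed_interval_empty(self):
        out = syn.sample_inhomogeneous_poisson(lambda t: t * 0 + 5, 10, 0, 5, 0)
        assert len(out) == 0

    def test_constant_rate_count(self):
        out = syn.sample_inhomogeneous_poisson(lambda t: t * 0 + 10, 0, 1000, 10, 42)
        assert abs(len(out) - 10000) < 5 * np.sqrt(10000)
        assert np.all(np.diff(out) >= 0)
        assert out.min() >= 0 and out.max() < 1000

    def test_ramp_rate_recovered_in_psth(self):
        # 10,000 one-second repetitions folded into one call: rate ramps
        # 0 -> 20 Hz within each repetition
        n_rep, peak = 10000, 20.0
        out = syn.sample_inhomogeneous_poisson(
            lambda t: peak * (t % 1.0), 0, n_rep, peak, 3
        )
        phase = out % 1.0
        bins = np.linspace(0, 1, 21)
        counts, _ = np.histogram(phase, bins=bins)
        centers = 0.5 * (bins[:-1] + bins[1:])
        expected = peak * centers * n_rep * np.diff(bins)
        se = np.sqrt(expected)
        assert np.all(np.abs(counts - expected) <= 3.5 * se + 3)

    def test_ceiling_violation_raises(self):
        with pytest.raises(ValueError):
            syn.sample_inhomogeneous_poisson(lambda t: t * 0 + 20, 0, 100, 5, 0)


class TestLicks:
    def test_change_locked_rarely_licks_before_change(self):
        tr = _trial()
        rng = np.random.default_rng(5)
        pre = post = 0
        for _ in range(1000):
            licks = syn.simulate_licks("change_locked", tr, rng)
            pre += np.sum(licks < tr.t_change_on)
            post += np.sum(licks >= tr.t_change_on)
        assert pre / (pre + post) < 0.05

    def test_early_peak_mode_in_first_second(self):
        tr = _trial(chg=5.0)
        rng = np.random.default_rng(6)
        alllicks = np.concatenate(
            [syn.simulate_licks("early_peak", tr, rng) for _ in range(1000)]
        )
        counts, edges = np.histogram(alllicks - tr.t_noise_on, bins=np.arange(0, 6, 0.5))
        assert edges[np.argmax(counts)] < 1.0

    def test_zero_scale_no_licks(self):
        assert len(syn.simulate_licks("ramping", _trial(), 0, scale=0.0)) == 0

    def test_unknown_archetype_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_licks("bursting", _trial(), 0)


class TestEyeTrace:
    def test_empty_schedule_constant(self):
        tr = syn.simulate_eye_trace(2.0, [], 0.0, 0)
        assert np.all(tr.x_deg == tr.x_deg[0])
        assert np.all(tr.y_deg == tr.y_deg[0])
        assert tr.sample_rate_hz == 240

    def test_net_displacement_equals_amplitude(self):
        tr = syn.simulate_eye_trace(2.0, [(1.0, 5.0, 30.0)], 0.0, 1)
        disp = np.hypot(tr.x_deg[-1] - tr.x_deg[0], tr.y_deg[-1] - tr.y_deg[0])
        assert disp == pytest.approx(5.0, abs=1e-6)

    def test_peak_speed_exceeds_detection_threshold(self):
        tr = syn.simulate_eye_trace(2.0, [(1.0, 5.0, 30.0)], 0.0, 2)
        dt = 1.0 / tr.sample_rate_hz
        speed = np.hypot(np.gradient(tr.x_deg, dt), np.gradient(tr.y_deg, dt))
        assert speed.max() > 50.0

    def test_overlapping_saccades_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_eye_trace(2.0, [(1.0, 5.0, 100.0), (1.05, 3.0, 100.0)], 0.0, 0)

    def test_out_of_range_saccade_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_eye_trace(1.0, [(0.99, 5.0, 30.0)], 0.0, 0)


class TestSessionDeterminism:
    def test_same_seed_identical_session(self, expert_spec):
        a = syn.simulate_session(expert_spec, 99, with_eye=True)
        b = syn.simulate_session(expert_spec, 99, with_eye=True)
        assert np.array_equal(a.units[0].spike_times, b.units[0].spike_times)
        assert np.array_equal(a.eye.x_deg, b.eye.x_deg)
        assert [t.outcome for t in a.trials] == [t.outcome for t in b.trials]

    def test_different_seed_differs(self, expert_spec):
        a = syn.simulate_session(expert_spec, 99, with_eye=False)
        b = syn.simulate_session(expert_spec, 100, with_eye=False)
        assert not np.array_equal(a.units[0].spike_times, b.units[0].spike_times)

    def test_all_times_within_session_span(self, expert_spec):
        sd = syn.simulate_session(expert_spec, 3, with_eye=False)
        t_end = sd.trials[-1].t_change_on + 1.5
        for u in sd.units:
            assert np.all(np.diff(u.spike_times) >= 0)
            assert u.spike_times.min() > -2 and u.spike_times.max() < t_end + 1
        for licks in sd.record.licks_by_trial.values():
            if len(licks):
                assert licks.min() >= sd.trials[0].t_noise_on
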