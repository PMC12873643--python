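"""Saccade detection and event-aligned saccade statistics."""

import numpy as np
import pytest

from sc_attention import eye_movements as em
from sc_attention import synthetic_data as syn
from sc_attention.types import EyeTrace, SaccadeEvent, TrialEvents


def _flat_trace(duration=2.0, fs=240.0):
    n = int(duration * fs)
    t = np.arange(n) / fs
    return EyeTrace("s", fs, t, np.zeros(n), np.zeros(n))


def _trial(t0=0.0):
    return TrialEvents("s", int(t0), "contra", t0, t0 + 0.3, t0 + 1.0, t0 + 4.0, 30, True)


class TestDetectSaccades:
    def test_constant_position_no_detections(self):
        assert em.detect_saccades(_flat_trace()) == []

    def test_injected_saccade_recovered(self):
        trace = syn.simulate_eye_trace(4.0, [(1.5, 5.0, 30.0)], 0.0, 0)
        events = em.detect_saccades(trace)
        assert len(events) == 1
        ev = events[0]
        assert ev.amplitude_deg == pytest.approx(5.0, abs=0.1)
        assert abs(ev.onset_s - 1.5) < 0.02
        assert ev.duration_ms > 15
        assert ev.peak_speed_dps > 50

    def test_slow_drift_ignored(self):
        # 10 deg/s drift: large amplitude but never crosses the speed threshold
        fs = 240.0
        n = int(4 * fs)
        t = np.arange(n) / fs
        trace = EyeTrace("s", fs, t, 10.0 * t, np.zeros(n))
        assert em.detect_saccades(trace) == []

    def test_subthreshold_amplitude_ignored(self):
        # fast but tiny (1.5 deg) movement fails the amplitude criterion
        trace = syn.simulate_eye_trace(4.0, [(1.5, 1.5, 20.0)], 0.0, 0)
        assert em.detect_saccades(trace) == []

    def test_translation_invariance(self):
        a = syn.simulate_eye_trace(4.0, [(1.0, 4.0, 30.0)], 0.0, 3)
        b = EyeTrace("s", a.sample_rate_hz, a.t, a.x_deg + 7.5, a.y_deg - 2.0)
        ev_a = em.detect_saccades(a)
        ev_b = em.detect_saccades(b)
        assert len(ev_a) == len(ev_b) == 1
        assert ev_a[0].amplitude_deg == pytest.approx(ev_b[0].amplitude_deg)
        assert ev_a[0].onset_s == ev_b[0].onset_s

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            em.detect_saccades(EyeTrace("s", 240.0, [0.0], [0.0], [0.0]))

    def test_detection_under_noise(self):
        """With tracker noise the detector still finds large saccades."""
        trace = syn.simulate_eye_trace(6.0, [(2.0, 6.0, 40.0)], 0.05, 5)
        events = em.detect_saccades(trace)
        assert len(events) == 1
        assert events[0].amplitude_deg == pytest.approx(6.0, abs=0.5)


class TestSaccadeProbability:
    def test_no_saccades_zero_probability(self):
        trials = [_trial(10.0 * i) for i in range(5)]
        _, prob = em.saccade_probability_timecourse([], trials, "cue_on", (-200, 200), 20)
        assert np.all(prob == 0)

    def test_saccade_every_trial_at_fixed_latency(self):
        trials = [_trial(10.0 * i) for i in range(5)]
        sacc = [
            SaccadeEvent("s", tr.t_cue_on + 0.050, 20.0, 5.0, 200.0) for tr in trials
        ]
        starts, prob = em.saccade_probability_timecourse(sacc, trials, "cue_on", (-200, 200), 20)
        k = np.where(starts == 40)[0][0]
        assert prob[k] == 1.0
        assert prob.sum() == 1.0

    def test_poisson_rate_interval_probability(self, rng):
        """P(>=1 onset in a window) matches 1 - exp(-rate * width)."""
        lam, width_s, n_trials = 0.8, 0.5, 2000
        events = []
        for i in range(n_trials):
            t0 = 10.0 * i
            n = rng.poisson(lam * width_s)
            events += [SaccadeEvent("s", float(t0 + u), 20, 5, 200) for u in rng.uniform(0, width_s, n)]
        times = 10.0 * np.arange(n_trials)
        p = em.interval_saccade_probability(events, times, (0, width_s * 1000))
        expected = 1 - np.exp(-lam * width_s)
        se = np.sqrt(expected * (1 - expected) / n_trials)
        assert abs(p - expected) < 3 * se

    def test_interval_probability_bounds_single_bins(self, rng):
        trials = [_trial(10.0 * i) for i in range(50)]
        sacc = [
            SaccadeEvent("s", tr.t_cue_on + rng.uniform(-0.2, 0.2), 20, 5, 200)
            for tr in trials
            if rng.random() < 0.6
        ]
        starts, prob = em.saccade_probability_timecourse(sacc, trials, "cue_on", (-200, 200), 20)
        times = np.array([tr.t_cue_on for tr in trials])
        p_int = em.interval_saccade_probability(sacc, times, (-200, 200))
        assert prob.max() <= p_int <= 1.0


class TestSaccadeFreeMask:
    WINDOWS = [("cue_on", (-100.0, 0.0)), ("cue_on", (40.0, 140.0))]

    def test_no_saccades_all_true(self):
        trials = [_trial(10.0 * i) for i in range(4)]
        assert em.saccade_free_mask([], trials, self.WINDOWS).all()

    def test_saccade_in_response_window_flags_trial(self):
        trials = [_trial(0.0), _trial(10.0)]
        sacc = [SaccadeEvent("s", trials[1].t_cue_on + 0.100, 20, 5, 200)]
        mask = em.saccade_free_mask(sacc, trials, self.WINDOWS)
        assert mask.tolist() == [True, False]

    def test_saccade_outside_windows_ignored(self):
        trials = [_trial(0.0)]
        sacc = [SaccadeEvent("s", trials[0].t_cue_on + 0.500, 20, 5, 200)]
        assert em.saccade_free_mask(sacc, trials, self.WINDOWS).all()

    def test_masking_leaves_unmodulated_auroc_unchanged(self):
        """Removing saccade-marked trials does not shift AROC when spiking
        is independent of saccades (difference within the CI width)."""
        from sc_attention import discriminability as disc
        from sc_attention.types import CohortSpec, RateKernelParams, UnitRecord

        spec = CohortSpec("expert", 1, 200, True, "change_locked")
        trials = syn.simulate_trial_timeline(spec, 41)
        params = RateKernelParams()
        spikes = syn.simulate_unit_spikes(trials, params, "expert", "deep", 42)
        unit = UnitRecord("u", "s", "deep", 500, spikes)
        rng = np.random.default_rng(43)
        sacc = [
            SaccadeEvent("s", tr.t_cue_on + rng.uniform(-0.1, 0.14), 20, 5, 200)
            for tr in trials
            if rng.random() < 0.15
        ]
        mask = em.saccade_free_mask(sacc, trials, self.WINDOWS)
        assert 0 < mask.sum() < len(trials)
        spec_cue = disc.epoch_spec("cue_onset")
        full = disc.epoch_discriminability(unit, trials, spec_cue, rng_seed=44)
        masked = disc.epoch_discriminability(
            unit, [t for t, ok in zip(trials, mask) if ok], spec_cue, rng_seed=45
        )
        ci_width = full.ci_hi - full.ci_lo
        assert abs(masked.auroc - full.auroc) < ci_width
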