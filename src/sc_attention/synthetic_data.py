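"""Synthetic session generator with known ground-truth modulation.

Emulates the structure of a head-fixed visual change-detection experiment:
four-epoch trials (noise -> spatial cue -> 2-patch delay -> orientation
change), inhomogeneous-Poisson spike trains with event-locked transients
and a sustained contralateral delay bias, cohort-specific lick patterns,
and 240 Hz eye traces with sparse saccades.  Every downstream analysis
stage can therefore be tested against amplitudes the generator wrote down.

Epoch durations are drawn uniformly from the task's time ranges
(noise 0.2-0.3 s, cue 0.36-1.55 s, 2-patch 0.84-3.6 s); the wheel-distance
mechanism that produced those ranges in the experiment is not modeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .types import (
    LAYERS,
    LEVELS,
    TILT_DEGREES,
    CohortSpec,
    EyeTrace,
    RateKernelParams,
    SessionRecord,
    TrialEvents,
    UnitRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EPOCH_RANGES",
    "DEFAULT_GAIN_TABLE",
    "SessionData",
    "as_rng",
    "simulate_trial_timeline",
    "transient_kernel",
    "kernel_area",
    "event_locked_rate",
    "session_rate",
    "sample_inhomogeneous_poisson",
    "simulate_unit_spikes",
    "simulate_licks",
    "lick_intensity",
    "simulate_eye_trace",
    "make_saccade_schedule",
    "simulate_session",
    "simulate_cohort",
]

#: Uniform draw ranges for epoch durations, seconds.
EPOCH_RANGES = {"noise": (0.2, 0.3), "cue": (0.36, 1.55), "twopatch": (0.84, 3.6)}

#: Default level x layer gains applied to the kernel amplitudes.  These are
#: the generator's *synthetic ground truth*, chosen to encode the qualitative
#: pattern under study (deep-layer cue/change/delay modulation absent when
#: naive, growing with training; superficial visual responses present
#: throughout and growing moderately).  They are not estimates of any
#: recorded dataset.
DEFAULT_GAIN_TABLE = {
    ("naive", "superficial"): {"cue": 1.0, "change": 0.4, "delay": 0.05},
    ("intermediate", "superficial"): {"cue": 1.5, "change": 0.7, "delay": 0.05},
    ("expert", "superficial"): {"cue": 2.0, "change": 1.0, "delay": 0.10},
    ("naive", "deep"): {"cue": 0.0, "change": 0.1, "delay": 0.0},
    ("intermediate", "deep"): {"cue": 0.6, "change": 0.6, "delay": 0.4},
    ("expert", "deep"): {"cue": 1.0, "change": 1.0, "delay": 0.8},
}

#: Lick-intensity parameters per archetype (rates in Hz, times in s).
#: Peak rates are calibrated so the scored behavior lands at the study's
#: scale: near-zero nominal hit rate for passive viewing, ~2/3 for the
#: reward-association cohort, ~0.8 with a plausible false-alarm rate for
#: the change-detection cohort.  The reactive burst fires only when a
#: change actually occurs; on no-change catch trials a much weaker burst
#: (``fa_scale``) produces occasional false alarms.
LICK_ARCHETYPES = {
    # passive viewing: burst at trial start, exponential decay
    "early_peak": {"floor_hz": 0.05, "peak_hz": 4.0, "tau_s": 0.8},
    # stimulus-reward association: linear climb through the trial
    "ramping": {"floor_hz": 0.2, "peak_hz": 2.2},
    # change detection: near-silent until the change, then a reactive burst
    # centered at the expert reaction-time scale (~450 ms)
    "change_locked": {"floor_hz": 0.01, "peak_hz": 9.5, "center_s": 0.45,
                      "sd_s": 0.09, "fa_scale": 0.12},
}

#: Spontaneous saccade rate per performance level, Hz.  Naive sessions have
#: the highest rate, mirroring the direction of the behavioral control
#: analysis (saccades were most frequent in naive sessions).
SACCADE_RATE_HZ = {"naive": 0.25, "intermediate": 0.15, "expert": 0.10}


def as_rng(seed) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# trial timelines
# ---------------------------------------------------------------------------

def simulate_trial_timeline(
    spec: CohortSpec,
    rng_seed,
    *,
    session_id: str = "s0",
    iti_range_s: tuple = (1.5, 2.5),
    block_len: int = 10,
    post_change_s: float = 1.0,
    t_start: float = 0.0,
    probe_fraction: float = 0.0,
) -> list[TrialEvents]:
    """Draw a full session of trial-event times.

    Cue sides alternate in interleaved blocks of ``block_len`` trials.
    Intermediate-cohort trials are all change trials; for the other cohorts
    a random half of the trials are no-change catch trials (the change-epoch
    onset is still recorded, with no change occurring there).  A
    ``probe_fraction`` of change trials can be marked as cue-omitted probe
    trials, used to measure the behavioral benefit of the spatial cue.
    """
    if spec.trials_per_session < 1:
        raise ValueError("trials_per_session must be >= 1")
    rng = as_rng(rng_seed)
    n = spec.trials_per_session

    # interleaved blocks of contra / ipsi cues, random starting side
    sides = []
    side = rng.integers(0, 2)
    while len(sides) < n:
        sides.extend([("contra", "ipsi")[side]] * block_len)
        side = 1 - side
    sides = sides[:n]

    if spec.has_no_change_trials:
        is_change = np.zeros(n, dtype=bool)
        is_change[: (n + 1) // 2] = True
        rng.shuffle(is_change)
    else:
        is_change = np.ones(n, dtype=bool)

    is_probe = rng.random(n) < probe_fraction if probe_fraction > 0 else np.zeros(n, bool)
    tilts = rng.choice(TILT_DEGREES, size=n)
    d_noise = rng.uniform(*EPOCH_RANGES["noise"], size=n)
    d_cue = rng.uniform(*EPOCH_RANGES["cue"], size=n)
    d_two = rng.uniform(*EPOCH_RANGES["twopatch"], size=n)
    itis = rng.uniform(*iti_range_s, size=n)

    trials = []
    t = t_start
    for i in range(n):
        t0 = t + itis[i]
        t_cue = t0 + d_noise[i]
        t_two = t_cue + d_cue[i]
        t_chg = t_two + d_two[i]
        trials.append(
            TrialEvents(
                session_id=session_id,
                trial_id=i,
                cue_side=sides[i],
                t_noise_on=t0,
                t_cue_on=t_cue,
                t_twopatch_on=t_two,
                t_change_on=t_chg,
                tilt_deg=int(tilts[i]),
                is_change=bool(is_change[i]),
                is_probe=bool(is_probe[i] and is_change[i]),
            )
        )
        t = t_chg + post_change_s
    return trials


# ---------------------------------------------------------------------------
# firing-rate model
# ---------------------------------------------------------------------------

def transient_kernel(t_rel_s, params: RateKernelParams):
    """Peak-normalized causal difference-of-exponentials kernel.

    Zero for ``t_rel < latency``; rises with time constant ``rise_ms`` and
    decays with ``decay_ms``; the maximum value is exactly 1, so an
    amplitude multiplying this kernel is a peak rate in Hz.
    """
    t = np.asarray(t_rel_s, dtype=float) - params.latency_ms / 1000.0
    tr = params.rise_ms / 1000.0
    td = params.decay_ms / 1000.0
    raw = np.where(t > 0, np.exp(-np.maximum(t, 0.0) / td) - np.exp(-np.maximum(t, 0.0) / tr), 0.0)
    # analytic peak of exp(-t/td) - exp(-t/tr)
    t_pk = np.log(td / tr) * tr * td / (td - tr)
    peak = np.exp(-t_pk / td) - np.exp(-t_pk / tr)
    return raw / peak


def kernel_area(amp_hz: float, params: RateKernelParams) -> float:
    """Closed-form integral of ``amp * transient_kernel`` over [0, inf), in spikes."""
    tr = params.rise_ms / 1000.0
    td = params.decay_ms / 1000.0
    t_pk = np.log(td / tr) * tr * td / (td - tr)
    peak = np.exp(-t_pk / td) - np.exp(-t_pk / tr)
    return amp_hz * (td - tr) / peak


def event_locked_rate(
    t,
    trial: TrialEvents,
    params: RateKernelParams,
    level: str,
    layer: str,
    gain_table: dict | None = None,
):
    """Instantaneous firing rate (Hz) at absolute times ``t`` for one trial.

    rate = baseline + cue transient + change transient (change trials only)
    + sustained contralateral bias during the 2-patch delay epoch.  Transient
    amplitudes are scaled by the level x layer gain table.  Negative values
    (impossible with non-negative amplitudes, possible with user-supplied
    negative gains) are clamped to zero and logged.
    """
    if level not in LEVELS or layer not in LAYERS:
        raise ValueError(f"unknown level/layer {level!r}/{layer!r}")
    gains = (gain_table or DEFAULT_GAIN_TABLE)[(level, layer)]
    t = np.asarray(t, dtype=float)
    r = np.full(t.shape, params.baseline_hz)
    r += gains["cue"] * params.cue_amp_hz * transient_kernel(t - trial.t_cue_on, params)
    if trial.is_change:
        r += gains["change"] * params.change_amp_hz * transient_kernel(
            t - trial.t_change_on, params
        )
    if trial.cue_side == "contra":
        in_delay = (t >= trial.t_twopatch_on) & (t < trial.t_change_on)
        r += gains["delay"] * params.delay_contra_bias_hz * in_delay
    if np.any(r < 0):
        logger.warning("negative rate clamped to 0 (check gain table signs)")
        r = np.maximum(r, 0.0)
    return r


def session_rate(
    t,
    trials: list[TrialEvents],
    params: RateKernelParams,
    level: str,
    layer: str,
    gain_table: dict | None = None,
):
    """Vectorized session-long rate: each time is attributed to the trial
    whose noise onset most recently precedes it (baseline only between
    trials)."""
    gains = (gain_table or DEFAULT_GAIN_TABLE)[(level, layer)]
    t = np.asarray(t, dtype=float)
    starts = np.array([tr.t_noise_on for tr in trials])
    t_cue = np.array([tr.t_cue_on for tr in trials])
    t_two = np.array([tr.t_twopatch_on for tr in trials])
    t_chg = np.array([tr.t_change_on for tr in trials])
    chg = np.array([tr.is_change for tr in trials])
    contra = np.array([tr.cue_side == "contra" for tr in trials])

    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(trials) - 1)
    r = np.full(t.shape, params.baseline_hz)
    r += gains["cue"] * params.cue_amp_hz * transient_kernel(t - t_cue[idx], params)
    r += (
        gains["change"]
        * params.change_amp_hz
        * chg[idx]
        * transient_kernel(t - t_chg[idx], params)
    )
    in_delay = (t >= t_two[idx]) & (t < t_chg[idx])
    r += gains["delay"] * params.delay_contra_bias_hz * (contra[idx] & in_delay)
    return np.maximum(r, 0.0)


def sample_inhomogeneous_poisson(rate_fn, t0: float, t1: float, rate_max: float, rng_seed):
    """Inhomogeneous-Poisson spike times on [t0, t1) by thinning.

    ``rate_fn`` must be bounded above by ``rate_max`` on the interval
    (candidates where it is not are a programming error and raise).
    Returns a sorted array; empty when ``t1 <= t0``.
    """
    if t1 <= t0 or rate_max <= 0:
        return np.empty(0)
    rng = as_rng(rng_seed)
    n_cand = rng.poisson(rate_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, size=n_cand))
    if n_cand == 0:
        return cand
    rates = np.asarray(rate_fn(cand), dtype=float)
    if np.any(rates > rate_max * (1 + 1e-9)):
        raise ValueError("rate_fn exceeds the stated ceiling rate_max")
    keep = rng.uniform(0.0, rate_max, size=n_cand) < rates
    return cand[keep]


def simulate_unit_spikes(
    trials: list[TrialEvents],
    params: RateKernelParams,
    level: str,
    layer: str,
    rng_seed,
    gain_table: dict | None = None,
    *,
    pad_s: float = 1.0,
):
    """Spike train for one unit over a whole session timeline."""
    gains = (gain_table or DEFAULT_GAIN_TABLE)[(level, layer)]
    ceiling = (
        params.baseline_hz
        + gains["cue"] * params.cue_amp_hz
        + gains["change"] * params.change_amp_hz
        + gains["delay"] * params.delay_contra_bias_hz
    )
    t0 = trials[0].t_noise_on - pad_s
    t1 = trials[-1].t_change_on + pad_s

    def rate_fn(t):
        return session_rate(t, trials, params, level, layer, gain_table)

    return sample_inhomogeneous_poisson(rate_fn, t0, t1, ceiling, rng_seed)


# ---------------------------------------------------------------------------
# licks
# ---------------------------------------------------------------------------

def lick_intensity(t, archetype: str, trial: TrialEvents, *, scale: float = 1.0):
    """Time-varying lick intensity (Hz) at absolute times ``t`` for one trial."""
    if archetype not in LICK_ARCHETYPES:
        raise ValueError(f"unknown lick archetype {archetype!r}")
    p = LICK_ARCHETYPES[archetype]
    t = np.asarray(t, dtype=float)
    if archetype == "early_peak":
        rel = t - trial.t_noise_on
        r = p["floor_hz"] + p["peak_hz"] * np.exp(-np.maximum(rel, 0.0) / p["tau_s"])
    elif archetype == "ramping":
        frac = np.clip((t - trial.t_noise_on) / (trial.t_change_on - trial.t_noise_on), 0, 1)
        r = p["floor_hz"] + p["peak_hz"] * frac
    else:  # change_locked
        rel = t - trial.t_change_on
        burst = p["peak_hz"] if trial.is_change else p["fa_scale"] * p["peak_hz"]
        center = p["center_s"]
        if trial.is_probe:
            # cue-omitted probe: detection is weaker and slightly slower
            burst = 0.7 * burst
            center = center + 0.012
        r = p["floor_hz"] + burst * np.exp(-0.5 * ((rel - center) / p["sd_s"]) ** 2)
    return scale * r


def simulate_licks(
    archetype: str,
    trial: TrialEvents,
    rng_seed,
    *,
    scale: float = 1.0,
    post_change_s: float = 1.0,
):
    """Lick times for one trial, drawn from the archetype intensity."""
    if archetype not in LICK_ARCHETYPES:
        raise ValueError(f"unknown lick archetype {archetype!r}")
    p = LICK_ARCHETYPES[archetype]
    ceiling = scale * (p["floor_hz"] + p["peak_hz"])
    if ceiling == 0:
        return np.empty(0)
    return sample_inhomogeneous_poisson(
        lambda t: lick_intensity(t, archetype, trial, scale=scale),
        trial.t_noise_on,
        trial.t_change_on + post_change_s,
        ceiling,
        rng_seed,
    )


# ---------------------------------------------------------------------------
# eye traces
# ---------------------------------------------------------------------------

def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def simulate_eye_trace(
    duration_s: float,
    saccade_schedule: list,
    noise_sd_deg: float,
    rng_seed,
    *,
    session_id: str = "s0",
    sample_rate_hz: float = 240.0,
) -> EyeTrace:
    """240 Hz eye trace with scheduled sigmoidal saccades and Gaussian noise.

    Each schedule entry is ``(onset_s, amplitude_deg, duration_ms)``; the
    displacement follows a smoothstep profile (exact plateaus before onset
    and after offset), in a random direction per saccade.  Overlapping or
    out-of-range saccades are rejected.
    """
    sched = sorted(saccade_schedule)
    last_end = -np.inf
    for onset, amp, dur_ms in sched:
        end = onset + dur_ms / 1000.0
        if onset < 0 or end > duration_s:
            raise ValueError("scheduled saccade outside [0, duration]")
        if onset < last_end:
            raise ValueError("scheduled saccades overlap")
        last_end = end
    rng = as_rng(rng_seed)
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    x = np.zeros(n)
    y = np.zeros(n)
    for onset, amp, dur_ms in sched:
        phi = rng.uniform(0, 2 * np.pi)
        s = _smoothstep((t - onset) / (dur_ms / 1000.0))
        x += amp * np.cos(phi) * s
        y += amp * np.sin(phi) * s
    if noise_sd_deg > 0:
        x += rng.normal(0.0, noise_sd_deg, size=n)
        y += rng.normal(0.0, noise_sd_deg, size=n)
    return EyeTrace(
        session_id=session_id,
        sample_rate_hz=sample_rate_hz,
        t=t,
        x_deg=x,
        y_deg=y,
        pupil=np.ones(n),
    )


def make_saccade_schedule(
    duration_s: float,
    rate_hz: float,
    rng_seed,
    *,
    amp_range_deg: tuple = (2.5, 8.0),
    dur_range_ms: tuple = (20.0, 60.0),
) -> list:
    """Homogeneous-Poisson saccade schedule; overlapping draws are dropped."""
    rng = as_rng(rng_seed)
    n = rng.poisson(rate_hz * duration_s)
    onsets = np.sort(rng.uniform(0.0, duration_s, size=n))
    sched = []
    last_end = -np.inf
    for onset in onsets:
        amp = rng.uniform(*amp_range_deg)
        dur = rng.uniform(*dur_range_ms)
        if onset < last_end or onset + dur / 1000.0 > duration_s:
            continue
        sched.append((float(onset), float(amp), float(dur)))
        last_end = onset + dur / 1000.0
    return sched


# ---------------------------------------------------------------------------
# full sessions
# ---------------------------------------------------------------------------

_COHORT_OF_LEVEL = {
    "naive": "passive",
    "intermediate": "stim_reward",
    "expert": "change_detect",
}

@dataclass
class SessionData:
    """One fully simulated session plus its generator ground truth."""

    record: SessionRecord
    level: str
    units: list = field(default_factory=list)
    eye: EyeTrace | None = None
    ground_truth: dict = field(default_factory=dict)

    @property
    def trials(self):
        return self.record.trials


def _sample_unit_params(base: RateKernelParams, rng) -> RateKernelParams:
    """Per-unit heterogeneity: lognormal jitter on baseline and amplitudes."""
    return replace(
        base,
        baseline_hz=base.baseline_hz * rng.lognormal(0.0, 0.4),
        cue_amp_hz=base.cue_amp_hz * rng.lognormal(0.0, 0.3),
        change_amp_hz=base.change_amp_hz * rng.lognormal(0.0, 0.3),
        delay_contra_bias_hz=base.delay_contra_bias_hz * rng.lognormal(0.0, 0.3),
    )


def simulate_session(
    spec: CohortSpec,
    seed,
    *,
    session_id: str = "s0",
    base_params: RateKernelParams | None = None,
    gain_table: dict | None = None,
    with_eye: bool = True,
    eye_noise_sd_deg: float = 0.1,
    probe_fraction: float = 0.0,
) -> SessionData:
    """Simulate one complete session: timeline, spikes, licks, eye trace.

    The master seed is expanded into independent per-stream seeds
    (timeline / units / licks / eye), so each stream is reproducible on
    its own.  Trial outcomes are scored from the generated licks with the
    behavioral rules of the cohort's task.
    """
    from . import behavior  # deferred: behavior depends only on types

    base_params = base_params or RateKernelParams()
    gain_table = gain_table or DEFAULT_GAIN_TABLE
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_timeline, s_units, s_licks, s_eye = ss.spawn(4)

    level = spec.level
    trials = simulate_trial_timeline(
        spec, np.random.default_rng(s_timeline),
        session_id=session_id, probe_fraction=probe_fraction,
    )

    # licks + behavioral scoring
    lick_rng = np.random.default_rng(s_licks)
    licks_by_trial = {}
    for tr in trials:
        licks_by_trial[tr.trial_id] = simulate_licks(spec.lick_archetype, tr, lick_rng)
        tr.outcome = behavior.score_trial(
            tr,
            licks_by_trial[tr.trial_id],
            abort_on_anticipatory=(level == "expert"),
        )

    # units
    unit_rng = np.random.default_rng(s_units)
    n_units = spec.units_per_session
    n_sup = int(round(spec.superficial_fraction * n_units))
    layers = np.array(["superficial"] * n_sup + ["deep"] * (n_units - n_sup))
    unit_rng.shuffle(layers)
    units, ground_truth = [], {}
    unit_seeds = s_units.spawn(n_units)
    for k in range(n_units):
        layer = str(layers[k])
        params = _sample_unit_params(base_params, unit_rng)
        depth = (
            float(unit_rng.uniform(-400, 0))
            if layer == "superficial"
            else float(unit_rng.uniform(0, 1600))
        )
        uid = f"{session_id}_u{k:03d}"
        spikes = simulate_unit_spikes(
            trials, params, level, layer, np.random.default_rng(unit_seeds[k]), gain_table
        )
        units.append(
            UnitRecord(unit_id=uid, session_id=session_id, layer=layer, depth_um=depth, spike_times=spikes)
        )
        g = gain_table[(level, layer)]
        ground_truth[uid] = {
            "layer": layer,
            "baseline_hz": params.baseline_hz,
            "cue_amp_hz": g["cue"] * params.cue_amp_hz,
            "change_amp_hz": g["change"] * params.change_amp_hz,
            "delay_contra_bias_hz": g["delay"] * params.delay_contra_bias_hz,
        }

    eye = None
    if with_eye:
        duration = trials[-1].t_change_on + 1.5
        eye_rng = np.random.default_rng(s_eye)
        sched = make_saccade_schedule(duration, SACCADE_RATE_HZ[level], eye_rng)
        eye = simulate_eye_trace(
            duration, sched, eye_noise_sd_deg, eye_rng, session_id=session_id
        )

    record = SessionRecord(
        session_id=session_id,
        cohort=_COHORT_OF_LEVEL[level],
        trials=trials,
        licks_by_trial=licks_by_trial,
        assigned_level="naive" if level == "naive" else "",
    )
    return SessionData(record=record, level=level, units=units, eye=eye, ground_truth=ground_truth)


def simulate_cohort(
    spec: CohortSpec,
    seed,
    *,
    session_prefix: str | None = None,
    **session_kwargs,
) -> list[SessionData]:
    """Simulate all sessions of a cohort with independent per-session seeds."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    prefix = session_prefix or f"{spec.level[:3]}"
    children = ss.spawn(spec.n_sessions)
    return [
        simulate_session(spec, children[i], session_id=f"{prefix}{i:03d}", **session_kwargs)
        for i in range(spec.n_sessions)
    ]
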