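"""Shared domain types for the superior-colliculus attention-learning pipeline.

Conventions used throughout the package:

* all event and spike times are **seconds from session start**;
* all analysis windows are **milliseconds relative to an alignment event**
  and half-open, ``[a, b)``;
* eye position is in degrees of visual angle, sampled uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "LEVELS",
    "LAYERS",
    "TILT_DEGREES",
    "CohortSpec",
    "TrialEvents",
    "RateKernelParams",
    "EyeTrace",
    "UnitRecord",
    "AurocResult",
    "SaccadeEvent",
    "SessionRecord",
    "tilt_category",
]

#: Performance levels, ordered from least to most trained.
LEVELS = ("naive", "intermediate", "expert")

#: Collicular layer groups: above vs below the stratum opticum.
LAYERS = ("superficial", "deep")

#: Orientation-change amplitudes used in the task, degrees.
TILT_DEGREES = (9, 12, 15, 20, 30)

_TILT_CATEGORY = {9: "small", 12: "small", 15: "medium", 20: "medium", 30: "large"}


def tilt_category(tilt_deg: float) -> str:
    """Map an orientation-change amplitude to its size category.

    Large = 30 deg, medium = 15 or 20 deg, small = 9 or 12 deg.
    """
    try:
        return _TILT_CATEGORY[int(tilt_deg)]
    except KeyError:
        raise ValueError(
            f"tilt_deg must be one of {TILT_DEGREES}, got {tilt_deg!r}"
        ) from None


@dataclass
class CohortSpec:
    """Design of one training cohort of synthetic sessions.

    ``lick_archetype`` names the lick-intensity shape the cohort produces:
    ``early_peak`` (passive viewing — licking concentrated at trial start),
    ``ramping`` (stimulus–reward association — licking climbs through the
    trial), or ``change_locked`` (change detection — licking starts abruptly
    after the orientation change).
    """

    level: str
    n_sessions: int
    trials_per_session: int
    has_no_change_trials: bool
    lick_archetype: str
    units_per_session: int = 8
    superficial_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        if self.trials_per_session < 1:
            raise ValueError("trials_per_session must be >= 1")
        if self.lick_archetype not in ("early_peak", "ramping", "change_locked"):
            raise ValueError(f"unknown lick_archetype {self.lick_archetype!r}")
        if self.level == "intermediate" and self.has_no_change_trials:
            # The stimulus–reward association cohort was never shown
            # no-change catch trials.
            raise ValueError("intermediate cohort cannot have no-change trials")


@dataclass
class TrialEvents:
    """Epoch onsets and metadata for a single trial.

    The four epochs are noise -> cue -> 2-patch -> change; onsets are
    strictly ordered.  ``t_change_on`` marks the onset of the fourth epoch
    whether or not an orientation change actually occurs there
    (``is_change``).
    """

    session_id: str
    trial_id: int
    cue_side: str  # "contra" | "ipsi"
    t_noise_on: float
    t_cue_on: float
    t_twopatch_on: float
    t_change_on: float
    tilt_deg: int
    is_change: bool
    outcome: str = "unscored"
    #: cue-omitted probe trial (synthetic-session option; in-memory only,
    #: used to quantify the behavioral cueing benefit)
    is_probe: bool = False

    def __post_init__(self) -> None:
        if self.cue_side not in ("contra", "ipsi"):
            raise ValueError(f"cue_side must be contra|ipsi, got {self.cue_side!r}")
        if not (self.t_noise_on < self.t_cue_on < self.t_twopatch_on < self.t_change_on):
            raise ValueError(
                f"epoch onsets must be strictly ordered, got "
                f"({self.t_noise_on}, {self.t_cue_on}, {self.t_twopatch_on}, "
                f"{self.t_change_on})"
            )

    @property
    def tilt_category(self) -> str:
        return tilt_category(self.tilt_deg)


@dataclass
class RateKernelParams:
    """Parameters of the event-locked firing-rate model for one unit.

    The rate is a baseline plus causal transients locked to cue and change
    onset (difference-of-exponentials kernels, peak-normalized so the
    ``*_amp_hz`` values are peak rates) plus a sustained contralateral bias
    during the delay (2-patch) epoch.
    """

    baseline_hz: float = 8.0
    cue_amp_hz: float = 20.0
    change_amp_hz: float = 20.0
    delay_contra_bias_hz: float = 3.0
    latency_ms: float = 40.0
    rise_ms: float = 10.0
    decay_ms: float = 60.0

    def __post_init__(self) -> None:
        for name in ("baseline_hz", "cue_amp_hz", "change_amp_hz", "delay_contra_bias_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.latency_ms < 0:
            raise ValueError("latency_ms must be >= 0")
        if self.rise_ms <= 0 or self.decay_ms <= 0 or self.rise_ms >= self.decay_ms:
            raise ValueError("need 0 < rise_ms < decay_ms")


@dataclass
class EyeTrace:
    """Uniformly sampled 2-D eye-position trace for one session."""

    session_id: str
    sample_rate_hz: float
    t: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    pupil: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x_deg = np.asarray(self.x_deg, dtype=float)
        self.y_deg = np.asarray(self.y_deg, dtype=float)
        if not (len(self.t) == len(self.x_deg) == len(self.y_deg)):
            raise ValueError("t, x_deg, y_deg must have equal length")
        if not (np.isfinite(self.x_deg).all() and np.isfinite(self.y_deg).all()):
            raise ValueError("eye trace contains non-finite values")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / self.sample_rate_hz, rtol=1e-6, atol=1e-9):
                raise ValueError("samples must be uniformly spaced at 1/sample_rate_hz")


@dataclass
class UnitRecord:
    """One recorded (or simulated) unit with sorted spike times."""

    unit_id: str
    session_id: str
    layer: str  # "superficial" | "deep"
    depth_um: float
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if len(self.spike_times) > 1 and np.any(np.diff(self.spike_times) < 0):
            raise ValueError(f"spike_times of unit {self.unit_id} are not sorted")


@dataclass
class AurocResult:
    """Per-unit discriminability for one epoch contrast.

    ``significance`` follows the bootstrap-CI rule: ``positive`` iff the
    95% CI lower bound exceeds 0.5, ``negative`` iff the upper bound is
    below 0.5, ``ns`` otherwise.
    """

    unit_id: str
    epoch: str
    auroc: float
    ci_lo: float
    ci_hi: float
    significance: str
    n_signal_trials: int
    n_noise_trials: int
    session_id: str = ""
    layer: str = ""
    level: str = ""
    tilt_category: str = ""


@dataclass
class SaccadeEvent:
    """One detected saccade: onset, duration, net displacement, peak speed."""

    session_id: str
    onset_s: float
    duration_ms: float
    amplitude_deg: float
    peak_speed_dps: float


@dataclass
class SessionRecord:
    """One session: cohort identity, trials, licks, and assigned level.

    Passive-cohort sessions are always assigned ``naive`` and bypass the
    lick-pattern classifier; other sessions receive ``intermediate`` or
    ``expert`` from the classifier.
    """

    session_id: str
    cohort: str  # "passive" | "stim_reward" | "change_detect"
    trials: list = field(default_factory=list)
    licks_by_trial: dict = field(default_factory=dict)
    assigned_level: str = ""

    def __post_init__(self) -> None:
        if self.cohort not in ("passive", "stim_reward", "change_detect"):
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.cohort == "passive" and self.assigned_level not in ("", "naive"):
            raise ValueError("passive-cohort sessions are always naive")
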