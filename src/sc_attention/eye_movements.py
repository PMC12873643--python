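"""Saccade detection and event-aligned saccade statistics.

Saccades are detected from the 2-D eye speed (central differences, with a
3-sample median prefilter against tracker noise): candidate epochs are
maximal runs of samples faster than 50 deg/s, extended outward while the
speed stays above a low hysteresis threshold, and kept only when they last
longer than 15 ms and displace the eye by more than 2 deg (strict
inequalities at all three thresholds).  Amplitude is the straight-line
displacement between the epoch endpoints, not the path length.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import medfilt

from . import spike_analysis as sa
from .types import EyeTrace, SaccadeEvent, TrialEvents

logger = logging.getLogger(__name__)

__all__ = [
    "SPEED_THRESHOLD_DPS",
    "AMPLITUDE_THRESHOLD_DEG",
    "DURATION_THRESHOLD_MS",
    "detect_saccades",
    "saccade_probability_timecourse",
    "interval_saccade_probability",
    "saccade_free_mask",
]

SPEED_THRESHOLD_DPS = 50.0
AMPLITUDE_THRESHOLD_DEG = 2.0
DURATION_THRESHOLD_MS = 15.0


def detect_saccades(
    trace: EyeTrace,
    *,
    speed_threshold_dps: float = SPEED_THRESHOLD_DPS,
    amplitude_threshold_deg: float = AMPLITUDE_THRESHOLD_DEG,
    duration_threshold_ms: float = DURATION_THRESHOLD_MS,
    low_speed_threshold_dps: float = 10.0,
    median_filter: bool = True,
) -> list[SaccadeEvent]:
    """Detect saccades in a uniformly sampled eye trace.

    The low hysteresis threshold recovers the slow head and tail of each
    movement so the measured displacement spans the full excursion rather
    than only its fastest core.
    """
    n = len(trace.t)
    if n < 3:
        raise ValueError("trace must have at least 3 samples")
    x, y = trace.x_deg, trace.y_deg
    if median_filter:
        x = medfilt(x, 3)
        y = medfilt(y, 3)
    dt = 1.0 / trace.sample_rate_hz
    vx = np.gradient(x, dt)
    vy = np.gradient(y, dt)
    speed = np.hypot(vx, vy)

    fast = speed > speed_threshold_dps
    if not fast.any():
        return []
    # maximal runs of suprathreshold samples
    edges = np.diff(fast.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0])
    if fast[0]:
        starts.insert(0, 0)
    if fast[-1]:
        ends.append(n - 1)

    # hysteresis extension, then merge epochs that touch or overlap
    slow_ok = speed > low_speed_threshold_dps
    epochs = []
    for i0, i1 in zip(starts, ends):
        while i0 > 0 and slow_ok[i0 - 1]:
            i0 -= 1
        while i1 < n - 1 and slow_ok[i1 + 1]:
            i1 += 1
        if epochs and i0 <= epochs[-1][1] + 1:
            epochs[-1][1] = max(epochs[-1][1], i1)
        else:
            epochs.append([i0, i1])

    events: list[SaccadeEvent] = []
    for i0, i1 in epochs:
        ev = _make_event(trace, x, y, speed, i0, i1, dt)
        if (
            ev.duration_ms > duration_threshold_ms
            and ev.amplitude_deg > amplitude_threshold_deg
        ):
            events.append(ev)
    return events


def _make_event(trace, x, y, speed, i0, i1, dt) -> SaccadeEvent:
    # displacement measured one sample outside the epoch on each side:
    # the epoch endpoints are the last suprathreshold samples, so the
    # flanking samples sit essentially on the pre/post plateaus
    j0 = max(i0 - 1, 0)
    j1 = min(i1 + 1, len(x) - 1)
    return SaccadeEvent(
        session_id=trace.session_id,
        onset_s=float(trace.t[i0]),
        duration_ms=float((i1 - i0) * dt * 1000.0),
        amplitude_deg=float(np.hypot(x[j1] - x[j0], y[j1] - y[j0])),
        peak_speed_dps=float(speed[i0 : i1 + 1].max()),
    )


def saccade_probability_timecourse(
    saccades: list[SaccadeEvent],
    trials: list[TrialEvents],
    align_event: str,
    range_ms,
    bin_ms: float = 20.0,
):
    """Per-bin fraction of trials containing at least one saccade onset.

    A saccade belongs to the bin containing its onset.  Returns
    ``(bin_starts_ms, probability_per_bin)``.
    """
    if not trials:
        raise ValueError("need >= 1 trial")
    a, b = range_ms
    n_bins = int(round((b - a) / bin_ms))
    if abs((b - a) / bin_ms - n_bins) > 1e-9 or n_bins < 1:
        raise ValueError("bin_ms must evenly divide the range")
    times, kept = sa.event_times(trials, align_event)
    onsets = np.sort([s.onset_s for s in saccades])
    edges = a + bin_ms * np.arange(n_bins + 1)
    hit = np.zeros(n_bins)
    for t0 in times:
        rel = (onsets - t0) * 1000.0
        counts = np.histogram(rel[(rel >= a) & (rel < b)], bins=edges)[0]
        hit += counts > 0
    return edges[:-1], hit / len(times)


def interval_saccade_probability(
    saccades: list[SaccadeEvent],
    event_times_s,
    window_ms,
) -> float:
    """Fraction of trials with >= 1 saccade onset inside ``window_ms``
    around the event (the baseline/response interval summaries)."""
    onsets = np.sort([s.onset_s for s in saccades])
    counts = sa.counts_for_events(onsets, np.asarray(event_times_s, dtype=float), window_ms)
    return float(np.mean(counts > 0))


def saccade_free_mask(
    saccades: list[SaccadeEvent],
    trials: list[TrialEvents],
    epoch_windows: list,
) -> np.ndarray:
    """Per-trial flag: True iff no saccade onset falls in any of the
    epoch's analysis windows.

    ``epoch_windows`` is a list of ``(event_name, (a_ms, b_ms))`` pairs,
    e.g. the baseline and response windows of one epoch contrast.  Trials
    lacking an event (no-change trials for change alignment) ignore that
    window.
    """
    onsets = np.sort([s.onset_s for s in saccades])
    mask = np.ones(len(trials), dtype=bool)
    for i, tr in enumerate(trials):
        for event, window in epoch_windows:
            if event == "change_on" and not tr.is_change:
                continue
            t0 = getattr(tr, sa.EVENT_FIELDS[event])
            if sa.count_in_window(onsets, t0, window) > 0:
                mask[i] = False
                break
    return mask
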