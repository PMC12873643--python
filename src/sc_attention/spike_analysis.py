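"""Event-aligned spike counting, PSTHs, and windowed rate extraction.

All windows are half-open ``[a, b)`` in ms relative to an alignment event,
so contiguous 20 ms bins partition a range with no double counting.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import TrialEvents, UnitRecord

logger = logging.getLogger(__name__)

__all__ = [
    "EVENT_FIELDS",
    "count_in_window",
    "counts_for_events",
    "rates_for_events",
    "event_times",
    "compute_psth",
    "zscore_response",
]

#: Alignment-event name -> TrialEvents attribute.
EVENT_FIELDS = {
    "noise_on": "t_noise_on",
    "cue_on": "t_cue_on",
    "twopatch_on": "t_twopatch_on",
    "change_on": "t_change_on",
}


def _check_sorted(spikes: np.ndarray) -> np.ndarray:
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size > 1 and np.any(np.diff(spikes) < 0):
        raise ValueError("spike times must be sorted")
    return spikes


def count_in_window(spikes, event_time: float, window_ms) -> int:
    """Number of spikes with event-relative time in ``[a, b)`` ms."""
    a, b = window_ms
    if not a < b:
        raise ValueError(f"window must satisfy a < b, got {window_ms}")
    spikes = _check_sorted(spikes)
    lo = event_time + a / 1000.0
    hi = event_time + b / 1000.0
    return int(np.searchsorted(spikes, hi, "left") - np.searchsorted(spikes, lo, "left"))


def counts_for_events(spikes, events, window_ms) -> np.ndarray:
    """Vectorized ``count_in_window`` over many alignment times."""
    a, b = window_ms
    if not a < b:
        raise ValueError(f"window must satisfy a < b, got {window_ms}")
    spikes = _check_sorted(spikes)
    events = np.asarray(events, dtype=float)
    lo = np.searchsorted(spikes, events + a / 1000.0, "left")
    hi = np.searchsorted(spikes, events + b / 1000.0, "left")
    return (hi - lo).astype(int)


def rates_for_events(spikes, events, window_ms) -> np.ndarray:
    """Firing rates (Hz) = counts / window duration, per alignment time."""
    a, b = window_ms
    return counts_for_events(spikes, events, window_ms) / ((b - a) / 1000.0)


def event_times(trials: list[TrialEvents], event: str, *, require_change: bool | None = None):
    """Alignment times for an event, skipping trials that lack it.

    ``change_on`` alignment skips no-change trials (logged); pass
    ``require_change=False`` to override.
    """
    if event not in EVENT_FIELDS:
        raise ValueError(f"unknown event {event!r}; expected one of {sorted(EVENT_FIELDS)}")
    if require_change is None:
        require_change = event == "change_on"
    kept = [tr for tr in trials if (tr.is_change or not require_change)]
    if len(kept) < len(trials):
        logger.debug("skipped %d trials lacking event %s", len(trials) - len(kept), event)
    return np.array([getattr(tr, EVENT_FIELDS[event]) for tr in kept]), kept


def compute_psth(
    unit: UnitRecord,
    trials: list[TrialEvents],
    event: str,
    range_ms,
    bin_ms: float = 20.0,
):
    """Trial-averaged firing rate in contiguous ``bin_ms`` bins.

    Bins are ``[k*bin_ms, (k+1)*bin_ms)`` anchored at 0; ``bin_ms`` must
    evenly divide the range.  Returns ``(bin_starts_ms, mean_rate_hz)``.
    """
    a, b = range_ms
    n_bins = (b - a) / bin_ms
    if abs(n_bins - round(n_bins)) > 1e-9 or n_bins < 1:
        raise ValueError("bin_ms must evenly divide the range")
    n_bins = int(round(n_bins))
    times, kept = event_times(trials, event)
    if len(kept) == 0:
        raise ValueError("no trials with the alignment event")
    edges = a + bin_ms * np.arange(n_bins + 1)
    # per-trial relative spike times, histogrammed on the shared edges
    counts = np.zeros(n_bins)
    spikes = _check_sorted(unit.spike_times)
    for t0 in times:
        rel = (spikes - t0) * 1000.0
        sel = rel[(rel >= a) & (rel < b)]
        counts += np.histogram(sel, bins=edges)[0]
    rate = counts / len(times) / (bin_ms / 1000.0)
    return edges[:-1], rate


def zscore_response(
    unit: UnitRecord,
    trials: list[TrialEvents],
    event: str,
    baseline_window_ms,
    response_window_ms,
) -> float:
    """z-scored response used for heat-map ordering:
    (mean response rate - mean baseline rate) / SD of baseline rates.

    With zero baseline SD the result is signed infinity (logged), to be
    ordered after all finite values.
    """
    times, kept = event_times(trials, event)
    if len(kept) < 2:
        raise ValueError("need >= 2 trials")
    base = rates_for_events(unit.spike_times, times, baseline_window_ms)
    resp = rates_for_events(unit.spike_times, times, response_window_ms)
    diff = resp.mean() - base.mean()
    sd = base.std(ddof=1)
    if sd == 0:
        logger.warning("zero baseline SD for unit %s; z is signed infinity", unit.unit_id)
        return float(np.sign(diff) * np.inf) if diff != 0 else 0.0
    return float(diff / sd)
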