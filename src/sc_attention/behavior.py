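"""Behavioral scoring: trial outcomes, hit rate, d', reaction times, and
cued-vs-probe session comparisons.

A change trial is a hit when the animal licks inside the response window
(300-800 ms after change onset).  On no-change trials a lick in the
equivalent window is a false alarm.  Under the change-detection task rules,
licking after the cue but before the response window opens aborts the trial
(anticipatory lick, timeout penalty).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import stats

from .types import TrialEvents

logger = logging.getLogger(__name__)

__all__ = [
    "RESPONSE_WINDOW_MS",
    "score_trial",
    "score_session",
    "dprime",
    "reaction_time_ms",
    "compare_cued_vs_probe",
]

#: Response window after change onset, ms, half-open.
RESPONSE_WINDOW_MS = (300.0, 800.0)


def score_trial(
    trial: TrialEvents,
    lick_times,
    *,
    abort_on_anticipatory: bool = False,
    response_window_ms: tuple = RESPONSE_WINDOW_MS,
) -> str:
    """Score one trial from its licks.

    Returns one of ``hit``, ``miss``, ``false_alarm``, ``correct_reject``,
    ``aborted``.  Anticipatory licks (between cue onset and the opening of
    the response window) abort the trial only when ``abort_on_anticipatory``
    is set — i.e. under the change-detection task's timeout rule.
    """
    licks = np.asarray(lick_times, dtype=float)
    if licks.size and (licks.min() < trial.t_noise_on - 60.0):
        raise ValueError("lick outside the session span")
    lo, hi = (w / 1000.0 for w in response_window_ms)
    if abort_on_anticipatory:
        anticipatory = (licks >= trial.t_cue_on) & (licks < trial.t_change_on + lo)
        if np.any(anticipatory):
            return "aborted"
    in_window = (licks >= trial.t_change_on + lo) & (licks < trial.t_change_on + hi)
    if trial.is_change:
        return "hit" if np.any(in_window) else "miss"
    return "false_alarm" if np.any(in_window) else "correct_reject"


def score_session(
    trials: list[TrialEvents],
    licks_by_trial: dict,
    *,
    abort_on_anticipatory: bool = False,
) -> dict:
    """Score every trial and summarize the session.

    ``hit_rate`` uses all change trials in the denominator (aborted ones
    included); ``false_alarm_rate`` is None when the session has no
    no-change trials, and d' is then undefined (None) as well.
    """
    outcomes = []
    for tr in trials:
        out = score_trial(
            tr,
            licks_by_trial.get(tr.trial_id, ()),
            abort_on_anticipatory=abort_on_anticipatory,
        )
        tr.outcome = out
        outcomes.append(out)
    outcomes = np.array(outcomes)
    n_change = sum(tr.is_change for tr in trials)
    n_nochange = len(trials) - n_change
    n_hit = int(np.sum(outcomes == "hit"))
    n_fa = int(np.sum(outcomes == "false_alarm"))
    hit_rate = n_hit / n_change if n_change else None
    fa_rate = n_fa / n_nochange if n_nochange else None
    d = (
        dprime(hit_rate, fa_rate, n_signal=n_change, n_noise=n_nochange)
        if (n_change and n_nochange)
        else None
    )
    rts = reaction_time_ms(trials, licks_by_trial)
    return {
        "n_trials": len(trials),
        "n_change": n_change,
        "n_nochange": n_nochange,
        "n_hit": n_hit,
        "n_false_alarm": n_fa,
        "n_aborted": int(np.sum(outcomes == "aborted")),
        "hit_rate": hit_rate,
        "false_alarm_rate": fa_rate,
        "dprime": d,
        "median_rt_ms": float(np.median(rts)) if len(rts) else None,
        "outcomes": outcomes,
    }


def dprime(
    hit_rate: float,
    false_alarm_rate: float,
    *,
    n_signal: int | None = None,
    n_noise: int | None = None,
) -> float:
    """Signal-detection sensitivity z(HR) - z(FAR).

    When trial counts are supplied, the log-linear correction is applied
    (add 0.5 to the hit/false-alarm counts and 1 to the denominators) so the
    value stays finite at rates of 0 or 1.  Without counts the raw rates are
    used and must lie strictly inside (0, 1).
    """
    for r, name in ((hit_rate, "hit_rate"), (false_alarm_rate, "false_alarm_rate")):
        if r is None or not (0.0 <= r <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {r!r}")
    if n_signal is not None and n_noise is not None:
        hr = (hit_rate * n_signal + 0.5) / (n_signal + 1)
        far = (false_alarm_rate * n_noise + 0.5) / (n_noise + 1)
    else:
        hr, far = hit_rate, false_alarm_rate
        if not (0 < hr < 1 and 0 < far < 1):
            raise ValueError("rates at 0 or 1 require trial counts for correction")
    return float(stats.norm.ppf(hr) - stats.norm.ppf(far))


def reaction_time_ms(
    trials: list[TrialEvents],
    licks_by_trial: dict,
    *,
    response_window_ms: tuple = RESPONSE_WINDOW_MS,
) -> np.ndarray:
    """First-lick latencies (ms after change onset) on hit trials."""
    lo, hi = (w / 1000.0 for w in response_window_ms)
    rts = []
    for tr in trials:
        if not tr.is_change or tr.outcome != "hit":
            continue
        licks = np.asarray(licks_by_trial.get(tr.trial_id, ()), dtype=float)
        rel = licks - tr.t_change_on
        in_win = rel[(rel >= lo) & (rel < hi)]
        if in_win.size:
            rts.append(in_win.min() * 1000.0)
    return np.asarray(rts)


def compare_cued_vs_probe(cued_values, probe_values) -> float:
    """Two-sided Wilcoxon signed-rank p for paired per-session metrics
    (e.g. hit rate on cued vs cue-omitted probe trials)."""
    cued = np.asarray(cued_values, dtype=float)
    probe = np.asarray(probe_values, dtype=float)
    if cued.shape != probe.shape or cued.size < 2:
        raise ValueError("need >= 2 paired session values")
    diffs = cued - probe
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    res = stats.wilcoxon(cued, probe, alternative="two-sided")
    return float(res.pvalue)
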