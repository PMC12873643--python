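"""Epoch-windowed AROC discriminability with bootstrap inference.

Three contrasts are computed per unit:

* ``cue_onset`` — response window [40, 140) ms after cue onset vs baseline
  [-100, 0) ms before it, on contralateral-cue change trials;
* ``delay_spatial`` — end-of-delay window [-200, 0) ms before change onset,
  contralateral-cue vs ipsilateral-cue change trials;
* ``change_onset`` — [40, 140) ms after change onset vs [-100, 0) before
  it, on contralateral-cue change trials, optionally stratified by
  orientation-change size category.

AROC is the probability that a randomly drawn signal-window count exceeds a
randomly drawn noise-window count, with ties given half credit — i.e. the
Mann-Whitney U statistic normalized by the number of pairs.  Per-unit 95%
CIs come from a percentile bootstrap (independent resampling of the two
trial sets, 1,000 replicates, 2.5/97.5 percentiles); a unit is significantly
positive when the CI lower bound exceeds 0.5 and negative when the upper
bound is below 0.5.  No-change trials are excluded from every contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import spike_analysis as sa
from .synthetic_data import as_rng
from .types import AurocResult, TrialEvents, UnitRecord

logger = logging.getLogger(__name__)

__all__ = [
    "WINDOWS_MS",
    "EpochSpec",
    "epoch_spec",
    "auroc",
    "bootstrap_auroc_ci",
    "significance_from_ci",
    "epoch_discriminability",
    "population_summary",
    "auroc_timecourse",
]

#: Analysis windows, ms relative to the alignment event, half-open.
WINDOWS_MS = {
    "cue_baseline": (-100.0, 0.0),
    "cue_response": (40.0, 140.0),
    "delay": (-200.0, 0.0),
    "change_baseline": (-100.0, 0.0),
    "change_response": (40.0, 140.0),
}

EPOCH_KINDS = ("cue_onset", "delay_spatial", "change_onset")


@dataclass(frozen=True)
class EpochSpec:
    """One of the three epoch contrasts, fully resolved to windows/filters."""

    kind: str
    signal_event: str
    signal_window_ms: tuple
    noise_event: str
    noise_window_ms: tuple
    contra_only: bool = True
    tilt_category: str | None = None  # change_onset only: small|medium|large|None


def epoch_spec(
    kind: str,
    *,
    tilt_category: str | None = None,
    contra_only: bool = True,
) -> EpochSpec:
    """Build the standard spec for one of the three epoch contrasts."""
    if kind == "cue_onset":
        return EpochSpec(kind, "cue_on", WINDOWS_MS["cue_response"],
                         "cue_on", WINDOWS_MS["cue_baseline"], contra_only)
    if kind == "delay_spatial":
        # signal = contra-cue trials, noise = ipsi-cue trials, same window
        return EpochSpec(kind, "change_on", WINDOWS_MS["delay"],
                         "change_on", WINDOWS_MS["delay"], contra_only)
    if kind == "change_onset":
        if tilt_category not in (None, "small", "medium", "large"):
            raise ValueError(f"bad tilt_category {tilt_category!r}")
        return EpochSpec(kind, "change_on", WINDOWS_MS["change_response"],
                         "change_on", WINDOWS_MS["change_baseline"], contra_only,
                         tilt_category)
    raise ValueError(f"unknown epoch kind {kind!r}; expected one of {EPOCH_KINDS}")


# ---------------------------------------------------------------------------
# the AROC statistic
# ---------------------------------------------------------------------------

def auroc(signal_counts, noise_counts) -> float:
    """Pairwise AROC with tie half-credit.

    Equals ``sum over (s, n) pairs of [1 if s > n, 0.5 if s == n, 0]``
    divided by ``n_s * n_n``; computed via midranks in O(N log N).
    """
    s = np.asarray(signal_counts, dtype=float)
    n = np.asarray(noise_counts, dtype=float)
    if s.size == 0 or n.size == 0:
        raise ValueError("both count sets must be non-empty")
    return _auroc_presorted(s, np.sort(n))


def _auroc_presorted(signal: np.ndarray, noise_sorted: np.ndarray) -> float:
    """AROC against an already-sorted noise sample (bootstrap fast path)."""
    below = np.searchsorted(noise_sorted, signal, "left")
    equal = np.searchsorted(noise_sorted, signal, "right") - below
    return float((below.sum() + 0.5 * equal.sum()) / (signal.size * noise_sorted.size))


def bootstrap_auroc_ci(signal_counts, noise_counts, n_boot: int = 1000, rng_seed=None):
    """Percentile bootstrap CI for the AROC.

    Signal and noise sets are resampled independently with replacement,
    preserving their sizes; returns the 2.5 and 97.5 percentiles of the
    replicate distribution.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    s = np.asarray(signal_counts, dtype=float)
    n = np.asarray(noise_counts, dtype=float)
    if s.size == 0 or n.size == 0:
        raise ValueError("both count sets must be non-empty")
    rng = as_rng(rng_seed)
    si = rng.integers(0, s.size, size=(n_boot, s.size))
    ni = rng.integers(0, n.size, size=(n_boot, n.size))
    reps = np.empty(n_boot)
    for b in range(n_boot):
        reps[b] = _auroc_presorted(s[si[b]], np.sort(n[ni[b]]))
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(lo), float(hi)


def significance_from_ci(ci_lo: float, ci_hi: float) -> str:
    if ci_lo > 0.5:
        return "positive"
    if ci_hi < 0.5:
        return "negative"
    return "ns"


# ---------------------------------------------------------------------------
# per-unit epoch contrasts
# ---------------------------------------------------------------------------

def _select_trials(trials: list[TrialEvents], spec: EpochSpec):
    """Change trials passing the spec's cue-side / tilt filters.

    Returns (signal_trials, noise_trials).  For the within-trial contrasts
    both sets are the same trials; for the spatial contrast they are the
    contra vs ipsi split.
    """
    change = [tr for tr in trials if tr.is_change]
    if spec.kind == "delay_spatial":
        return (
            [tr for tr in change if tr.cue_side == "contra"],
            [tr for tr in change if tr.cue_side == "ipsi"],
        )
    kept = change
    if spec.contra_only:
        kept = [tr for tr in kept if tr.cue_side == "contra"]
    if spec.tilt_category is not None:
        kept = [tr for tr in kept if tr.tilt_category == spec.tilt_category]
    return kept, kept


def epoch_discriminability(
    unit: UnitRecord,
    trials: list[TrialEvents],
    spec: EpochSpec,
    *,
    min_trials: int = 5,
    n_boot: int = 1000,
    rng_seed=None,
    compute_ci: bool = True,
) -> AurocResult | None:
    """AROC + bootstrap CI + significance class for one unit and contrast.

    Returns None (logged) when either trial set is smaller than
    ``min_trials``.  With ``compute_ci=False`` the CI and significance are
    skipped (NaN / "ns") — used by bulk comparisons that only need the
    point estimates.
    """
    sig_trials, noise_trials = _select_trials(trials, spec)
    if len(sig_trials) < min_trials or len(noise_trials) < min_trials:
        logger.info(
            "unit %s excluded for %s: %d/%d trials < min %d",
            unit.unit_id, spec.kind, len(sig_trials), len(noise_trials), min_trials,
        )
        return None
    sig_t = np.array([getattr(tr, sa.EVENT_FIELDS[spec.signal_event]) for tr in sig_trials])
    noi_t = np.array([getattr(tr, sa.EVENT_FIELDS[spec.noise_event]) for tr in noise_trials])
    s = sa.rates_for_events(unit.spike_times, sig_t, spec.signal_window_ms)
    n = sa.rates_for_events(unit.spike_times, noi_t, spec.noise_window_ms)
    a = auroc(s, n)
    if compute_ci:
        lo, hi = bootstrap_auroc_ci(s, n, n_boot=n_boot, rng_seed=rng_seed)
        sig = significance_from_ci(lo, hi)
    else:
        lo = hi = float("nan")
        sig = "ns"
    return AurocResult(
        unit_id=unit.unit_id,
        epoch=spec.kind,
        auroc=a,
        ci_lo=lo,
        ci_hi=hi,
        significance=sig,
        n_signal_trials=len(sig_trials),
        n_noise_trials=len(noise_trials),
        session_id=unit.session_id,
        layer=unit.layer,
        tilt_category=spec.tilt_category or "",
    )


def population_summary(results: list[AurocResult], rng_seed=None, n_boot: int = 1000) -> dict:
    """Median AROC with a bootstrap-over-units CI, plus significance prevalence.

    Returns ``{"median", "median_ci", "pct_positive", "pct_negative", "n_units"}``
    with prevalences in percent.
    """
    if not results:
        raise ValueError("empty result list")
    vals = np.array([r.auroc for r in results])
    rng = as_rng(rng_seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    reps = np.median(vals[idx], axis=1)
    sig = np.array([r.significance for r in results])
    return {
        "median": float(np.median(vals)),
        "median_ci": (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5))),
        "pct_positive": float(100.0 * np.mean(sig == "positive")),
        "pct_negative": float(100.0 * np.mean(sig == "negative")),
        "n_units": int(vals.size),
    }


def auroc_timecourse(
    unit: UnitRecord,
    trials: list[TrialEvents],
    event: str = "change_on",
    range_ms=(-1000.0, 0.0),
    bin_ms: float = 20.0,
):
    """Per-bin contra-vs-ipsi AROC for delay-period visualization.

    Spike counts in nonoverlapping ``bin_ms`` bins aligned on ``event`` are
    compared between contralateral-cue (signal) and ipsilateral-cue (noise)
    change trials; returns ``(bin_starts_ms, auroc_per_bin)``.
    """
    a, b = range_ms
    n_bins = (b - a) / bin_ms
    if abs(n_bins - round(n_bins)) > 1e-9 or n_bins < 1:
        raise ValueError("bin_ms must evenly divide the range")
    n_bins = int(round(n_bins))
    change = [tr for tr in trials if tr.is_change]
    contra = np.array([getattr(tr, sa.EVENT_FIELDS[event]) for tr in change if tr.cue_side == "contra"])
    ipsi = np.array([getattr(tr, sa.EVENT_FIELDS[event]) for tr in change if tr.cue_side == "ipsi"])
    if contra.size == 0 or ipsi.size == 0:
        raise ValueError("need both contra and ipsi change trials")
    starts = a + bin_ms * np.arange(n_bins)
    out = np.empty(n_bins)
    for k, s0 in enumerate(starts):
        win = (s0, s0 + bin_ms)
        out[k] = auroc(
            sa.counts_for_events(unit.spike_times, contra, win),
            sa.counts_for_events(unit.spike_times, ipsi, win),
        )
    return starts, out
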