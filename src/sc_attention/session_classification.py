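"""Classify non-naive sessions as intermediate or expert from lick patterns.

Each session is summarized by its change-aligned, trial-averaged,
unit-sum-normalized lick time course; the set of session traces is embedded
in two dimensions with UMAP and split into two clusters with k-means.  The
cluster whose sessions concentrate more lick mass in the post-change
response window (300-800 ms) is labeled ``expert``, the other
``intermediate``.  Passive-cohort sessions bypass the classifier and are
always labeled ``naive``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import RESPONSE_WINDOW_MS
from .types import SessionRecord

logger = logging.getLogger(__name__)

__all__ = [
    "LickTimeCourse",
    "lick_time_course",
    "embed_sessions",
    "cluster_and_label",
    "classify_sessions",
]

#: Default trace parameterization: change-aligned range and bin width, ms.
DEFAULT_RANGE_MS = (-3000.0, 1500.0)
DEFAULT_BIN_MS = 100.0


@dataclass
class LickTimeCourse:
    """Normalized change-aligned lick-frequency trace for one session."""

    session_id: str
    bin_edges_ms: np.ndarray
    values: np.ndarray  # sums to 1, or all-zero when the session has no licks
    all_zero: bool


def lick_time_course(
    session: SessionRecord,
    *,
    range_ms=DEFAULT_RANGE_MS,
    bin_ms: float = DEFAULT_BIN_MS,
) -> LickTimeCourse:
    """Per-bin lick counts aligned on change onset, averaged over trials and
    normalized to unit sum.  Sessions with no licks in range yield an
    all-zero trace, flagged for exclusion from the embedding."""
    if not session.trials:
        raise ValueError("session has no trials")
    a, b = range_ms
    n_bins = int(round((b - a) / bin_ms))
    if abs((b - a) / bin_ms - n_bins) > 1e-9 or n_bins < 1:
        raise ValueError("bin_ms must evenly divide the range")
    edges = a + bin_ms * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for tr in session.trials:
        licks = np.asarray(session.licks_by_trial.get(tr.trial_id, ()), dtype=float)
        rel = (licks - tr.t_change_on) * 1000.0
        counts += np.histogram(rel[(rel >= a) & (rel < b)], bins=edges)[0]
    total = counts.sum()
    if total == 0:
        logger.warning("session %s has no licks in range; all-zero trace", session.session_id)
        return LickTimeCourse(session.session_id, edges, counts, all_zero=True)
    return LickTimeCourse(session.session_id, edges, counts / total, all_zero=False)


def embed_sessions(
    courses: list[LickTimeCourse],
    rng_seed: int,
    *,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> np.ndarray:
    """Two-dimensional UMAP embedding of the session traces (deterministic
    for a given seed)."""
    import umap  # deferred: slow import

    usable = [c for c in courses if not c.all_zero]
    if len(usable) < len(courses):
        raise ValueError("all-zero traces must be excluded before embedding")
    if len(courses) <= n_neighbors:
        raise ValueError(
            f"need more than n_neighbors={n_neighbors} sessions "
            f"(got {len(courses)}); reduce n_neighbors"
        )
    X = np.vstack([c.values for c in courses])
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        metric="euclidean",
        random_state=int(rng_seed),
        n_jobs=1,
    )
    return reducer.fit_transform(X)


def cluster_and_label(
    embedding: np.ndarray,
    courses: list[LickTimeCourse],
    rng_seed: int = 0,
    *,
    response_window_ms=RESPONSE_WINDOW_MS,
) -> np.ndarray:
    """Two-means clustering of the embedding, mapped to performance levels.

    The cluster with higher mean lick mass inside the post-change response
    window is ``expert``; the other is ``intermediate``.
    """
    from sklearn.cluster import KMeans

    if len(courses) < 2:
        raise ValueError("need >= 2 sessions to cluster")
    km = KMeans(n_clusters=2, n_init=10, random_state=int(rng_seed))
    clusters = km.fit_predict(np.asarray(embedding, dtype=float))
    if len(np.unique(clusters)) < 2:
        raise ValueError("degenerate clustering: one cluster is empty")
    lo, hi = response_window_ms
    masses = np.empty(len(courses))
    for i, c in enumerate(courses):
        centers = 0.5 * (c.bin_edges_ms[:-1] + c.bin_edges_ms[1:])
        masses[i] = c.values[(centers >= lo) & (centers < hi)].sum()
    mean_mass = [masses[clusters == k].mean() for k in (0, 1)]
    expert_cluster = int(np.argmax(mean_mass))
    return np.where(clusters == expert_cluster, "expert", "intermediate")


def classify_sessions(
    sessions: list[SessionRecord],
    rng_seed: int,
    *,
    range_ms=DEFAULT_RANGE_MS,
    bin_ms: float = DEFAULT_BIN_MS,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> pd.DataFrame:
    """End-to-end session classification.

    Passive-cohort sessions are assigned ``naive`` without entering the
    embedding; lick-free sessions are excluded (level left empty, flagged).
    Returns a frame with embedding coordinates and assigned levels; output
    is independent of the input session ordering (sessions are sorted by id
    before embedding).
    """
    order = np.argsort([s.session_id for s in sessions])
    sessions = [sessions[i] for i in order]
    rows = {s.session_id: {"session_id": s.session_id, "cohort": s.cohort,
                           "embedded_x": np.nan, "embedded_y": np.nan,
                           "assigned_level": ""} for s in sessions}
    to_embed, courses = [], []
    for s in sessions:
        if s.cohort == "passive":
            rows[s.session_id]["assigned_level"] = "naive"
            continue
        c = lick_time_course(s, range_ms=range_ms, bin_ms=bin_ms)
        if c.all_zero:
            logger.warning("session %s excluded from classification (no licks)", s.session_id)
            continue
        to_embed.append(s)
        courses.append(c)
    if courses:
        emb = embed_sessions(courses, rng_seed, n_neighbors=n_neighbors, min_dist=min_dist)
        labels = cluster_and_label(emb, courses, rng_seed)
        for s, xy, lvl in zip(to_embed, emb, labels):
            rows[s.session_id].update(
                embedded_x=float(xy[0]), embedded_y=float(xy[1]), assigned_level=str(lvl)
            )
            s.assigned_level = str(lvl)
    return pd.DataFrame(rows.values())
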