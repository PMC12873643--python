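"""Group comparison of AROC values across performance levels.

Two complementary inferences, applied jointly:

* a random-intercept linear mixed model,
  ``AROC_ij = beta0 + beta1 * Level_ij + u_j + eps_ij`` (i = units,
  j = sessions, Level binary), with a Wald z-test on ``beta1``; and
* a nonparametric session-level permutation test on session-averaged AROC
  values, comparing the observed difference of group medians to a null
  built by shuffling level labels across sessions (two-sided).

A comparison counts as significant only when **both** tests reject at the
chosen alpha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic_data import as_rng

logger = logging.getLogger(__name__)

__all__ = [
    "LmmResult",
    "PermutationResult",
    "fit_random_intercept_model",
    "session_mean_auroc",
    "session_permutation_test",
    "joint_significance",
    "compare_groups",
]


@dataclass
class LmmResult:
    beta0: float
    beta1: float
    se_beta1: float
    p_beta1: float
    sigma_u: float
    sigma_e: float
    n_units: int
    n_sessions: int
    degenerate: bool = False


@dataclass
class PermutationResult:
    observed_stat: float
    n_perm: int
    p_two_sided: float
    method: str  # "exhaustive" | "monte_carlo"
    null_quantiles: tuple  # (2.5%, 50%, 97.5%) of the null distribution


def fit_random_intercept_model(values, session_ids, level_labels, *, reml: bool = True) -> LmmResult:
    """Fit the random-intercept model for one pairwise level comparison.

    ``level_labels`` must be binary (0/1 or two distinct labels; the larger
    label after factorization codes 1, so ``beta1`` is its mean shift).
    The p-value is a two-sided Wald z-test on the fixed-effect coefficient.
    """
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite AROC values")
    session_ids = np.asarray(session_ids)
    codes, uniques = pd.factorize(np.asarray(level_labels), sort=True)
    if len(uniques) != 2:
        raise ValueError(f"need exactly two levels, got {list(uniques)}")
    n_sessions = len(np.unique(session_ids))
    for lvl in (0, 1):
        n_sess = len(np.unique(session_ids[codes == lvl]))
        if n_sess < 2:
            warnings.warn(
                f"level {uniques[lvl]!r} has only {n_sess} session(s); "
                "the random intercept is weakly identified", stacklevel=2,
            )
    if np.ptp(values) == 0:
        # all-identical input: no variance to fit; flagged degenerate
        return LmmResult(float(values[0]), 0.0, 0.0, 1.0, 0.0, 0.0,
                         len(values), n_sessions, degenerate=True)
    exog = sm.add_constant(codes.astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary (sigma_u ~ 0) convergence chatter
        model = sm.MixedLM(values, exog, groups=session_ids)
        fit = model.fit(reml=reml)
    beta0, beta1 = fit.fe_params
    se = float(fit.bse_fe[1])
    p = float(fit.pvalues[1])
    sigma_u = float(np.sqrt(max(np.asarray(fit.cov_re)[0, 0], 0.0)))
    sigma_e = float(np.sqrt(fit.scale))
    degenerate = not (np.isfinite(se) and np.isfinite(p))
    if degenerate:
        # boundary fit with a collapsed variance structure: report the
        # estimate but make the test a non-rejection
        logger.warning("mixed-model SE not finite; comparison marked degenerate")
        se, p = 0.0, 1.0
    return LmmResult(float(beta0), float(beta1), se, p, sigma_u, sigma_e,
                     len(values), n_sessions, degenerate=degenerate)


def session_mean_auroc(values, session_ids, *, statistic: str = "mean"):
    """Collapse unit AROC values to one value per session (mean by default)."""
    df = pd.DataFrame({"v": np.asarray(values, dtype=float), "s": np.asarray(session_ids)})
    agg = df.groupby("s")["v"].mean() if statistic == "mean" else df.groupby("s")["v"].median()
    return agg.to_numpy(), agg.index.to_numpy()


def session_permutation_test(
    session_values,
    level_labels,
    n_perm: int = 10000,
    rng_seed=None,
    *,
    method: str = "auto",
) -> PermutationResult:
    """Two-sided session-label permutation test on the difference of group
    medians of session-averaged AROC.

    The observed statistic is ``median(level-1 sessions) - median(level-0
    sessions)``.  When the number of distinct label assignments is at most
    ``n_perm`` the null is enumerated exhaustively and the p-value is the
    exact fraction of assignments at least as extreme; otherwise ``n_perm``
    random shuffles are drawn and the add-one-corrected Monte-Carlo p is
    returned, ``(1 + #extreme) / (n_perm + 1)``.  ``method`` forces
    ``"exhaustive"`` or ``"monte_carlo"`` instead of the automatic choice.
    """
    vals = np.asarray(session_values, dtype=float)
    codes, uniques = pd.factorize(np.asarray(level_labels), sort=True)
    if len(uniques) != 2:
        raise ValueError(f"need exactly two levels, got {list(uniques)}")
    n = vals.size
    n1 = int(codes.sum())
    if n1 < 2 or n - n1 < 2:
        raise ValueError("need >= 2 sessions per level")
    observed = float(np.median(vals[codes == 1]) - np.median(vals[codes == 0]))
    tol = 1e-12
    if method not in ("auto", "exhaustive", "monte_carlo"):
        raise ValueError(f"unknown method {method!r}")

    n_assign = comb(n, n1)
    use_exhaustive = method == "exhaustive" or (method == "auto" and n_assign <= n_perm)
    if use_exhaustive:
        null = np.empty(n_assign)
        idx_all = np.arange(n)
        for k, ones in enumerate(combinations(idx_all, n1)):
            mask = np.zeros(n, dtype=bool)
            mask[list(ones)] = True
            null[k] = np.median(vals[mask]) - np.median(vals[~mask])
        p = float(np.mean(np.abs(null) >= abs(observed) - tol))
        method = "exhaustive"
        n_used = n_assign
    else:
        rng = as_rng(rng_seed)
        # n_perm independent shuffles of the label vector, vectorized
        order = np.argsort(rng.random((n_perm, n)), axis=1)
        perm_codes = np.asarray(codes)[order]
        v1 = np.where(perm_codes == 1, vals, np.nan)
        v0 = np.where(perm_codes == 0, vals, np.nan)
        null = np.nanmedian(v1, axis=1) - np.nanmedian(v0, axis=1)
        p = float((1 + np.sum(np.abs(null) >= abs(observed) - tol)) / (n_perm + 1))
        method = "monte_carlo"
        n_used = n_perm
    q = tuple(float(x) for x in np.percentile(null, [2.5, 50, 97.5]))
    return PermutationResult(observed, n_used, p, method, q)


def joint_significance(p_lmm: float, p_perm: float, alpha: float = 0.05) -> bool:
    """True iff both tests reject at ``alpha`` (strict inequalities)."""
    for p in (p_lmm, p_perm):
        if not (0 <= p <= 1):
            raise ValueError(f"invalid p value {p!r}")
    return bool(p_lmm < alpha and p_perm < alpha)


def compare_groups(
    results_df: pd.DataFrame,
    *,
    n_perm: int = 10000,
    rng_seed=None,
    alpha: float = 0.05,
    session_statistic: str = "mean",
) -> pd.DataFrame:
    """All pairwise level comparisons within each epoch x layer (x tilt) cell.

    ``results_df`` needs columns ``auroc, session_id, layer, level, epoch,
    tilt_category``.  Returns one row per comparison with both p-values and
    the joint-significance flag, mirroring a summary-table layout.
    """
    rng = as_rng(rng_seed)
    rows = []
    group_cols = ["epoch", "layer", "tilt_category"]
    pairs = [("naive", "intermediate"), ("intermediate", "expert"), ("naive", "expert")]
    for keys, cell in results_df.groupby(group_cols, dropna=False):
        for lo_lvl, hi_lvl in pairs:
            sub = cell[cell["level"].isin([lo_lvl, hi_lvl])]
            if sub["level"].nunique() < 2:
                continue
            # order levels so beta1 / observed_stat measure hi minus lo
            labels = (sub["level"] == hi_lvl).astype(int).to_numpy()
            try:
                lmm = fit_random_intercept_model(
                    sub["auroc"].to_numpy(), sub["session_id"].to_numpy(), labels
                )
                sess_vals, sess_ids = session_mean_auroc(
                    sub["auroc"].to_numpy(), sub["session_id"].to_numpy(),
                    statistic=session_statistic,
                )
                sess_labels = (
                    sub.drop_duplicates("session_id").set_index("session_id")
                    .loc[sess_ids, "level"] == hi_lvl
                ).astype(int).to_numpy()
                perm = session_permutation_test(
                    sess_vals, sess_labels, n_perm=n_perm, rng_seed=rng
                )
            except ValueError as err:
                logger.warning("comparison %s %s-vs-%s skipped: %s", keys, lo_lvl, hi_lvl, err)
                continue
            rows.append({
                "epoch": keys[0], "layer": keys[1], "tilt_category": keys[2],
                "comparison": f"{lo_lvl}_vs_{hi_lvl}",
                "beta1": lmm.beta1, "p_lmm": lmm.p_beta1,
                "observed_median_diff": perm.observed_stat, "p_perm": perm.p_two_sided,
                "significant": joint_significance(lmm.p_beta1, perm.p_two_sided, alpha),
                "n_units": lmm.n_units, "n_sessions": lmm.n_sessions,
            })
    return pd.DataFrame(rows)
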