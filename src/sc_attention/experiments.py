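"""Prepackaged simulation experiments over the full analysis chain.

The central one contrasts a visually naive cohort (deep-layer cue, change
and delay-bias gains all zero) with an expert cohort (all three positive)
and asks whether the joint mixed-model + permutation rule detects the
difference in each of the three epoch contrasts — and stays silent when
both cohorts are generated with identical gains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import discriminability, group_comparison
from .synthetic_data import DEFAULT_GAIN_TABLE, simulate_cohort
from .types import CohortSpec, RateKernelParams

__all__ = [
    "naive_vs_expert_gain_tables",
    "equal_gain_tables",
    "EpochTestResult",
    "deep_layer_joint_tests",
]

EPOCHS = ("cue_onset", "delay_spatial", "change_onset")


def naive_vs_expert_gain_tables() -> dict:
    """Gain table where deep-layer modulation exists only in the expert
    cohort (the directional ground truth of the learning effect)."""
    table = {k: dict(v) for k, v in DEFAULT_GAIN_TABLE.items()}
    table[("naive", "deep")] = {"cue": 0.0, "change": 0.0, "delay": 0.0}
    table[("expert", "deep")] = {"cue": 1.0, "change": 1.0, "delay": 0.8}
    return table


def equal_gain_tables() -> dict:
    """Null ground truth: every cohort generated with the same mid-level
    gains, so no level difference exists anywhere."""
    shared_sup = {"cue": 1.5, "change": 0.7, "delay": 0.05}
    shared_deep = {"cue": 0.5, "change": 0.5, "delay": 0.4}
    return {
        (lvl, "superficial"): dict(shared_sup)
        for lvl in ("naive", "intermediate", "expert")
    } | {
        (lvl, "deep"): dict(shared_deep)
        for lvl in ("naive", "intermediate", "expert")
    }


@dataclass
class EpochTestResult:
    epoch: str
    beta1: float
    p_lmm: float
    observed_median_diff: float
    p_perm: float
    joint_significant: bool
    n_units: int


def deep_layer_joint_tests(
    seed,
    gain_table: dict,
    *,
    n_sessions: int = 8,
    trials_per_session: int = 150,
    units_per_session: int = 10,
    n_perm: int = 10000,
    min_trials: int = 5,
) -> dict[str, EpochTestResult]:
    """Simulate naive and expert cohorts and run the three deep-layer epoch
    comparisons with the joint significance rule.

    Deep-layer units only (the locus of the learning effect in the ground
    truth); per-unit bootstrap CIs are skipped since the group tests need
    only the AROC point estimates.  Returns one result per epoch contrast.
    """
    ss = np.random.SeedSequence(seed)
    s_naive, s_expert, s_perm = ss.spawn(3)
    cohorts = {}
    for level, child in (("naive", s_naive), ("expert", s_expert)):
        spec = CohortSpec(
            level, n_sessions, trials_per_session,
            has_no_change_trials=True,
            lick_archetype="early_peak" if level == "naive" else "change_locked",
            units_per_session=units_per_session,
            superficial_fraction=0.3,
        )
        cohorts[level] = simulate_cohort(
            spec, child, base_params=RateKernelParams(),
            gain_table=gain_table, with_eye=False,
        )

    rows = []
    especs = {
        "cue_onset": discriminability.epoch_spec("cue_onset"),
        "delay_spatial": discriminability.epoch_spec("delay_spatial"),
        "change_onset": discriminability.epoch_spec("change_onset"),
    }
    for level, sessions in cohorts.items():
        for sd in sessions:
            for u in sd.units:
                if u.layer != "deep":
                    continue
                for epoch, espec in especs.items():
                    r = discriminability.epoch_discriminability(
                        u, sd.trials, espec, min_trials=min_trials, compute_ci=False
                    )
                    if r is not None:
                        rows.append({
                            "epoch": epoch, "level": level,
                            "session_id": sd.record.session_id, "auroc": r.auroc,
                        })
    df = pd.DataFrame(rows)

    rng = np.random.default_rng(s_perm)
    out = {}
    for epoch in EPOCHS:
        sub = df[df["epoch"] == epoch]
        labels = (sub["level"] == "expert").astype(int).to_numpy()
        lmm = group_comparison.fit_random_intercept_model(
            sub["auroc"].to_numpy(), sub["session_id"].to_numpy(), labels
        )
        sess_vals, sess_ids = group_comparison.session_mean_auroc(
            sub["auroc"].to_numpy(), sub["session_id"].to_numpy()
        )
        sess_labels = (
            sub.drop_duplicates("session_id").set_index("session_id")
            .loc[sess_ids, "level"] == "expert"
        ).astype(int).to_numpy()
        perm = group_comparison.session_permutation_test(
            sess_vals, sess_labels, n_perm=n_perm, rng_seed=rng
        )
        out[epoch] = EpochTestResult(
            epoch=epoch,
            beta1=lmm.beta1,
            p_lmm=lmm.p_beta1,
            observed_median_diff=perm.observed_stat,
            p_perm=perm.p_two_sided,
            joint_significant=group_comparison.joint_significance(
                lmm.p_beta1, perm.p_two_sided
            ),
            n_units=lmm.n_units,
        )
    return out
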