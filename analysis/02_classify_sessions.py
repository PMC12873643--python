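#!/usr/bin/env python
"""Assign a performance level to every session from its lick pattern.

Passive-cohort sessions are naive by definition; the remaining sessions are
embedded (UMAP on change-aligned normalized lick time courses) and split
into two clusters, with the cluster licking more inside the 300-800 ms
response window labeled expert.  Writes results/session_levels.csv and
reports agreement with the generating cohorts — the synthetic analogue of
checking classifications against training-cohort identity.
"""

from pathlib import Path

import pandas as pd

from sc_attention.pipeline_io import read_session_bundle
from sc_attention.session_classification import classify_sessions

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"
SEED = 0


def main() -> None:
    bundle = read_session_bundle(SCRATCH)
    gt = bundle.ground_truth
    records = [
        bundle.session_record(sid, gt[sid]["cohort"])
        for sid in sorted(bundle.events["session_id"].unique())
    ]
    df = classify_sessions(records, rng_seed=SEED, n_neighbors=8)
    df["generator_level"] = df["session_id"].map({k: v["level"] for k, v in gt.items()})
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "session_levels.csv", index=False)

    agree = (df["assigned_level"] == df["generator_level"]).sum()
    print(f"assigned levels for {len(df)} sessions "
          f"({agree}/{len(df)} match the generating cohort)")
    print(pd.crosstab(df["generator_level"], df["assigned_level"]))


if __name__ == "__main__":
    main()
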