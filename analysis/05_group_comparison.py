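#!/usr/bin/env python
"""Compare AROC distributions across performance levels.

Every epoch x layer (x tilt size) cell gets the three pairwise level
comparisons, each tested twice: a random-intercept mixed model
(AROC_ij = b0 + b1 Level_ij + u_j + e_ij, Wald test on b1) and a
session-label permutation test on the difference of group medians of
session-mean AROC (10,000 shuffles, two-sided, exhaustive when feasible).
A comparison is starred only when both tests reject at alpha = 0.05.
Writes results/comparisons.csv.
"""

from pathlib import Path

import pandas as pd

from sc_attention.group_comparison import compare_groups

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 0


def main() -> None:
    results = pd.read_csv(RESULTS / "auroc_results.csv")
    comp = compare_groups(results, n_perm=10000, rng_seed=SEED)
    comp.to_csv(RESULTS / "comparisons.csv", index=False)

    sig = comp[comp["significant"]]
    print(f"{len(comp)} comparisons; {len(sig)} pass the joint rule:\n")
    cols = ["epoch", "layer", "tilt_category", "comparison",
            "beta1", "p_lmm", "observed_median_diff", "p_perm"]
    with pd.option_context("display.width", 140):
        print(sig[cols].to_string(index=False))
    deep = comp[(comp["layer"] == "deep") & (comp["comparison"] == "naive_vs_expert")
                & (comp["tilt_category"] == "all")]
    print("\nnaive-vs-expert, deep layer (pooled tilts):")
    print(deep[cols].to_string(index=False))


if __name__ == "__main__":
    main()
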