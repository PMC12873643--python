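#!/usr/bin/env python
"""Per-unit AROC discriminability for the three epoch contrasts.

For every unit: cue-onset (post-cue 40-140 ms vs pre-cue baseline),
delay-spatial (end-of-delay firing, contra- vs ipsi-cue trials), and
change-onset (post- vs pre-change, pooled and per tilt size), each with a
1,000-replicate bootstrap CI and the CI-vs-0.5 significance class.
Writes results/auroc_results.csv and prints population medians and the
prevalence of significant units by level and layer.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from sc_attention import discriminability as disc
from sc_attention.pipeline_io import read_session_bundle

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"
SEED = 0


def main() -> None:
    bundle = read_session_bundle(SCRATCH)
    levels = pd.read_csv(RESULTS / "session_levels.csv").set_index("session_id")
    especs = [disc.epoch_spec("cue_onset"), disc.epoch_spec("delay_spatial"),
              disc.epoch_spec("change_onset")]
    especs += [disc.epoch_spec("change_onset", tilt_category=c)
               for c in ("small", "medium", "large")]
    rng = np.random.default_rng(SEED)
    rows = []
    for sid in sorted(bundle.events["session_id"].unique()):
        trials = bundle.trials_of(sid)
        level = levels.loc[sid, "assigned_level"]
        for unit in bundle.unit_records(sid):
            for espec in especs:
                r = disc.epoch_discriminability(unit, trials, espec, rng_seed=rng)
                if r is None:
                    continue
                rows.append({
                    "unit_id": r.unit_id, "session_id": sid, "layer": r.layer,
                    "level": level, "epoch": r.epoch,
                    "tilt_category": r.tilt_category or "all",
                    "auroc": r.auroc, "ci_lo": r.ci_lo, "ci_hi": r.ci_hi,
                    "significance": r.significance,
                    "n_signal": r.n_signal_trials, "n_noise": r.n_noise_trials,
                })
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "auroc_results.csv", index=False)

    pooled = df[df["tilt_category"] == "all"]
    print(f"{df['unit_id'].nunique()} units, {len(df)} unit x epoch results\n")
    for (epoch, layer), grp in pooled.groupby(["epoch", "layer"]):
        print(f"{epoch} / {layer}:")
        for level in ("naive", "intermediate", "expert"):
            g = grp[grp["level"] == level]
            if g.empty:
                continue
            print(f"  {level:>12}: median AROC {g['auroc'].median():.3f} "
                  f"({100 * (g['significance'] == 'positive').mean():.0f}% positive, "
                  f"{100 * (g['significance'] == 'negative').mean():.0f}% negative, "
                  f"n={len(g)})")


if __name__ == "__main__":
    main()
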