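#!/usr/bin/env python
"""Simulate the three training cohorts and write the session fixtures.

Three cohorts of synthetic sessions — passive viewing (naive), stimulus-
reward association (intermediate), change detection (expert) — with 6
sessions x 150 trials x 8 units each, event-locked Poisson spiking whose
deep-layer gains grow with training, cohort-specific licking, and 240 Hz
eye traces.  Fixtures (including eye.csv, which is large) go to
scratch/run/; later steps read them back from disk.
"""

from pathlib import Path

from sc_attention.pipeline_io import RunConfig, write_session_bundle
from sc_attention.synthetic_data import simulate_cohort
from sc_attention.types import RateKernelParams

import numpy as np

SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "run"
SEED = 0


def build_config() -> RunConfig:
    cfg = RunConfig(seed=SEED)
    for c in cfg.cohorts:
        c["n_sessions"] = 6
        c["trials_per_session"] = 150
    cfg.classifier["n_neighbors"] = 8  # 12 non-naive sessions at this scale
    cfg.write_eye = True
    return cfg


def main() -> None:
    cfg = build_config()
    master = np.random.SeedSequence(cfg.seed)
    sessions = []
    for spec, child in zip(cfg.cohort_specs(), master.spawn(len(cfg.cohorts))):
        sessions.extend(simulate_cohort(
            spec, child, base_params=RateKernelParams(**cfg.kernel),
            gain_table=cfg.resolved_gain_table(), with_eye=True,
        ))
    SCRATCH.mkdir(parents=True, exist_ok=True)
    write_session_bundle(sessions, SCRATCH, include_eye=True)
    cfg.to_yaml(SCRATCH / "config_resolved.yaml")
    n_spikes = sum(len(u.spike_times) for sd in sessions for u in sd.units)
    n_licks = sum(len(v) for sd in sessions for v in sd.record.licks_by_trial.values())
    print(f"wrote {len(sessions)} sessions ({len(sessions) * 150} trials, "
          f"{sum(len(sd.units) for sd in sessions)} units, {n_spikes} spikes, "
          f"{n_licks} licks) to {SCRATCH}")


if __name__ == "__main__":
    main()
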