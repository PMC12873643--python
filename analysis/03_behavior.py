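#!/usr/bin/env python
"""Score trial outcomes and summarize behavior per session.

Hits are licks inside the 300-800 ms post-change window; false alarms come
from the matching window on no-change catch trials; the change-detection
task additionally aborts trials with anticipatory licks.  d' uses the
log-linear correction and is undefined for the intermediate cohort, which
has no catch trials.  Writes results/behavior.csv.
"""

from pathlib import Path

import pandas as pd

from sc_attention.behavior import score_session
from sc_attention.pipeline_io import read_session_bundle

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"


def main() -> None:
    bundle = read_session_bundle(SCRATCH)
    levels = pd.read_csv(RESULTS / "session_levels.csv").set_index("session_id")
    rows = []
    for sid in sorted(bundle.events["session_id"].unique()):
        rec = bundle.session_record(sid, bundle.ground_truth[sid]["cohort"])
        level = levels.loc[sid, "assigned_level"]
        summ = score_session(rec.trials, rec.licks_by_trial,
                             abort_on_anticipatory=(level == "expert"))
        summ.pop("outcomes")
        rows.append({"session_id": sid, "level": level, **summ})
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "behavior.csv", index=False)

    by_level = df.groupby("level")[["hit_rate", "false_alarm_rate", "dprime",
                                    "median_rt_ms"]].mean(numeric_only=True)
    print("session-mean behavior by assigned level:")
    print(by_level.round(3))
    print("\n(d' and false-alarm rate are undefined for levels without "
          "no-change catch trials)")


if __name__ == "__main__":
    main()
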