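"""Fixture file formats, run configuration, and the end-to-end pipeline.

All fixtures are plain delimited text with headers (diff-able, dependency
light): ``events.csv``, ``units.csv``, ``spikes.csv``, ``licks.csv``,
``eye.csv``.  Times are seconds from session start; windows are ms relative
to events; eye position is in degrees.  A run writes its resolved
configuration and seed next to its outputs, and the resolved config + seed
fully determine every output byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, discriminability, eye_movements, group_comparison, session_classification
from .synthetic_data import (
    DEFAULT_GAIN_TABLE,
    SessionData,
    simulate_cohort,
)
from .types import CohortSpec, EyeTrace, RateKernelParams, SessionRecord, TrialEvents, UnitRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SCHEMAS",
    "RunConfig",
    "write_session_bundle",
    "read_session_bundle",
    "run_pipeline",
]

SCHEMAS = {
    "events.csv": [
        "session_id", "trial_id", "cue_side", "t_noise_on", "t_cue_on",
        "t_twopatch_on", "t_change_on", "tilt_deg", "is_change", "outcome",
    ],
    "units.csv": ["unit_id", "session_id", "layer", "depth_um"],
    "spikes.csv": ["session_id", "unit_id", "spike_time_s"],
    "licks.csv": ["session_id", "trial_id", "lick_time_s"],
    "eye.csv": ["session_id", "t", "x_deg", "y_deg", "pupil"],
}


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, including all analysis
    constants (epoch windows, resample counts) at their standard values."""

    seed: int = 0
    cohorts: list = field(default_factory=lambda: [
        {"level": "naive", "n_sessions": 8, "trials_per_session": 200,
         "has_no_change_trials": True, "lick_archetype": "early_peak",
         "units_per_session": 8},
        {"level": "intermediate", "n_sessions": 8, "trials_per_session": 200,
         "has_no_change_trials": False, "lick_archetype": "ramping",
         "units_per_session": 8},
        {"level": "expert", "n_sessions": 8, "trials_per_session": 200,
         "has_no_change_trials": True, "lick_archetype": "change_locked",
         "units_per_session": 8},
    ])
    kernel: dict = field(default_factory=lambda: dataclasses.asdict(RateKernelParams()))
    gain_table: dict | None = None  # None -> generator defaults
    n_boot: int = 1000
    n_perm: int = 10000
    min_trials: int = 5
    alpha: float = 0.05
    classifier: dict = field(default_factory=lambda: {
        "n_neighbors": 15, "min_dist": 0.1,
        "range_ms": [-3000.0, 1500.0], "bin_ms": 100.0,
    })
    with_eye: bool = True
    write_eye: bool = False  # eye.csv is by far the largest fixture; opt in
    change_tilt_categories: list = field(default_factory=lambda: ["all", "small", "medium", "large"])
    saccade_free_reanalysis: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def cohort_specs(self) -> list[CohortSpec]:
        return [CohortSpec(**c) for c in self.cohorts]

    def resolved_gain_table(self) -> dict:
        if self.gain_table is None:
            return DEFAULT_GAIN_TABLE
        # YAML keys are "level/layer" strings
        return {tuple(k.split("/")): v for k, v in self.gain_table.items()}


# ---------------------------------------------------------------------------
# fixture writing / reading
# ---------------------------------------------------------------------------

def write_session_bundle(sessions: list[SessionData], out_dir, *, include_eye: bool = True) -> None:
    """Write all fixture files plus the generator ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ev_rows, unit_rows, spike_rows, lick_rows, eye_frames = [], [], [], [], []
    ground_truth = {}
    for sd in sessions:
        for tr in sd.trials:
            ev_rows.append({
                "session_id": tr.session_id, "trial_id": tr.trial_id,
                "cue_side": tr.cue_side, "t_noise_on": tr.t_noise_on,
                "t_cue_on": tr.t_cue_on, "t_twopatch_on": tr.t_twopatch_on,
                "t_change_on": tr.t_change_on, "tilt_deg": tr.tilt_deg,
                "is_change": tr.is_change, "outcome": tr.outcome,
            })
            for lt in sd.record.licks_by_trial.get(tr.trial_id, ()):
                lick_rows.append({"session_id": tr.session_id,
                                  "trial_id": tr.trial_id, "lick_time_s": lt})
        for u in sd.units:
            unit_rows.append({"unit_id": u.unit_id, "session_id": u.session_id,
                              "layer": u.layer, "depth_um": u.depth_um})
            spike_rows.extend(
                {"session_id": u.session_id, "unit_id": u.unit_id, "spike_time_s": t}
                for t in u.spike_times
            )
        if include_eye and sd.eye is not None:
            eye_frames.append(pd.DataFrame({
                "session_id": sd.eye.session_id, "t": sd.eye.t,
                "x_deg": sd.eye.x_deg, "y_deg": sd.eye.y_deg,
                "pupil": sd.eye.pupil if sd.eye.pupil is not None else 1.0,
            }))
        ground_truth[sd.record.session_id] = {
            "level": sd.level, "cohort": sd.record.cohort, "units": sd.ground_truth,
        }
    pd.DataFrame(ev_rows, columns=SCHEMAS["events.csv"]).to_csv(out / "events.csv", index=False)
    pd.DataFrame(unit_rows, columns=SCHEMAS["units.csv"]).to_csv(out / "units.csv", index=False)
    pd.DataFrame(spike_rows, columns=SCHEMAS["spikes.csv"]).to_csv(out / "spikes.csv", index=False)
    pd.DataFrame(lick_rows, columns=SCHEMAS["licks.csv"]).to_csv(out / "licks.csv", index=False)
    if eye_frames:
        pd.concat(eye_frames, ignore_index=True).to_csv(out / "eye.csv", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(ground_truth, fh, indent=1, sort_keys=True)


@dataclass
class SessionBundle:
    """Validated in-memory session set reconstructed from fixture files."""

    events: pd.DataFrame
    units: pd.DataFrame
    spikes: pd.DataFrame
    licks: pd.DataFrame
    eye: pd.DataFrame | None
    ground_truth: dict | None

    def trials_of(self, session_id: str) -> list[TrialEvents]:
        sub = self.events[self.events["session_id"] == session_id].sort_values("trial_id")
        return [
            TrialEvents(
                session_id=r.session_id, trial_id=int(r.trial_id), cue_side=r.cue_side,
                t_noise_on=r.t_noise_on, t_cue_on=r.t_cue_on,
                t_twopatch_on=r.t_twopatch_on, t_change_on=r.t_change_on,
                tilt_deg=int(r.tilt_deg), is_change=bool(r.is_change), outcome=r.outcome,
            )
            for r in sub.itertuples()
        ]

    def unit_records(self, session_id: str | None = None) -> list[UnitRecord]:
        units = self.units if session_id is None else self.units[self.units["session_id"] == session_id]
        grouped = self.spikes.groupby("unit_id")["spike_time_s"]
        out = []
        for r in units.itertuples():
            spikes = grouped.get_group(r.unit_id).to_numpy() if r.unit_id in grouped.groups else np.empty(0)
            out.append(UnitRecord(unit_id=r.unit_id, session_id=r.session_id,
                                  layer=r.layer, depth_um=r.depth_um,
                                  spike_times=np.sort(spikes)))
        return out

    def session_record(self, session_id: str, cohort: str) -> SessionRecord:
        trials = self.trials_of(session_id)
        licks = self.licks[self.licks["session_id"] == session_id]
        by_trial = {
            int(tid): np.sort(g["lick_time_s"].to_numpy())
            for tid, g in licks.groupby("trial_id")
        }
        return SessionRecord(session_id=session_id, cohort=cohort,
                             trials=trials, licks_by_trial=by_trial)

    def eye_trace(self, session_id: str) -> EyeTrace | None:
        if self.eye is None:
            return None
        sub = self.eye[self.eye["session_id"] == session_id]
        if sub.empty:
            return None
        t = sub["t"].to_numpy()
        fs = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 240.0
        return EyeTrace(session_id=session_id, sample_rate_hz=float(round(fs)),
                        t=t, x_deg=sub["x_deg"].to_numpy(),
                        y_deg=sub["y_deg"].to_numpy(), pupil=sub["pupil"].to_numpy())


def _check_schema(df: pd.DataFrame, name: str) -> None:
    missing = [c for c in SCHEMAS[name] if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing required columns {missing}")


def read_session_bundle(in_dir) -> SessionBundle:
    """Read and validate the fixture files of one directory.

    Cross-file referential integrity is enforced: every spike must
    reference a known unit, every lick a known (session, trial), every unit
    a known session.  Violations are reported with the file and offending
    row index.
    """
    d = Path(in_dir)
    frames = {}
    for name in ("events.csv", "units.csv", "spikes.csv", "licks.csv"):
        path = d / name
        if not path.exists():
            raise FileNotFoundError(f"missing fixture file {path}")
        frames[name] = pd.read_csv(path)
        _check_schema(frames[name], name)
    events, units, spikes, licks = (
        frames["events.csv"], frames["units.csv"], frames["spikes.csv"], frames["licks.csv"]
    )
    known_sessions = set(events["session_id"])
    bad = units[~units["session_id"].isin(known_sessions)]
    if len(bad):
        raise ValueError(f"units.csv row {bad.index[0]}: unknown session_id "
                         f"{bad.iloc[0]['session_id']!r}")
    known_units = set(units["unit_id"])
    bad = spikes[~spikes["unit_id"].isin(known_units)]
    if len(bad):
        raise ValueError(f"spikes.csv row {bad.index[0]}: unknown unit_id "
                         f"{bad.iloc[0]['unit_id']!r}")
    trial_keys = set(zip(events["session_id"], events["trial_id"]))
    if len(licks):
        lick_keys = list(zip(licks["session_id"], licks["trial_id"]))
        for i, key in enumerate(lick_keys):
            if key not in trial_keys:
                raise ValueError(f"licks.csv row {i}: unknown trial {key!r}")
    else:
        logger.warning("licks.csv is empty (lick-free session set)")
    eye_path = d / "eye.csv"
    eye = pd.read_csv(eye_path) if eye_path.exists() else None
    if eye is not None:
        _check_schema(eye, "eye.csv")
    gt_path = d / "ground_truth.json"
    ground_truth = json.loads(gt_path.read_text()) if gt_path.exists() else None
    logger.info("read bundle: %d trials, %d units, %d spikes, %d licks",
                len(events), len(units), len(spikes), len(licks))
    return SessionBundle(events, units, spikes, licks, eye, ground_truth)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """simulate -> classify -> behavior -> discriminability -> compare -> report.

    Writes the fixture files plus ``session_levels.csv``, ``behavior.csv``,
    ``auroc_results.csv``, ``comparisons.csv``, ``saccades.csv``,
    ``summary.json`` and the resolved config; returns the summary dict.
    Deterministic for a fixed config (incl. seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")
    master = np.random.SeedSequence(config.seed)
    s_sim, s_classify, s_analysis = master.spawn(3)

    # -- simulate -----------------------------------------------------------
    specs = config.cohort_specs()
    kernel = RateKernelParams(**config.kernel)
    gain_table = config.resolved_gain_table()
    sessions: list[SessionData] = []
    for spec, child in zip(specs, s_sim.spawn(len(specs))):
        sessions.extend(simulate_cohort(
            spec, child, base_params=kernel, gain_table=gain_table,
            with_eye=config.with_eye,
        ))
    write_session_bundle(sessions, out, include_eye=config.with_eye and config.write_eye)
    logger.info("simulated %d sessions", len(sessions))

    # -- classify sessions --------------------------------------------------
    records = [sd.record for sd in sessions]
    levels_df = session_classification.classify_sessions(
        records, _seed_int(s_classify),
        range_ms=tuple(config.classifier["range_ms"]),
        bin_ms=config.classifier["bin_ms"],
        n_neighbors=config.classifier["n_neighbors"],
        min_dist=config.classifier["min_dist"],
    )
    truth = {sd.record.session_id: sd.level for sd in sessions}
    levels_df["generator_level"] = levels_df["session_id"].map(truth)
    levels_df.to_csv(out / "session_levels.csv", index=False)
    assigned = dict(zip(levels_df["session_id"], levels_df["assigned_level"]))

    # -- behavior -----------------------------------------------------------
    beh_rows = []
    for sd in sessions:
        summ = behavior.score_session(
            sd.trials, sd.record.licks_by_trial,
            abort_on_anticipatory=(sd.level == "expert"),
        )
        summ.pop("outcomes")
        beh_rows.append({"session_id": sd.record.session_id,
                         "level": assigned[sd.record.session_id], **summ})
    behavior_df = pd.DataFrame(beh_rows)
    behavior_df.to_csv(out / "behavior.csv", index=False)

    # -- per-unit discriminability -----------------------------------------
    epoch_specs = [discriminability.epoch_spec("cue_onset"),
                   discriminability.epoch_spec("delay_spatial")]
    for cat in config.change_tilt_categories:
        epoch_specs.append(discriminability.epoch_spec(
            "change_onset", tilt_category=None if cat == "all" else cat))
    rng = np.random.default_rng(s_analysis)
    res_rows = []
    for sd in sessions:
        level = assigned[sd.record.session_id]
        for u in sd.units:
            for espec in epoch_specs:
                r = discriminability.epoch_discriminability(
                    u, sd.trials, espec, min_trials=config.min_trials,
                    n_boot=config.n_boot, rng_seed=rng,
                )
                if r is None:
                    continue
                res_rows.append({
                    "unit_id": r.unit_id, "session_id": r.session_id,
                    "layer": r.layer, "level": level, "epoch": r.epoch,
                    "tilt_category": r.tilt_category or "all",
                    "auroc": r.auroc, "ci_lo": r.ci_lo, "ci_hi": r.ci_hi,
                    "significance": r.significance,
                    "n_signal": r.n_signal_trials, "n_noise": r.n_noise_trials,
                })
    results_df = pd.DataFrame(res_rows)
    results_df.to_csv(out / "auroc_results.csv", index=False)

    # -- group comparisons --------------------------------------------------
    comparisons = group_comparison.compare_groups(
        results_df, n_perm=config.n_perm, rng_seed=rng, alpha=config.alpha,
    )
    comparisons.to_csv(out / "comparisons.csv", index=False)

    # -- saccades -----------------------------------------------------------
    sacc_rows, prob_rows = [], []
    masked_medians = {}
    if config.with_eye:
        all_sacc = {}
        for sd in sessions:
            if sd.eye is None:
                continue
            evts = eye_movements.detect_saccades(sd.eye)
            all_sacc[sd.record.session_id] = evts
            sacc_rows.extend({
                "session_id": e.session_id, "onset_s": e.onset_s,
                "duration_ms": e.duration_ms, "amplitude_deg": e.amplitude_deg,
                "peak_speed_dps": e.peak_speed_dps,
            } for e in evts)
            level = assigned[sd.record.session_id]
            change_trials = [t for t in sd.trials if t.is_change]
            for label, event, window in (
                ("cue_baseline", "cue_on", discriminability.WINDOWS_MS["cue_baseline"]),
                ("cue_response", "cue_on", discriminability.WINDOWS_MS["cue_response"]),
                ("delay", "change_on", discriminability.WINDOWS_MS["delay"]),
                ("change_response", "change_on", discriminability.WINDOWS_MS["change_response"]),
            ):
                times = np.array([getattr(t, "t_cue_on" if event == "cue_on" else "t_change_on")
                                  for t in change_trials])
                prob_rows.append({
                    "session_id": sd.record.session_id, "level": level, "interval": label,
                    "probability": eye_movements.interval_saccade_probability(evts, times, window),
                })
        if config.saccade_free_reanalysis and len(results_df):
            # cue-onset AROC medians recomputed on saccade-free trials
            windows = [("cue_on", discriminability.WINDOWS_MS["cue_baseline"]),
                       ("cue_on", discriminability.WINDOWS_MS["cue_response"])]
            for sd in sessions:
                evts = all_sacc.get(sd.record.session_id, [])
                mask = eye_movements.saccade_free_mask(evts, sd.trials, windows)
                kept = [t for t, ok in zip(sd.trials, mask) if ok]
                level = assigned[sd.record.session_id]
                for u in sd.units:
                    r = discriminability.epoch_discriminability(
                        u, kept, discriminability.epoch_spec("cue_onset"),
                        min_trials=config.min_trials, compute_ci=False,
                    )
                    if r is not None:
                        masked_medians.setdefault((level, u.layer), []).append(r.auroc)
    pd.DataFrame(sacc_rows, columns=["session_id", "onset_s", "duration_ms",
                                     "amplitude_deg", "peak_speed_dps"]
                 ).to_csv(out / "saccades.csv", index=False)
    pd.DataFrame(prob_rows, columns=["session_id", "level", "interval", "probability"]
                 ).to_csv(out / "saccade_prob.csv", index=False)

    # -- summary ------------------------------------------------------------
    medians = {}
    if len(results_df):
        for (epoch, layer, level, cat), grp in results_df.groupby(
                ["epoch", "layer", "level", "tilt_category"]):
            key = f"{epoch}/{layer}/{level}/{cat}"
            medians[key] = {
                "median_auroc": float(grp["auroc"].median()),
                "pct_positive": float(100 * (grp["significance"] == "positive").mean()),
                "pct_negative": float(100 * (grp["significance"] == "negative").mean()),
                "n_units": int(len(grp)),
            }
    summary = {
        "seed": config.seed,
        "n_sessions": len(sessions),
        "n_units": int(len(results_df["unit_id"].unique())) if len(results_df) else 0,
        "classification_agreement": float(
            (levels_df["assigned_level"] == levels_df["generator_level"]).mean()
        ),
        "behavior": {
            r["session_id"]: {k: r[k] for k in ("hit_rate", "false_alarm_rate",
                                                "dprime", "median_rt_ms")}
            for r in beh_rows
        },
        "auroc_medians": medians,
        "comparisons": comparisons.to_dict(orient="records"),
        "saccade_free_cue_medians": {
            f"{lvl}/{lay}": float(np.median(v)) for (lvl, lay), v in sorted(masked_medians.items())
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=float)
    return summary
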