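"""Dataset layout, CSV/JSON schemas and the end-to-end runner.

A simulated dataset is a directory of plain-text files::

    manifest.json               seed, config snapshot, schema version
    cohort.csv                  participant covariates + parameter snapshot
    design/{baseline,control,cued}.csv      one row per trial
    ball/{normal,bouncy}.csv + .events.json sampled trajectories + events
    streams/<pid>/<block>_motion.csv        90 Hz poses, all trials stacked
    streams/<pid>/<block>_gaze.csv          120 Hz gaze directions
    streams/<pid>/<block>_events.json       per-trial ground-truth events

``process_dataset`` runs the kinematic and gaze pipelines over every trial
and writes ``metrics/trial_metrics.csv`` plus the participant-by-condition
summary; ``analyze_dataset`` runs the statistical battery on those tables.
Every table carries a ``schema_version`` column and readers reject unknown
versions.  Times are seconds from ball launch; positions metres; angles
degrees.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import agent as agt
from . import design as dsn
from . import gaze as gz
from . import kinematics as kin
from . import physics as phy
from . import stats as st
from .config import RunConfig, SCHEMA_VERSION
from .summary import participant_condition_summary, summary_long_table

__all__ = [
    "write_block_csv",
    "read_block_csv",
    "simulate_dataset",
    "process_dataset",
    "analyze_dataset",
]

_FLOAT_FMT = "%.9g"


class SchemaError(ValueError):
    pass


def _json_default(o):
    if isinstance(o, (np.bool_, np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _check_version(df: pd.DataFrame, path) -> pd.DataFrame:
    if "schema_version" not in df.columns:
        raise SchemaError(f"{path}: missing schema_version column")
    versions = set(df["schema_version"].unique())
    if versions != {SCHEMA_VERSION}:
        raise SchemaError(f"{path}: unsupported schema_version {versions}")
    return df.drop(columns=["schema_version"])


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df = df.copy()
    df["schema_version"] = SCHEMA_VERSION
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# design serialization


def block_to_frame(block: dsn.BlockPlan) -> pd.DataFrame:
    rows = []
    for t in block.trials:
        rows.append({
            "trial_index": t.trial_index, "block_kind": block.block_kind,
            "level_id": t.level_id, "p_normal": t.p_normal,
            "ball_type": t.ball_type, "elasticity": t.elasticity,
            "cued": t.cued,
            "bouncy_pct": t.cue.bouncy_pct if t.cue else "",
            "label": t.cue.label if t.cue else "",
        })
    return pd.DataFrame(rows)


def write_block_csv(block: dsn.BlockPlan, path) -> None:
    _write_csv(block_to_frame(block), Path(path))


def read_block_csv(path) -> pd.DataFrame:
    return _check_version(pd.read_csv(path, keep_default_na=False,
                                      na_values=[]), path)


# ---------------------------------------------------------------------------
# simulate


def simulate_dataset(config: RunConfig, outdir) -> Path:
    """Generate a full synthetic dataset under ``outdir``.

    Deterministic in ``config.master_seed``: rerunning with the same config
    reproduces every file byte for byte.
    """
    config.validate()
    out = Path(outdir)
    (out / "design").mkdir(parents=True, exist_ok=True)
    (out / "ball").mkdir(exist_ok=True)
    (out / "streams").mkdir(exist_ok=True)

    presets = {g: agt.PRESETS[name] for g, name in config.group_presets.items()}
    cohort_rows = []
    first = True
    for rec in agt.iter_cohort(config.n_per_group, config.master_seed,
                               config.sequence_id, presets=presets):
        if first:
            for kind in ("baseline", "control", "cued"):
                write_block_csv(rec.blocks[kind][0], out / "design" / f"{kind}.csv")
            for ball_type in ("normal", "bouncy"):
                traj = phy.make_trajectory(
                    phy.ELASTICITY_BOUNCY if ball_type == "bouncy"
                    else phy.ELASTICITY_NORMAL)
                df = pd.DataFrame({"t": traj.t, "x": traj.pos[:, 0],
                                   "y": traj.pos[:, 1], "z": traj.pos[:, 2]})
                _write_csv(df, out / "ball" / f"{ball_type}.csv")
                with open(out / "ball" / f"{ball_type}.events.json", "w") as fh:
                    json.dump({"schema_version": SCHEMA_VERSION, **traj.events()},
                              fh, indent=1)
            first = False
        pdir = out / "streams" / rec.participant_id
        pdir.mkdir(exist_ok=True)
        for kind, (block, trials) in rec.blocks.items():
            motion = []
            gaze = []
            events = []
            for raw in trials:
                m = raw.motion.copy()
                m.insert(0, "trial_index", raw.trial.trial_index)
                motion.append(m)
                g = raw.gaze.copy()
                g.insert(0, "trial_index", raw.trial.trial_index)
                gaze.append(g)
                events.append({"trial_index": raw.trial.trial_index,
                               **raw.events, "truth": raw.truth})
            _write_csv(pd.concat(motion, ignore_index=True),
                       pdir / f"{kind}_motion.csv")
            _write_csv(pd.concat(gaze, ignore_index=True),
                       pdir / f"{kind}_gaze.csv")
            with open(pdir / f"{kind}_events.json", "w") as fh:
                json.dump({"schema_version": SCHEMA_VERSION, "trials": events},
                          fh, indent=0)
        cohort_rows.append({
            "participant_id": rec.participant_id, "group": rec.group,
            "handedness": rec.handedness, "AQ_total": rec.aq_total,
            "IUS_total": rec.ius_total,
            "target_rate_pct": rec.target_rate_pct,
            "params_json": json.dumps(dataclasses.asdict(rec.params),
                                      sort_keys=True),
        })
        rec.blocks.clear()  # free streams as we go
    _write_csv(pd.DataFrame(cohort_rows), out / "cohort.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump({"schema_version": SCHEMA_VERSION,
                   "seed": config.master_seed,
                   "config": config.to_dict()}, fh, indent=1, sort_keys=True)
    return out


# ---------------------------------------------------------------------------
# process


def process_dataset(dataset_dir, outdir=None) -> Path:
    """Run both extraction pipelines over every trial of a dataset.

    Malformed or missing trial streams are skipped with a logged reason;
    the run continues.  Writes ``trial_metrics.csv``,
    ``participant_summary.csv`` and ``exclusions.csv``.
    """
    root = Path(dataset_dir)
    out = Path(outdir) if outdir else root / "metrics"
    out.mkdir(parents=True, exist_ok=True)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError("unsupported dataset schema_version")
    cfg = RunConfig(**manifest["config"])

    cohort = _check_version(pd.read_csv(root / "cohort.csv"), "cohort.csv")
    design = {kind: read_block_csv(root / "design" / f"{kind}.csv")
              for kind in ("baseline", "control", "cued")}
    trajs = {
        "normal": phy.make_trajectory(phy.ELASTICITY_NORMAL),
        "bouncy": phy.make_trajectory(phy.ELASTICITY_BOUNCY),
    }
    rows = []
    exclusions = []
    for _, person in cohort.iterrows():
        pid, group = person["participant_id"], person["group"]
        pdir = root / "streams" / pid
        for kind, block_df in design.items():
            try:
                motion = _check_version(
                    pd.read_csv(pdir / f"{kind}_motion.csv"), pdir)
                gaze_all = _check_version(
                    pd.read_csv(pdir / f"{kind}_gaze.csv"), pdir)
            except (OSError, SchemaError) as e:
                exclusions.append({"participant_id": pid, "block": kind,
                                   "trial_index": -1, "stage": "io",
                                   "reason": str(e)})
                continue
            m_groups = dict(tuple(motion.groupby("trial_index")))
            g_groups = dict(tuple(gaze_all.groupby("trial_index")))
            for _, trial in block_df.iterrows():
                ti = int(trial["trial_index"])
                traj = trajs[trial["ball_type"]]
                row = {
                    "participant_id": pid, "group": group, "block": kind,
                    "trial_index": ti, "ball_type": trial["ball_type"],
                    "AQ_total": person["AQ_total"],
                    "IUS_total": person["IUS_total"],
                }
                m = m_groups.get(ti)
                g = g_groups.get(ti)
                if m is None or g is None:
                    exclusions.append({"participant_id": pid, "block": kind,
                                       "trial_index": ti, "stage": "io",
                                       "reason": "missing stream"})
                    continue
                km = kin.process_trial(m.drop(columns="trial_index"),
                                       traj, rom_mode=cfg.rom_mode)
                row.update({
                    "intercepted": km.intercepted,
                    "kinematic_flagged": km.flagged,
                    "peak_velocity": km.peak_velocity, "rom": km.rom,
                    "t_contact": km.t_contact,
                })
                if km.flagged:
                    exclusions.append({"participant_id": pid, "block": kind,
                                       "trial_index": ti, "stage": "kinematics",
                                       "reason": km.flag_reason})
                gm = gz.process_trial(g.drop(columns="trial_index"),
                                      m.drop(columns="trial_index"),
                                      t_bounce=traj.t_bounce)
                row.update({
                    "gaze_excluded": gm.excluded,
                    "fixation_onset": gm.onset_rel_launch,
                    "fixation_duration": gm.duration,
                    "fixation_pitch": gm.pitch,
                })
                if gm.excluded:
                    exclusions.append({"participant_id": pid, "block": kind,
                                       "trial_index": ti, "stage": "gaze",
                                       "reason": gm.reason})
                rows.append(row)
    trial_metrics = pd.DataFrame(rows)
    _write_csv(trial_metrics, out / "trial_metrics.csv")
    summary = participant_condition_summary(trial_metrics)
    _write_csv(summary, out / "participant_summary.csv")
    _write_csv(pd.DataFrame(exclusions,
                            columns=["participant_id", "block", "trial_index",
                                     "stage", "reason"]),
               out / "exclusions.csv")
    return out


# ---------------------------------------------------------------------------
# analyze


def analyze_dataset(metrics_dir, outdir=None) -> Path:
    """Run the full statistical battery on processed metrics tables."""
    mdir = Path(metrics_dir)
    if not (mdir / "participant_summary.csv").exists() and (mdir / "metrics").exists():
        mdir = mdir / "metrics"
    out = Path(outdir) if outdir else mdir
    out.mkdir(parents=True, exist_ok=True)
    summary = _check_version(pd.read_csv(mdir / "participant_summary.csv"),
                             mdir)
    long = summary_long_table(summary)
    report = st.run_full_battery(long)
    with open(out / "results.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
    _write_csv(_flatten_results(report), out / "results.csv")
    with open(out / "results.txt", "w") as fh:
        fh.write(_format_report(report))
    return out


def _iter_statresults(report):
    if report.get("manipulation_check"):
        yield "manipulation_check", report["manipulation_check"]
    for outcome, block in report.get("outcomes", {}).items():
        for eff, r in (block.get("anova") or {}).items():
            yield f"anova:{eff}", r
        for r in block.get("posthoc") or []:
            yield "posthoc", r
        for r in block.get("correlations") or []:
            yield "correlation", r


def _flatten_results(report) -> pd.DataFrame:
    rows = []
    for kind, r in _iter_statresults(report):
        rows.append({"kind": kind, **{k: (json.dumps(v) if isinstance(v, list)
                                          else v)
                                      for k, v in r.items()}})
    return pd.DataFrame(rows)


def _format_report(report) -> str:
    lines = ["Virtual racquetball: statistical report", "=" * 40]
    mc = report.get("manipulation_check")
    if mc:
        lines.append(
            f"Manipulation check (bounce-fixation pitch, control vs baseline): "
            f"t({mc['df'][0]}) = {mc['value']:.2f}, p = {mc['p']:.4g}, "
            f"BF10 = {mc['bf10']:.3g}")
    for outcome, block in report.get("outcomes", {}).items():
        lines.append("")
        lines.append(outcome)
        lines.append("-" * len(outcome))
        if block.get("absent"):
            lines.append("  (outcome absent)")
            continue
        if block.get("error"):
            lines.append(f"  error: {block['error']}")
            continue
        for eff, r in block.get("anova", {}).items():
            if r["value"] is None:
                lines.append(f"  {eff}: degenerate")
                continue
            lines.append(
                f"  {eff}: F({r['df'][0]},{r['df'][1]}) = {r['value']:.2f}, "
                f"p = {r['p']:.4g}, pes = {r['effect_size']:.3f}, "
                f"BF10 = {r['bf10']:.3g}" if r["bf10"] is not None else
                f"  {eff}: F({r['df'][0]},{r['df'][1]}) = {r['value']:.2f}, "
                f"p = {r['p']:.4g}")
        for r in block.get("posthoc") or []:
            lines.append(
                f"  posthoc {r['name']}: {r['statistic']} = {r['value']:.2f}, "
                f"p_bonf = {r['p']:.4g}")
    return "\n".join(lines) + "\n"


def run_all(config: RunConfig, outdir) -> Path:
    """simulate -> process -> analyze in one call."""
    ds = simulate_dataset(config, outdir)
    metrics = process_dataset(ds)
    return analyze_dataset(metrics)
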