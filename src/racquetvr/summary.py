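"""Aggregation of per-trial metrics into participant-by-condition summaries
and the long outcome table the statistical battery consumes."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["participant_condition_summary", "summary_long_table"]

#: per-trial metric columns expected from the pipelines (or the fast
#: metrics-level simulator)
TRIAL_COLUMNS = [
    "participant_id", "group", "block", "trial_index", "intercepted",
    "kinematic_flagged", "peak_velocity", "rom", "gaze_excluded",
    "fixation_onset", "fixation_duration", "fixation_pitch",
]


def participant_condition_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """One row per participant x block with the seven outcome measures.

    Kinematic outcomes average over unflagged trials; gaze outcomes follow
    the aggregation rules of the gaze pipeline (median onset, mean duration,
    mean pitch, trial-to-trial pitch SD over unexcluded trials carrying a
    bounce fixation; cells with fewer than 2 usable trials are missing).
    """
    rows = []
    for (pid, block), sub in trials.groupby(["participant_id", "block"], sort=False):
        kin = sub[~sub["kinematic_flagged"].astype(bool)]
        ok = kin["intercepted"].notna()
        rate = 100.0 * kin.loc[ok, "intercepted"].astype(bool).mean() if ok.any() else np.nan
        gz = sub[~sub["gaze_excluded"].astype(bool)].dropna(subset=["fixation_pitch"])
        enough = len(gz) >= 2
        row = {
            "participant_id": pid,
            "block": block,
            "group": sub["group"].iloc[0],
            "interception_rate": rate,
            "peak_velocity": kin["peak_velocity"].mean(),
            "rom": kin["rom"].mean(),
            "fixation_onset": gz["fixation_onset"].median() if enough else np.nan,
            "fixation_duration": gz["fixation_duration"].mean() if enough else np.nan,
            "fixation_pitch": gz["fixation_pitch"].mean() if enough else np.nan,
            "fixation_pitch_sd": gz["fixation_pitch"].std(ddof=1) if enough else np.nan,
            "n_gaze_trials": len(gz),
            "n_kinematic_trials": int((~sub["kinematic_flagged"].astype(bool)).sum()),
        }
        for cov in ("AQ_total", "IUS_total"):
            if cov in sub.columns:
                row[cov] = sub[cov].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def summary_long_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Wide participant-by-block summary -> long (outcome_name, value) rows
    with condition labels, as consumed by the statistical battery."""
    outcome_cols = [
        "interception_rate", "peak_velocity", "rom", "fixation_onset",
        "fixation_duration", "fixation_pitch", "fixation_pitch_sd",
    ]
    id_cols = ["participant_id", "group", "block"]
    for cov in ("AQ_total", "IUS_total"):
        if cov in summary.columns:
            id_cols.append(cov)
    long = summary.melt(id_vars=id_cols, value_vars=outcome_cols,
                        var_name="outcome_name", value_name="value")
    long = long.rename(columns={"block": "condition"})
    return long.dropna(subset=["value"]).reset_index(drop=True)
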