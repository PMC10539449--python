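"""Gaze processing: head-centred angles, I-DT fixations, bounce-fixation
metrics and trial exclusion.

Gaze direction samples (120 Hz world-frame unit vectors) are expressed in
head-centred egocentric coordinates (yaw = signed horizontal angle from the
head's facing axis, pitch = signed vertical angle, degrees), smoothed with
a three-frame median filter followed by a second-order zero-phase
Butterworth low-pass at 15 Hz, and segmented with a dispersion-threshold
(I-DT) algorithm: maximal windows in which gaze stays within a 3 deg area
for at least 100 ms.  Trials lose their gaze metrics when tracking was lost
for more than 100 ms contiguously or more than 20% of samples are missing
(strict inequalities in both rules).

The *bounce fixation* is the fixation intersecting the +-0.1 s window
around the bounce (latest onset wins on ties) or, failing that, the
fixation ending most recently before the bounce (bounded lookback).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, medfilt

from .kinematics import FilterError

__all__ = [
    "EgocentricGaze",
    "Fixation",
    "GazeTrialMetrics",
    "to_egocentric",
    "smooth_gaze",
    "detect_fixations",
    "exclude_trial",
    "bounce_fixation",
    "aggregate_gaze",
    "process_trial",
]

GAZE_CUTOFF_HZ = 15.0
DISPERSION_MAX_DEG = 3.0
MIN_FIX_DURATION_S = 0.100
GAP_MAX_S = 0.100
MISSING_MAX_FRAC = 0.20
BOUNCE_WINDOW_S = 0.100
#: how far before the bounce the "immediately prior" branch may reach
PRIOR_LOOKBACK_S = 0.500


@dataclass
class EgocentricGaze:
    """Gaze in head-centred angles: DataFrame(t, yaw, pitch, valid)."""

    samples: pd.DataFrame

    def __post_init__(self):
        missing = {"t", "yaw", "pitch", "valid"} - set(self.samples.columns)
        if missing:
            raise ValueError(f"EgocentricGaze missing columns: {missing}")


@dataclass(frozen=True)
class Fixation:
    t_onset: float
    duration: float
    centroid_yaw: float
    centroid_pitch: float

    @property
    def t_offset(self) -> float:
        return self.t_onset + self.duration


@dataclass
class GazeTrialMetrics:
    excluded: bool
    reason: str = ""
    bounce_fix: Optional[Fixation] = None
    onset_rel_launch: Optional[float] = None
    duration: Optional[float] = None
    pitch: Optional[float] = None


def _head_rotation(yaw_deg, pitch_deg):
    """World-from-head rotation: yaw about world +y (+ toward +x), then
    pitch about the head's +x (+ looking up)."""
    cy, sy = np.cos(np.radians(yaw_deg)), np.sin(np.radians(yaw_deg))
    cp, sp = np.cos(np.radians(pitch_deg)), np.sin(np.radians(pitch_deg))
    # R = Ry(yaw) @ Rx(pitch); positive pitch tilts the facing axis upward
    r = np.empty((len(np.atleast_1d(cy)), 3, 3))
    r[:, 0, 0] = cy
    r[:, 0, 1] = -sy * sp
    r[:, 0, 2] = sy * cp
    r[:, 1, 0] = 0.0
    r[:, 1, 1] = cp
    r[:, 1, 2] = sp
    r[:, 2, 0] = -sy
    r[:, 2, 1] = -cy * sp
    r[:, 2, 2] = cy * cp
    return r


def to_egocentric(gaze: pd.DataFrame, head: pd.DataFrame) -> EgocentricGaze:
    """Express world-frame gaze directions in the head frame.

    Head orientation (yaw/pitch, 90 Hz) is linearly interpolated to the
    gaze clock; invalid samples propagate with valid=False.
    """
    tg = gaze["t"].to_numpy()
    th = head["t"].to_numpy()
    hyaw = np.interp(tg, th, head["hyaw"].to_numpy(dtype=float))
    hpitch = np.interp(tg, th, head["hpitch"].to_numpy(dtype=float))
    g = gaze[["gx", "gy", "gz"]].to_numpy(dtype=float)
    R = _head_rotation(hyaw, hpitch)
    # ego = R^T @ g  per sample
    ego = np.einsum("nij,ni->nj", R, g)
    yaw = np.degrees(np.arctan2(ego[:, 0], ego[:, 2]))
    pitch = np.degrees(np.arctan2(ego[:, 1], np.hypot(ego[:, 0], ego[:, 2])))
    valid = gaze["valid"].to_numpy(dtype=bool) if "valid" in gaze else np.ones(len(tg), bool)
    return EgocentricGaze(pd.DataFrame({"t": tg, "yaw": yaw, "pitch": pitch,
                                        "valid": valid}))


def _smooth_channel(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    med = medfilt(x, kernel_size=3)
    b, a = butter(2, cutoff / (fs / 2.0), btype="low")
    padlen = 3 * max(len(a), len(b))
    if len(med) <= padlen:
        return med  # too short for the IIR stage: median-only
    return filtfilt(b, a, med)


def smooth_gaze(angles: EgocentricGaze, cutoff: float = GAZE_CUTOFF_HZ) -> EgocentricGaze:
    """Three-frame median then second-order zero-phase Butterworth at 15 Hz.

    Invalid samples are excluded from the filter windows (each contiguous
    valid segment is filtered on its own), never zero-filled.  Yaw is
    unwrapped before filtering to avoid +-180 deg seam artefacts.
    """
    df = angles.samples
    t = df["t"].to_numpy()
    if len(t) < 4:
        raise FilterError("gaze stream shorter than the smoothing warm-up")
    fs = 1.0 / (t[1] - t[0])
    yaw = df["yaw"].to_numpy(dtype=float).copy()
    pitch = df["pitch"].to_numpy(dtype=float).copy()
    valid = df["valid"].to_numpy(dtype=bool)
    idx = np.nonzero(valid)[0]
    if len(idx) == 0:
        return EgocentricGaze(df.copy())
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    for seg in np.split(idx, breaks + 1):
        if len(seg) < 3:
            continue
        yw = np.degrees(np.unwrap(np.radians(yaw[seg])))
        yaw[seg] = _smooth_channel(yw, fs, cutoff)
        pitch[seg] = _smooth_channel(pitch[seg], fs, cutoff)
    yaw = (yaw + 180.0) % 360.0 - 180.0
    return EgocentricGaze(pd.DataFrame({"t": t, "yaw": yaw, "pitch": pitch,
                                        "valid": valid}))


def _dispersion_pairwise(yaw, pitch) -> float:
    """Maximum pairwise separation (small-angle Euclidean on yaw/pitch)."""
    dy = yaw[:, None] - yaw[None, :]
    dp = pitch[:, None] - pitch[None, :]
    return float(np.sqrt(dy**2 + dp**2).max())


def detect_fixations(angles: EgocentricGaze,
                     dispersion_max: float = DISPERSION_MAX_DEG,
                     min_duration: float = MIN_FIX_DURATION_S,
                     metric: str = "pairwise") -> list[Fixation]:
    """Dispersion-threshold (I-DT) fixation detection.

    Grows a window while its dispersion stays within ``dispersion_max``;
    maximal windows spanning at least ``min_duration`` are emitted as
    fixations (non-overlapping, time-ordered).  ``metric`` selects the
    dispersion measure: "pairwise" (max pairwise angular separation,
    default) or "bbox" ((max-min)_yaw + (max-min)_pitch).  Invalid samples
    break windows.
    """
    df = angles.samples
    t = df["t"].to_numpy()
    yaw = df["yaw"].to_numpy(dtype=float)
    pitch = df["pitch"].to_numpy(dtype=float)
    valid = df["valid"].to_numpy(dtype=bool)
    fixations: list[Fixation] = []
    idx = np.nonzero(valid)[0]
    if len(idx) == 0:
        return fixations
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    for seg in np.split(idx, breaks + 1):
        fixations.extend(
            _idt_segment(t[seg], yaw[seg], pitch[seg], dispersion_max,
                         min_duration, metric))
    return fixations


def _idt_segment(t, yaw, pitch, dmax, min_dur, metric) -> list[Fixation]:
    n = len(t)
    out = []
    i = 0
    while i < n:
        j = i  # window [i, j] inclusive
        if metric == "bbox":
            ylo = yhi = yaw[i]
            plo = phi_ = pitch[i]
            while j + 1 < n:
                ny_lo, ny_hi = min(ylo, yaw[j + 1]), max(yhi, yaw[j + 1])
                np_lo, np_hi = min(plo, pitch[j + 1]), max(phi_, pitch[j + 1])
                if (ny_hi - ny_lo) + (np_hi - np_lo) <= dmax:
                    ylo, yhi, plo, phi_ = ny_lo, ny_hi, np_lo, np_hi
                    j += 1
                else:
                    break
        elif metric == "pairwise":
            cur = 0.0  # running max pairwise separation in the window
            while j + 1 < n:
                dy = yaw[i:j + 1] - yaw[j + 1]
                dp = pitch[i:j + 1] - pitch[j + 1]
                cand = max(cur, float(np.sqrt(dy**2 + dp**2).max()))
                if cand <= dmax:
                    cur = cand
                    j += 1
                else:
                    break
        else:
            raise ValueError(f"unknown dispersion metric: {metric}")
        if t[j] - t[i] >= min_dur:
            out.append(Fixation(
                t_onset=float(t[i]), duration=float(t[j] - t[i]),
                centroid_yaw=float(yaw[i:j + 1].mean()),
                centroid_pitch=float(pitch[i:j + 1].mean()),
            ))
            i = j + 1
        else:
            i += 1
    return out


def exclude_trial(gaze: pd.DataFrame, gap_max_s: float = GAP_MAX_S,
                  missing_max_frac: float = MISSING_MAX_FRAC):
    """Trial-level gaze exclusion (strict inequalities).

    Excluded iff any contiguous invalid run lasts more than ``gap_max_s``
    OR the invalid fraction exceeds ``missing_max_frac``.
    """
    valid = gaze["valid"].to_numpy(dtype=bool)
    n = len(valid)
    if n == 0:
        return True, "empty stream"
    t = gaze["t"].to_numpy()
    dt = (t[-1] - t[0]) / (n - 1) if n > 1 else 0.0
    frac = 1.0 - valid.mean()
    if frac > missing_max_frac:
        return True, f"missing fraction {frac:.1%} > {missing_max_frac:.0%}"
    run = longest = 0
    for v in valid:
        run = 0 if v else run + 1
        longest = max(longest, run)
    if longest * dt > gap_max_s:
        return True, f"tracking lost for {longest * dt * 1000:.0f} ms > {gap_max_s * 1000:.0f} ms"
    return False, ""


def bounce_fixation(fixations: list[Fixation], t_bounce: float,
                    window: float = BOUNCE_WINDOW_S,
                    lookback: float = PRIOR_LOOKBACK_S) -> Optional[Fixation]:
    """Select the predictive bounce fixation.

    Preference: fixations whose interval intersects
    [t_bounce - window, t_bounce + window], latest onset first; otherwise
    the fixation with the latest offset strictly before the bounce (within
    ``lookback``); otherwise None.
    """
    lo, hi = t_bounce - window, t_bounce + window
    hits = [f for f in fixations if f.t_onset <= hi and f.t_offset >= lo]
    if hits:
        return max(hits, key=lambda f: f.t_onset)
    prior = [f for f in fixations
             if f.t_offset < t_bounce and f.t_offset >= t_bounce - lookback]
    if prior:
        return max(prior, key=lambda f: f.t_offset)
    return None


def process_trial(gaze: pd.DataFrame, head: pd.DataFrame, t_bounce: float,
                  t_launch: float = 0.0) -> GazeTrialMetrics:
    """Full gaze pipeline for one trial: exclusion, egocentric conversion,
    smoothing, fixation detection and bounce-fixation metrics."""
    excluded, reason = exclude_trial(gaze)
    if excluded:
        return GazeTrialMetrics(excluded=True, reason=reason)
    try:
        ego = smooth_gaze(to_egocentric(gaze, head))
    except FilterError as e:
        return GazeTrialMetrics(excluded=True, reason=str(e))
    fixations = detect_fixations(ego)
    fix = bounce_fixation(fixations, t_bounce)
    if fix is None:
        return GazeTrialMetrics(excluded=False, reason="no bounce fixation")
    return GazeTrialMetrics(
        excluded=False, bounce_fix=fix,
        onset_rel_launch=fix.t_onset - t_launch,
        duration=fix.duration, pitch=fix.centroid_pitch,
    )


def aggregate_gaze(trials: list[GazeTrialMetrics]):
    """Participant-by-condition gaze summary.

    Over unexcluded trials with a bounce fixation: median onset (relative
    to launch), mean duration, mean pitch, and the sample SD of pitch
    (trial-to-trial fixation-location variability).  Fewer than 2 usable
    trials yields None (missing cell).
    """
    usable = [m for m in trials if not m.excluded and m.bounce_fix is not None]
    if len(usable) < 2:
        return None
    onsets = np.array([m.onset_rel_launch for m in usable])
    durs = np.array([m.duration for m in usable])
    pitches = np.array([m.pitch for m in usable])
    return {
        "fixation_onset": float(np.median(onsets)),
        "fixation_duration": float(durs.mean()),
        "fixation_pitch": float(pitches.mean()),
        "fixation_pitch_sd": float(pitches.std(ddof=1)),
        "n_trials": len(usable),
    }
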