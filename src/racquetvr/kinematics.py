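"""Interception, peak velocity and range of motion from raw motion streams.

Hand-controller positions are smoothed with a dual-pass, zero-phase
Butterworth low-pass at 10 Hz (order 2 per pass, 4th-order effective)
before any differentiation.  The *foreswing* runs from the first forward
racquet motion to ball contact (or, on misses, to the last sample at which
the ball's depth still exceeded the racquet's).  Peak velocity is the
maximum toward-target (+z) component of central-difference velocity inside
that window; range of motion (ROM) is the maximum transverse-plane angle
between the headset's facing direction and the head-to-hand displacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from . import physics as phy

__all__ = [
    "FilterError",
    "ForeswingWindow",
    "KinematicTrialMetrics",
    "smooth_motion",
    "detect_foreswing",
    "detect_interception",
    "peak_velocity",
    "range_of_motion",
    "interception_rate",
    "process_trial",
]

MOTION_CUTOFF_HZ = 10.0
#: forward-motion onset threshold (m/s) sustained for K samples (~33 ms @90 Hz)
V_THRESH = 0.2
K_SUSTAIN = 3
RACQUET_HALFEXT = np.array([0.3, 0.15, 0.005])


class FilterError(ValueError):
    """Stream too short for the zero-phase filter warm-up."""


@dataclass(frozen=True)
class ForeswingWindow:
    t_onset: float
    t_offset: float
    offset_kind: str  # "contact" | "ball_passed"

    def __post_init__(self):
        if self.t_onset >= self.t_offset:
            raise ValueError("foreswing onset must precede its offset")


@dataclass
class KinematicTrialMetrics:
    intercepted: Optional[bool]
    t_contact: Optional[float]
    peak_velocity: Optional[float]
    rom: Optional[float]
    foreswing: Optional[ForeswingWindow]
    flagged: bool = False
    flag_reason: str = ""


def _filtfilt(x: np.ndarray, fs: float, cutoff: float, order: int = 2) -> np.ndarray:
    b, a = butter(order, cutoff / (fs / 2.0), btype="low")
    padlen = 3 * max(len(a), len(b))
    if len(x) <= padlen:
        raise FilterError(f"stream of {len(x)} samples shorter than filter warm-up")
    return filtfilt(b, a, x)


def _sample_rate(t: np.ndarray) -> float:
    dt = np.diff(t)
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise FilterError("stream must be uniformly sampled")
    return 1.0 / dt[0]


def smooth_motion(stream: pd.DataFrame, cutoff: float = MOTION_CUTOFF_HZ) -> pd.DataFrame:
    """Dual-pass zero-phase Butterworth smoothing of every pose channel."""
    fs = _sample_rate(stream["t"].to_numpy())
    out = stream.copy()
    for col in stream.columns:
        if col == "t":
            continue
        out[col] = _filtfilt(stream[col].to_numpy(dtype=float), fs, cutoff)
    return out


def _central_diff(x: np.ndarray, dt: float) -> np.ndarray:
    v = np.empty_like(x)
    v[1:-1] = (x[2:] - x[:-2]) / (2 * dt)
    v[0] = (x[1] - x[0]) / dt
    v[-1] = (x[-1] - x[-2]) / dt
    return v


def detect_foreswing(hand: pd.DataFrame, ball: phy.BallTrajectory,
                     contact: Optional[float] = None,
                     v_thresh: float = V_THRESH,
                     k_sustain: int = K_SUSTAIN) -> Optional[ForeswingWindow]:
    """Locate the foreswing on a smoothed hand stream.

    Onset: first sample of the last pre-offset run in which forward (+z)
    velocity exceeds ``v_thresh`` for at least ``k_sustain`` consecutive
    samples.  Offset: the contact time when one is given, otherwise the
    final sample at which the ball's depth exceeded the racquet's.
    Returns None (the trial is flagged, not an exception) when no forward
    motion is found.
    """
    t = hand["t"].to_numpy()
    z = hand["cz"].to_numpy(dtype=float)
    dt = t[1] - t[0]
    vz = _central_diff(z, dt)

    if contact is not None:
        t_off = float(contact)
        kind = "contact"
    else:
        tt = np.clip(t, ball.t_launch, ball.t_end)
        ball_z = phy.ball_state_at(ball, tt)[0][:, 2]
        in_span = (t >= ball.t_launch) & (t <= ball.t_end)
        ahead = in_span & (ball_z > z)
        if not ahead.any():
            return None
        t_off = float(t[np.nonzero(ahead)[0][-1]])
        kind = "ball_passed"

    mask = (vz > v_thresh) & (t < t_off)
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return None
    # split into consecutive runs, keep the last of length >= k_sustain
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    runs = np.split(idx, breaks + 1)
    runs = [r for r in runs if len(r) >= k_sustain]
    if not runs:
        return None
    onset = float(t[runs[-1][0]])
    if onset >= t_off:
        return None
    return ForeswingWindow(t_onset=onset, t_offset=t_off, offset_kind=kind)


def detect_interception(hand: pd.DataFrame, ball: phy.BallTrajectory,
                        racquet_halfext: np.ndarray = RACQUET_HALFEXT,
                        ball_radius: float = phy.BALL_RADIUS,
                        resolution_hz: float = 1000.0):
    """First time the ball centre enters the racquet box inflated by the
    ball radius (closed boundary).  The pose stream is linearly upsampled
    so brief crossings between motion samples are not missed.

    The stream schema carries no controller orientation, so the racquet box
    is axis-aligned with its face normal toward the front wall -- the
    orientation in which the task presents it.
    """
    t = hand["t"].to_numpy()
    lo = max(t[0], ball.t_launch)
    hi = min(t[-1], ball.t_end)
    if hi <= lo:
        return False, None
    tq = np.arange(lo, hi, 1.0 / resolution_hz)
    hx = np.interp(tq, t, hand["cx"].to_numpy(dtype=float))
    hy = np.interp(tq, t, hand["cy"].to_numpy(dtype=float))
    hz = np.interp(tq, t, hand["cz"].to_numpy(dtype=float))
    bp = phy.ball_state_at(ball, tq)[0]
    inflate = racquet_halfext + ball_radius
    inside = ((np.abs(bp[:, 0] - hx) <= inflate[0])
              & (np.abs(bp[:, 1] - hy) <= inflate[1])
              & (np.abs(bp[:, 2] - hz) <= inflate[2]))
    if not inside.any():
        return False, None
    return True, float(tq[int(np.argmax(inside))])


def peak_velocity(hand: pd.DataFrame, window: ForeswingWindow) -> Optional[float]:
    """Maximum +z (toward-target) central-difference velocity in the
    window; negative maxima floor at 0.  Windows under 3 samples flag."""
    t = hand["t"].to_numpy()
    z = hand["cz"].to_numpy(dtype=float)
    dt = t[1] - t[0]
    vz = _central_diff(z, dt)
    sel = (t >= window.t_onset) & (t <= window.t_offset)
    if sel.sum() < 3:
        return None
    return float(max(0.0, vz[sel].max()))


def _transverse_angle(facing_xz: np.ndarray, disp_xz: np.ndarray) -> np.ndarray:
    """Unsigned horizontal-plane angle (deg) between two 2-vectors per row;
    NaN where either projects to (near) zero length."""
    nf = np.linalg.norm(facing_xz, axis=1)
    nd = np.linalg.norm(disp_xz, axis=1)
    ok = (nf > 1e-9) & (nd > 1e-9)
    cosang = np.full(len(nf), np.nan)
    dot = np.einsum("ij,ij->i", facing_xz, disp_xz)
    cosang[ok] = np.clip(dot[ok] / (nf[ok] * nd[ok]), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def range_of_motion(head: pd.DataFrame, hand: pd.DataFrame,
                    window: ForeswingWindow,
                    mode: str = "facing_vs_displacement") -> Optional[float]:
    """Maximum transverse-plane angular deviation between headset and hand
    over the foreswing window.

    ``facing_vs_displacement`` (default): per sample, the horizontal angle
    between the headset's facing direction and the head-to-hand vector.
    ``hand_azimuth_range``: alternative reading -- the total azimuthal range
    swept by the head-to-hand vector within the window.
    Samples whose projected vectors vanish are skipped; an all-skipped
    window returns None (flagged).
    """
    t = head["t"].to_numpy()
    sel = (t >= window.t_onset) & (t <= window.t_offset)
    if not sel.any():
        return None
    yaw = np.radians(head["hyaw"].to_numpy(dtype=float)[sel])
    facing = np.column_stack([np.sin(yaw), np.cos(yaw)])
    dx = hand["cx"].to_numpy(dtype=float)[sel] - head["hx"].to_numpy(dtype=float)[sel]
    dz = hand["cz"].to_numpy(dtype=float)[sel] - head["hz"].to_numpy(dtype=float)[sel]
    disp = np.column_stack([dx, dz])
    if mode == "facing_vs_displacement":
        ang = _transverse_angle(facing, disp)
        if np.all(np.isnan(ang)):
            return None
        return float(np.nanmax(ang))
    elif mode == "hand_azimuth_range":
        az = np.degrees(np.arctan2(disp[:, 0], disp[:, 1]))
        return float(np.nanmax(az) - np.nanmin(az))
    raise ValueError(f"unknown ROM mode: {mode}")


def interception_rate(trials) -> Optional[float]:
    """Percentage of unflagged trials intercepted; None when all flagged."""
    hits = total = 0
    for m in trials:
        flagged = m.flagged if isinstance(m, KinematicTrialMetrics) else m.get("flagged", False)
        hit = m.intercepted if isinstance(m, KinematicTrialMetrics) else m.get("intercepted")
        if flagged or hit is None:
            continue
        total += 1
        hits += bool(hit)
    if total == 0:
        return None
    return 100.0 * hits / total


def process_trial(motion: pd.DataFrame, ball: phy.BallTrajectory,
                  rom_mode: str = "facing_vs_displacement") -> KinematicTrialMetrics:
    """Full kinematic pipeline for one trial: smooth, detect contact and the
    foreswing, then extract peak velocity and ROM."""
    try:
        smoothed = smooth_motion(motion)
    except FilterError as e:
        return KinematicTrialMetrics(None, None, None, None, None,
                                     flagged=True, flag_reason=str(e))
    hand = smoothed[["t", "cx", "cy", "cz"]]
    head = smoothed[["t", "hx", "hy", "hz", "hyaw", "hpitch"]]
    intercepted, t_contact = detect_interception(hand, ball)
    window = detect_foreswing(hand, ball, contact=t_contact)
    if window is None:
        return KinematicTrialMetrics(intercepted, t_contact, None, None, None,
                                     flagged=True, flag_reason="no foreswing detected")
    pv = peak_velocity(hand, window)
    rom = range_of_motion(head, hand, window, mode=rom_mode)
    flagged = pv is None or rom is None
    return KinematicTrialMetrics(intercepted, t_contact, pv, rom, window,
                                 flagged=flagged,
                                 flag_reason="degenerate window" if flagged else "")
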