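"""Deterministic projectile-and-bounce simulation of the task ball.

World frame convention (used package-wide): the origin sits on the floor at
the participant's prescribed starting position, +z points toward the front
wall, +y points up, and +x points toward the participant's dominant side.
All angles elsewhere in the package are reported in degrees; this module
works in metres and seconds.

The ball is launched from the front-wall plane at a fixed height and follows
a drag-free ballistic arc to a fixed bounce point.  Its vertical speed at
the moment of bounce is pinned (|vz| = 9 m/s downward), which together with
the launch height determines the launch velocity in closed form.  At the
bounce the vertical velocity is reflected and scaled by the coefficient of
restitution (the "elasticity": 0.65 for normal balls, 0.85 for bouncy
balls); horizontal velocity is unaffected.  Pre-bounce motion is therefore
identical for both ball types -- the two trajectories only separate at the
instant of floor contact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GRAVITY",
    "ELASTICITY_NORMAL",
    "ELASTICITY_BOUNCY",
    "BALL_RADIUS",
    "PhysicsError",
    "LaunchSpec",
    "BallTrajectory",
    "solve_launch",
    "simulate_trajectory",
    "ball_state_at",
    "bounce_apex",
]

GRAVITY = -9.8  # m/s^2
ELASTICITY_NORMAL = 0.65
ELASTICITY_BOUNCY = 0.85
#: standard tennis-ball radius; used only for contact detection
BALL_RADIUS = 0.0335


class PhysicsError(ValueError):
    """Raised when launch constraints cannot be satisfied."""


@dataclass(frozen=True)
class LaunchSpec:
    """Geometry and kinematic constraints of a single ball launch.

    Defaults reproduce the task: launch from 2 m height on the front-wall
    plane 9 m away, bounce 3.5 m in front of the participant and 0.75 m
    toward the dominant side, with vertical speed fixed at -9 m/s at bounce.
    """

    launch_height: float = 2.0
    bounce_distance_from_start: float = 3.5
    lateral_offset: float = 0.75
    participant_wall_distance: float = 9.0
    vz_at_bounce: float = -9.0
    gravity: float = GRAVITY
    elasticity: float = ELASTICITY_NORMAL
    #: "up" selects the physically plausible lobbed serve (slow horizontal
    #: speed); "down" the steep fast alternative root.
    arc: str = "up"

    def validate(self) -> None:
        if self.launch_height <= 0:
            raise PhysicsError("launch_height must be > 0")
        if not (0.0 < self.elasticity <= 1.0):
            raise PhysicsError("elasticity must lie in (0, 1]")
        if self.vz_at_bounce >= 0:
            raise PhysicsError("vz_at_bounce must be downward (negative)")
        if self.gravity >= 0:
            raise PhysicsError("gravity must be negative")
        if self.vz_at_bounce**2 <= 2.0 * abs(self.gravity) * self.launch_height:
            raise PhysicsError(
                "unsolvable launch: require vz_at_bounce^2 > 2*|gravity|*launch_height "
                "for an upward-arc solution"
            )
        if self.arc not in ("up", "down"):
            raise PhysicsError("arc must be 'up' or 'down'")


@dataclass
class BallTrajectory:
    """A simulated ball flight, sampled on a grid but analytic underneath.

    ``samples`` holds (t, x, y, z) rows at a fixed rate; event times and the
    piecewise-ballistic coefficients are stored exactly so that
    :func:`ball_state_at` never interpolates.
    """

    spec: LaunchSpec
    t: np.ndarray
    pos: np.ndarray  # shape (n, 3): x, y, z
    t_launch: float
    t_bounce: float
    t_end: float
    launch_point: np.ndarray
    launch_velocity: np.ndarray
    bounce_point: np.ndarray
    post_bounce_velocity: np.ndarray
    post_bounce_apex: float

    @property
    def elasticity(self) -> float:
        return self.spec.elasticity

    def events(self) -> dict:
        return {
            "t_launch": self.t_launch,
            "t_bounce": self.t_bounce,
            "t_end": self.t_end,
            "bounce_point": [float(v) for v in self.bounce_point],
            "post_bounce_apex": self.post_bounce_apex,
            "elasticity": self.spec.elasticity,
        }

    def time_at_depth(self, z_plane: float) -> float:
        """Post-bounce time at which the ball depth crosses ``z_plane``."""
        vz = self.post_bounce_velocity[2]
        dz = z_plane - self.bounce_point[2]
        if vz == 0.0 or dz / vz < 0:
            raise PhysicsError(f"ball never reaches depth z={z_plane} after bounce")
        return self.t_bounce + dz / vz


def bounce_apex(elasticity: float, vz_at_bounce: float = -9.0,
                gravity: float = GRAVITY) -> float:
    """Closed-form post-bounce apex height: (e*|vz|)^2 / (2*|g|)."""
    v_up = elasticity * abs(vz_at_bounce)
    return v_up**2 / (2.0 * abs(gravity))


def solve_launch(spec: LaunchSpec) -> tuple[np.ndarray, float, np.ndarray]:
    """Solve launch velocity and flight time from the spec's constraints.

    Returns ``(launch_velocity, flight_time, launch_point)`` such that
    ballistic flight from ``launch_point`` reaches the bounce point at floor
    level with vertical velocity exactly ``spec.vz_at_bounce``.
    """
    spec.validate()
    g = spec.gravity
    h = spec.launch_height
    vzb = spec.vz_at_bounce
    # v_b^2 = v_0^2 + 2 g (0 - h)  =>  v_0 = +-sqrt(v_b^2 + 2 g h)
    v0_sq = vzb**2 + 2.0 * g * h
    v0 = math.sqrt(v0_sq)
    if spec.arc == "down":
        v0 = -v0
    flight_time = (vzb - v0) / g
    launch_point = np.array(
        [spec.lateral_offset, spec.launch_height, spec.participant_wall_distance]
    )
    horizontal = (spec.bounce_distance_from_start - spec.participant_wall_distance)
    vz_horizontal = horizontal / flight_time
    launch_velocity = np.array([0.0, v0, vz_horizontal])
    return launch_velocity, flight_time, launch_point


def simulate_trajectory(spec: LaunchSpec, sample_rate: float = 120.0) -> BallTrajectory:
    """Simulate a full trial flight: launch, floor bounce, and travel past
    the participant (until the second floor contact).

    The bounce is handled as an exact analytic event -- it is never snapped
    to the sampling grid -- so halving the sample interval changes no event
    time or analytic state.
    """
    if sample_rate <= 0:
        raise PhysicsError("sample_rate must be positive")
    v0, t_bounce, p0 = solve_launch(spec)
    g = np.array([0.0, spec.gravity, 0.0])
    bounce_point = p0 + v0 * t_bounce + 0.5 * g * t_bounce**2
    bounce_point[1] = 0.0  # exact by construction; clamp roundoff
    v_at_bounce = v0 + g * t_bounce
    v_post = v_at_bounce.copy()
    v_post[1] = spec.elasticity * abs(spec.vz_at_bounce)
    apex = bounce_apex(spec.elasticity, spec.vz_at_bounce, spec.gravity)
    # end at the second floor contact
    t_end = t_bounce + 2.0 * v_post[1] / abs(spec.gravity)

    traj = BallTrajectory(
        spec=spec,
        t=np.empty(0),
        pos=np.empty((0, 3)),
        t_launch=0.0,
        t_bounce=t_bounce,
        t_end=t_end,
        launch_point=p0,
        launch_velocity=v0,
        bounce_point=bounce_point,
        post_bounce_velocity=v_post,
        post_bounce_apex=apex,
    )
    n = int(math.floor(t_end * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    pos = _positions(traj, t)
    traj.t = t
    traj.pos = pos
    return traj


def _positions(traj: BallTrajectory, t: np.ndarray) -> np.ndarray:
    spec = traj.spec
    g = np.array([0.0, spec.gravity, 0.0])
    t = np.asarray(t, dtype=float)
    pre = t[:, None] <= traj.t_bounce
    dt_pre = t[:, None]
    pos_pre = traj.launch_point + traj.launch_velocity * dt_pre + 0.5 * g * dt_pre**2
    dt_post = (t - traj.t_bounce)[:, None]
    pos_post = traj.bounce_point + traj.post_bounce_velocity * dt_post + 0.5 * g * dt_post**2
    return np.where(pre, pos_pre, pos_post)


def ball_state_at(traj: BallTrajectory, t: float | np.ndarray):
    """Analytic position and velocity at time ``t`` (piecewise-ballistic).

    ``t`` may be a scalar or an array; times outside [t_launch, t_end] raise
    a range error.  At exactly ``t_bounce`` the pre-bounce (incoming) state
    is returned; use ``t_bounce + eps`` for the outgoing state.
    """
    scalar = np.isscalar(t)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < traj.t_launch - 1e-12) or np.any(t_arr > traj.t_end + 1e-12):
        raise ValueError(
            f"time outside simulated span [{traj.t_launch}, {traj.t_end:.4f}]"
        )
    spec = traj.spec
    g = np.array([0.0, spec.gravity, 0.0])
    pos = _positions(traj, t_arr)
    pre = t_arr[:, None] <= traj.t_bounce
    vel_pre = traj.launch_velocity + g * t_arr[:, None]
    vel_post = traj.post_bounce_velocity + g * (t_arr - traj.t_bounce)[:, None]
    vel = np.where(pre, vel_pre, vel_post)
    if scalar:
        return pos[0], vel[0]
    return pos, vel


def make_trajectory(elasticity: float, sample_rate: float = 120.0,
                    **overrides) -> BallTrajectory:
    """Convenience wrapper: default launch geometry with a given elasticity."""
    spec = replace(LaunchSpec(), elasticity=elasticity, **overrides)
    return simulate_trajectory(spec, sample_rate=sample_rate)
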