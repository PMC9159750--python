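"""Stimulus geometry for the cue-conflict object-motion detection design.

The observer is translated sinusoidally in the fronto-parallel plane while
fixating a world-fixed target.  Each in-receptive-field (in-RF) stimulus is
either a world-stationary object (depth identical for binocular disparity and
motion parallax) or a "dynamic" object whose motion-parallax depth ``d_MP``
and disparity depth ``d_BD`` disagree by ``ΔDepth = d_MP − d_BD``.  ΔDepth is
applied symmetrically about a fixed pedestal depth, so the dynamic object's
two cue depths straddle the pedestal.  Depths are expressed in degrees of
equivalent disparity; negative values are nearer than fixation.

The module builds the canonical 16-row condition table (7 ΔDepth values plus
9 stationary depths), evaluates the platform motion envelope and trajectory,
and ray-traces the dynamic object so that its monocular image motion is
identical to that of a stationary object at ``d_MP`` while its rendered
disparity is ``d_BD`` — the property that makes the task unsolvable from
relative image motion alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MotionEnvelope",
    "StimulusCondition",
    "ViewingGeometry",
    "STANDARD_DELTA_SET",
    "STANDARD_STATIONARY_DEPTHS",
    "STANDARD_PEDESTAL",
    "motion_envelope",
    "platform_trajectory",
    "split_pedestal",
    "build_condition_table",
    "standard_condition_table",
    "disparity_to_distance",
    "distance_to_disparity",
    "project_stationary",
    "raytrace_dynamic_object",
]

#: ΔDepth values (deg of equivalent disparity) used in the standard design.
STANDARD_DELTA_SET: tuple[float, ...] = (-1.53, -0.57, -0.21, 0.0, 0.21, 0.57, 1.53)

#: Stationary-object depth grid, deg: -1.6 to +1.6 in steps of 0.4 (9 values).
STANDARD_STATIONARY_DEPTHS: tuple[float, ...] = tuple(
    round(-1.6 + 0.4 * i, 10) for i in range(9)
)

#: Fixed pedestal depth (deg) about which ΔDepth is applied.
STANDARD_PEDESTAL: float = -0.45

DEPTH_LIMIT_DEG = 2.0


@dataclass(frozen=True)
class MotionEnvelope:
    """Flattened-Gaussian envelope and sinusoid parameters of the platform.

    The 0.5 Hz sinusoidal trajectory is multiplied by a Gaussian raised to a
    large even power, G(t) = exp(−(t−t0)^n / σ^n), which smooths stimulus
    onset/offset while staying ≈1 through the middle of the 2.1 s epoch.
    """

    t0: float = 1.0  # s, center of the envelope
    sigma: float = 0.92  # s, envelope width
    n: int = 22  # even exponent
    amplitude: float = 2.8  # cm, peak platform displacement
    frequency: float = 0.5  # Hz
    phase: float = 0.0  # deg, 0 or 180 (starting direction)
    duration: float = 2.1  # s

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.n < 2 or self.n % 2 != 0:
            raise ValueError(f"envelope exponent must be even and >= 2, got {self.n}")
        if self.phase not in (0.0, 180.0):
            raise ValueError(f"phase must be 0 or 180 deg, got {self.phase}")


@dataclass(frozen=True)
class StimulusCondition:
    """One in-RF stimulus condition."""

    kind: str  # "dynamic" or "stationary"
    d_bd: float  # deg equivalent disparity (negative = near)
    d_mp: float  # deg
    delta_depth: float  # deg, d_mp − d_bd
    pedestal: float  # deg

    def __post_init__(self) -> None:
        if self.kind not in ("dynamic", "stationary"):
            raise ValueError(f"unknown condition kind {self.kind!r}")
        if self.kind == "stationary":
            if self.d_bd != self.d_mp or self.delta_depth != 0.0:
                raise ValueError("stationary condition requires d_bd == d_mp, delta 0")
        elif not math.isclose(self.delta_depth, self.d_mp - self.d_bd, abs_tol=1e-12):
            raise ValueError("dynamic condition requires delta_depth == d_mp - d_bd")
        for d in (self.d_bd, self.d_mp):
            if abs(d) > DEPTH_LIMIT_DEG:
                raise ValueError(f"depth {d} outside ±{DEPTH_LIMIT_DEG} deg")


@dataclass(frozen=True)
class ViewingGeometry:
    """Viewing geometry used to convert equivalent disparity to distance."""

    viewing_distance: float = 30.0  # cm, fixation/screen distance
    interocular: float = 3.0  # cm (macaque)
    screen_size: float = 90.0  # deg
    object_eccentricity: float = 5.0  # deg, object center from fixation

    def __post_init__(self) -> None:
        if self.viewing_distance <= 0:
            raise ValueError("viewing_distance must be positive")
        if self.interocular <= 0:
            raise ValueError("interocular must be positive")


def motion_envelope(t, env: MotionEnvelope):
    """Evaluate G(t) = exp(−(t−t0)^n / σ^n); in (0, 1], exactly 1 at t0."""
    t = np.asarray(t, dtype=float)
    out = np.exp(-(((t - env.t0) / env.sigma) ** env.n))
    return out if out.ndim else float(out)


def platform_trajectory(times, env: MotionEnvelope):
    """Position (cm) and velocity (cm/s) of the enveloped sinusoid.

    position(t) = A·sin(2πft + φ)·G(t); the velocity is the analytic
    derivative.  Phase 180 deg negates the phase-0 trace (half-cycle shift
    of the sinusoid).
    """
    t = np.asarray(times, dtype=float)
    if t.size and (t.min() < 0 or t.max() > env.duration + 1e-12):
        raise ValueError("times must lie within [0, duration]")
    w = 2.0 * math.pi * env.frequency
    phi = math.radians(env.phase)
    g = motion_envelope(t, env)
    s = np.sin(w * t + phi)
    pos = env.amplitude * s * g
    # dG/dt = −n(t−t0)^(n−1)/σ^n · G
    dg = -env.n * ((t - env.t0) ** (env.n - 1)) / env.sigma**env.n * g
    vel = env.amplitude * (w * np.cos(w * t + phi) * g + s * dg)
    return pos, vel


def split_pedestal(pedestal: float, delta_depth: float) -> tuple[float, float]:
    """Split ΔDepth symmetrically about the pedestal.

    Returns (d_MP, d_BD) with d_MP = pedestal + ΔDepth/2 and
    d_BD = pedestal − ΔDepth/2, so that d_MP − d_BD == ΔDepth exactly.
    """
    if abs(pedestal) > DEPTH_LIMIT_DEG:
        raise ValueError(f"|pedestal| must be <= {DEPTH_LIMIT_DEG} deg")
    half = delta_depth / 2.0
    return pedestal + half, pedestal - half


def build_condition_table(
    delta_set=STANDARD_DELTA_SET,
    stationary_depths=STANDARD_STATIONARY_DEPTHS,
    pedestal: float = STANDARD_PEDESTAL,
) -> pd.DataFrame:
    """Build the canonical in-RF condition table.

    One dynamic condition per ΔDepth (cue depths via :func:`split_pedestal`)
    followed by one stationary condition per stationary depth; dynamic rows
    ascend in ΔDepth, stationary rows ascend in depth.  Columns follow the
    ``conditions.csv`` schema.
    """
    delta_set = list(delta_set)
    stationary_depths = list(stationary_depths)
    if not delta_set or not stationary_depths:
        raise ValueError("delta_set and stationary_depths must be non-empty")
    if len(set(delta_set)) != len(delta_set):
        raise ValueError("duplicate ΔDepth values")
    if len(set(stationary_depths)) != len(stationary_depths):
        raise ValueError("duplicate stationary depths")

    rows = []
    for delta in sorted(delta_set):
        d_mp, d_bd = split_pedestal(pedestal, delta)
        cond = StimulusCondition("dynamic", d_bd, d_mp, delta, pedestal)
        rows.append(
            {
                "condition_id": f"dyn{delta:+.2f}",
                "kind": cond.kind,
                "d_bd_deg": cond.d_bd,
                "d_mp_deg": cond.d_mp,
                "delta_depth_deg": cond.delta_depth,
                "pedestal_deg": pedestal,
            }
        )
    for depth in sorted(stationary_depths):
        cond = StimulusCondition("stationary", depth, depth, 0.0, pedestal)
        rows.append(
            {
                "condition_id": f"sta{depth:+.2f}",
                "kind": cond.kind,
                "d_bd_deg": cond.d_bd,
                "d_mp_deg": cond.d_mp,
                "delta_depth_deg": 0.0,
                "pedestal_deg": pedestal,
            }
        )
    return pd.DataFrame(rows)


def standard_condition_table() -> pd.DataFrame:
    """The 16-condition standard design (7 ΔDepth + 9 stationary depths)."""
    return build_condition_table()


def disparity_to_distance(depth_deg, geom: ViewingGeometry):
    """Convert equivalent disparity (deg, negative = near) to distance (cm).

    Small-angle binocular geometry: δ = I·(1/D − 1/Z) with δ in radians,
    interocular I and fixation distance D, so Z = 1/(1/D − δ/I).
    """
    delta_rad = np.deg2rad(np.asarray(depth_deg, dtype=float))
    inv_z = 1.0 / geom.viewing_distance - delta_rad / geom.interocular
    if np.any(inv_z <= 0):
        raise ValueError("depth implies a distance behind the eye (Z <= 0)")
    out = 1.0 / inv_z
    return out if out.ndim else float(out)


def distance_to_disparity(distance_cm, geom: ViewingGeometry):
    """Inverse of :func:`disparity_to_distance`."""
    z = np.asarray(distance_cm, dtype=float)
    if np.any(z <= 0):
        raise ValueError("distance must be positive")
    delta_rad = geom.interocular * (1.0 / geom.viewing_distance - 1.0 / z)
    out = np.rad2deg(delta_rad)
    return out if out.ndim else float(out)


def _world_x(depth_deg: float, geom: ViewingGeometry) -> tuple[float, float]:
    """World (lateral, distance) of an object centered at the eccentricity."""
    z = disparity_to_distance(depth_deg, geom)
    return z * math.tan(math.radians(geom.object_eccentricity)), z


def project_stationary(depth_deg: float, camera_positions, geom: ViewingGeometry):
    """Screen angle (deg) of a world-fixed object at ``depth_deg`` per frame."""
    cam = np.asarray(camera_positions, dtype=float)
    x_w, z = _world_x(depth_deg, geom)
    return np.rad2deg(np.arctan2(x_w - cam, z))


def raytrace_dynamic_object(
    d_mp: float, d_bd: float, camera_positions, geom: ViewingGeometry
):
    """Ray-trace the dynamic object onto the disparity-defined depth plane.

    A world-fixed point at depth ``d_mp`` is viewed from each camera position;
    the rendered dot is the intersection of that viewing ray with the plane at
    depth ``d_bd``.  Returns ``(screen_deg, disparity_deg)`` arrays: the
    per-frame screen angle of the rendered dot and its rendered disparity
    (``d_bd`` on every frame).  By construction the screen trajectory is
    identical to a stationary object at ``d_mp``, so monocular image motion
    carries no signature of the conflict.
    """
    cam = np.asarray(camera_positions, dtype=float)
    x_mp, z_mp = _world_x(d_mp, geom)
    z_bd = disparity_to_distance(d_bd, geom)
    # Intersection of the ray from the camera through (x_mp, z_mp) with the
    # plane at z_bd; its screen angle from the camera equals the MP angle.
    x_render = cam + (x_mp - cam) * (z_bd / z_mp)
    screen_deg = np.rad2deg(np.arctan2(x_render - cam, z_bd))
    return screen_deg, np.full_like(cam, float(d_bd))
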