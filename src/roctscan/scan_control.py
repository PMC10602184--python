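"""Scanline planning and the closed-loop probe-altitude (NSD) controller.

The virtual rig sweeps a :class:`~roctscan.oct_simulation.VirtualSample` with
a free-flying downward-looking probe. Each scanline is: position the probe at
the entry pose, descend at constant speed until the sample surface appears at
the target normalized surface depth (NSD), then travel along base-x at
constant speed while a proportional low-pass velocity controller regulates
the probe altitude so the surface stays at the NSD setpoint.

NSD is ``mu = 1 - h_tis / H_OCT`` where ``h_tis`` is the depth (mm) of the
highest detected surface point in the B-scan and ``H_OCT`` the axial FOV.
The controller output is ``v_z[t] = w_s K_p (mu_ref - mu) + (1 - w_s) v_z[t-1]``;
positive output moves the probe down (along the probe's axial axis).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .geometry import DOWNWARD_ROTATION, BScan, PixelResolution, ProbePose
from .oct_simulation import VirtualSample, synthesize_bscan
from .parameter_maps import default_surface_threshold, detect_surface_rows

__all__ = [
    "ScanPlan",
    "ScanConfig",
    "ProbeSpec",
    "NSDControllerState",
    "ConstraintViolation",
    "LandingAbort",
    "num_scanlines",
    "entry_pose",
    "compute_nsd",
    "nsd_velocity",
    "land_probe",
    "run_scanline",
    "run_scan",
    "frames_per_scanline",
]

logger = logging.getLogger(__name__)


class ConstraintViolation(ValueError):
    """A scan-plan parameter violates the planning constraint."""


class LandingAbort(RuntimeError):
    """Landing descent exceeded the travel limit without detecting a surface."""


def num_scanlines(W: float, W_OCT: float, W_ol: float) -> int:
    """Number of scanlines needed to cover a lateral extent ``W``.

    Returns ``ceil(W / (W_OCT - W_ol))`` subject to ``W_OCT > 2 W_ol > 0``.
    """
    if not (W_OCT > 2 * W_ol > 0):
        raise ConstraintViolation(
            f"require W_OCT > 2*W_ol > 0, got W_OCT={W_OCT}, W_ol={W_ol}"
        )
    if W <= 0:
        raise ConstraintViolation("lateral extent W must be positive")
    return math.ceil(W / (W_OCT - W_ol))


@dataclass(frozen=True)
class ScanPlan:
    """Scanline layout: start point, extents, FOV and overlap (all mm)."""

    x_st: float
    y_st: float
    z_st: float
    L: float
    W: float
    W_ol: float
    W_OCT: float

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ConstraintViolation("scanline length L must be positive")
        num_scanlines(self.W, self.W_OCT, self.W_ol)  # validates W, W_OCT, W_ol

    @property
    def n(self) -> int:
        """Derived scanline count."""
        return num_scanlines(self.W, self.W_OCT, self.W_ol)

    @property
    def step(self) -> float:
        """Lateral offset between consecutive scanlines."""
        return self.W_OCT - self.W_ol


@dataclass(frozen=True)
class ProbeSpec:
    """Virtual probe image geometry."""

    width_px: int = 64
    height_px: int = 100
    alpha_res: PixelResolution = PixelResolution(lateral=0.05, axial=0.02, elevational=0.03)

    @property
    def lateral_fov(self) -> float:
        return self.width_px * self.alpha_res.lateral

    @property
    def axial_fov(self) -> float:
        return self.height_px * self.alpha_res.axial


@dataclass(frozen=True)
class ScanConfig:
    """Motion and acquisition parameters of the virtual rig."""

    v_x: float = 0.6  # along-scanline speed, mm/s
    v_land: float = 1.0  # landing descent speed, mm/s
    fps: float = 20.0  # B-scan acquisition rate
    mu_land: float = 0.75  # landing termination NSD threshold
    landing_travel_limit: float = 50.0  # mm of descent before aborting
    surface_threshold: Optional[float] = None  # None -> background-derived

    def __post_init__(self) -> None:
        if self.v_x <= 0 or self.v_land <= 0 or self.fps <= 0:
            raise ValueError("speeds and frame rate must be positive")
        if not (0 < self.mu_land < 1):
            raise ValueError("mu_land must lie in (0, 1)")

    @property
    def dt(self) -> float:
        return 1.0 / self.fps


@dataclass
class NSDControllerState:
    """Proportional + low-pass altitude controller state."""

    mu_ref: float = 0.75
    K_p: float = 1.0  # mm/s per unit NSD error
    w_s: float = 0.5  # low-pass weight
    v_prev: float = 0.0  # previous output, mm/s

    def __post_init__(self) -> None:
        if not (0 < self.mu_ref < 1):
            raise ValueError("mu_ref must lie in (0, 1)")
        if not (0 <= self.w_s <= 1):
            raise ValueError("w_s must lie in [0, 1]")
        if self.K_p <= 0:
            raise ValueError("K_p must be positive")


def entry_pose(i: int, plan: ScanPlan, timestamp: float = 0.0) -> ProbePose:
    """Entry pose of the ``i``-th scanline (1-based).

    Rotation ``diag(1, -1, -1)`` (probe looking down), translation
    ``(x_st, y_st + (i-1)(W_OCT - W_ol), z_st)``.
    """
    if not (1 <= i <= plan.n):
        raise IndexError(f"scanline index {i} out of range [1, {plan.n}]")
    t = (plan.x_st, plan.y_st + (i - 1) * plan.step, plan.z_st)
    return ProbePose.from_rt(DOWNWARD_ROTATION, t, timestamp=timestamp)


def compute_nsd(bscan: BScan, threshold: float | None = None) -> Optional[float]:
    """Normalized surface depth of a B-scan, or None when no surface is seen.

    Per A-scan column the surface is the shallowest pixel at or above the
    intensity threshold; ``h_tis`` is the minimum surface depth over columns
    (the highest surface point). Columns with no detection are ignored; the
    frame reports "no surface" only when every column fails.
    """
    if threshold is None:
        threshold = default_surface_threshold(bscan.pixels)
    if threshold <= 0:
        raise ValueError("surface threshold must be positive")
    rows = detect_surface_rows(bscan.pixels, threshold)
    found = rows >= 0
    if not found.any():
        return None
    h_tis = rows[found].min() * bscan.alpha_res.axial
    return 1.0 - h_tis / bscan.axial_fov


def nsd_velocity(mu: float, state: NSDControllerState) -> tuple[float, NSDControllerState]:
    """One controller step: returns (v_z, updated state).

    ``v_z = w_s K_p (mu_ref - mu) + (1 - w_s) v_prev``; positive values
    descend. The returned state carries the new ``v_prev``.
    """
    if not (0 <= mu <= 1):
        raise ValueError("NSD must lie in [0, 1]")
    v = state.w_s * state.K_p * (state.mu_ref - mu) + (1 - state.w_s) * state.v_prev
    return v, replace(state, v_prev=v)


def _frame(sample: VirtualSample, pose: ProbePose, probe: ProbeSpec) -> BScan:
    return synthesize_bscan(sample, pose, probe.width_px, probe.height_px, probe.alpha_res)


def land_probe(
    sample: VirtualSample,
    pose0: ProbePose,
    cfg: ScanConfig,
    probe: ProbeSpec,
) -> ProbePose:
    """Descend vertically at ``v_land`` until the surface reaches ``mu_land``.

    A B-scan is synthesized every ``1/fps``; termination is checked after
    each step, so a one-step overshoot of at most ``v_land / (fps * H_OCT)``
    in NSD is accepted. Orientation is unchanged. Raises
    :class:`LandingAbort` if the descent exceeds the travel limit with no
    surface detection.
    """
    pose = pose0
    traveled = 0.0
    step = cfg.v_land * cfg.dt
    while True:
        frame = _frame(sample, pose, probe)
        mu = compute_nsd(frame, cfg.surface_threshold)
        if mu is not None and mu >= cfg.mu_land:
            return pose
        if traveled >= cfg.landing_travel_limit:
            raise LandingAbort(
                f"no surface within {cfg.landing_travel_limit} mm of descent"
            )
        t = pose.translation.copy()
        t[2] -= step
        traveled += step
        pose = ProbePose.from_rt(pose.rotation, t, timestamp=pose.timestamp + cfg.dt)


def frames_per_scanline(L: float, v_x: float, fps: float) -> int:
    """Frame count of one scanline: ``ceil(L * fps / v_x)``."""
    return math.ceil(L * fps / v_x)


def run_scanline(
    sample: VirtualSample,
    pose0: ProbePose,
    L: float,
    cfg: ScanConfig,
    ctrl: NSDControllerState,
    probe: ProbeSpec,
) -> tuple[list[BScan], NSDControllerState]:
    """Travel one scanline, regulating altitude, and record every frame.

    Starting from the landed pose, x advances by ``v_x / fps`` per frame
    until the total travel reaches ``L``; each step feeds the measured NSD to
    :func:`nsd_velocity` and applies the output to z (positive output
    descends). Exactly ``ceil(L * fps / v_x)`` pose-tagged frames are
    emitted. Frames with no detectable surface hold z and log a warning.
    """
    n_frames = frames_per_scanline(L, cfg.v_x, cfg.fps)
    dx = cfg.v_x * cfg.dt
    pose = pose0
    frames: list[BScan] = []
    for m in range(n_frames):
        frame = _frame(sample, pose, probe)
        frames.append(frame)
        mu = compute_nsd(frame, cfg.surface_threshold)
        if mu is None:
            logger.warning("no surface detected mid-scan at frame %d; holding altitude", m)
            v_z = 0.0
        else:
            v_z, ctrl = nsd_velocity(min(max(mu, 0.0), 1.0), ctrl)
        t = pose.translation.copy()
        t[0] += dx
        t[2] -= v_z * cfg.dt
        pose = ProbePose.from_rt(pose.rotation, t, timestamp=pose.timestamp + cfg.dt)
    return frames, ctrl


def run_scan(
    sample: VirtualSample,
    plan: ScanPlan,
    cfg: ScanConfig,
    ctrl: NSDControllerState | None = None,
    probe: ProbeSpec | None = None,
) -> list[list[BScan]]:
    """Full acquisition: land + scan for every scanline of the plan.

    Returns one frame list per scanline; each frame carries its pose.
    The controller is reset (fresh ``v_prev``) at the start of each
    scanline, mirroring the land-then-scan procedure.
    """
    probe = probe or ProbeSpec()
    base_ctrl = ctrl or NSDControllerState()
    log: list[list[BScan]] = []
    t0 = 0.0
    for i in range(1, plan.n + 1):
        pose = entry_pose(i, plan, timestamp=t0)
        landed = land_probe(sample, pose, cfg, probe)
        frames, _ = run_scanline(
            sample, landed, plan.L, cfg, replace(base_ctrl, v_prev=0.0), probe
        )
        log.append(frames)
        t0 = frames[-1].pose.timestamp + cfg.dt
    return log
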