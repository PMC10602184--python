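"""Coordinate frames, pose bookkeeping and voxelization of tracked B-scans.

Frame conventions
-----------------
Base frame ``{F_base}``: *x* is the scanline travel direction, *y* the lateral
stepping direction between scanlines, *z* points up.

Probe frame ``{F_OCT}``: *x* is the elevational (travel) axis, *y* the lateral
axis across the B-scan width, *z* the axial axis pointing into the tissue.
The probe frame originates at the top center of the B-scan, so the lateral
pixel index is centered and axial index 0 is the shallowest row.

A downward-looking probe therefore carries the rotation ``diag(1, -1, -1)``:
the probe's axial axis maps onto ``-z`` of the base frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "PixelResolution",
    "ProbePose",
    "BScan",
    "TissueVolume",
    "DOWNWARD_ROTATION",
    "pixel_to_base",
    "voxelize",
]

#: Rotation block of the entry pose: probe axial axis points down in the base frame.
DOWNWARD_ROTATION = np.diag([1.0, -1.0, -1.0])

_ORTHONORMALITY_TOL = 1e-8


class PixelResolution(NamedTuple):
    """Per-axis pixel pitch in mm/pixel."""

    lateral: float
    axial: float
    elevational: float


def _check_rotation(R: np.ndarray) -> None:
    if R.shape != (3, 3):
        raise ValueError("rotation block must be 3x3")
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
        raise ValueError("rotation block is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("rotation block has negative determinant (reflection)")


@dataclass(frozen=True)
class ProbePose:
    """A timestamped rigid transform from the probe frame to the base frame.

    Parameters
    ----------
    timestamp : float
        Acquisition time in seconds; non-negative.
    T : (4, 4) ndarray
        Homogeneous transform. The 3x3 rotation block must be orthonormal
        with determinant +1; translation is in mm.
    """

    timestamp: float
    T: np.ndarray

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        if T.shape != (4, 4):
            raise ValueError("pose transform must be 4x4")
        if self.timestamp < 0:
            raise ValueError("timestamp must be non-negative")
        _check_rotation(T[:3, :3])
        if not np.allclose(T[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("last row of a homogeneous transform must be (0,0,0,1)")
        object.__setattr__(self, "T", T)

    @property
    def rotation(self) -> np.ndarray:
        return self.T[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.T[:3, 3]

    @classmethod
    def from_rt(
        cls, R: np.ndarray, t: Sequence[float], timestamp: float = 0.0
    ) -> "ProbePose":
        T = np.eye(4)
        T[:3, :3] = R
        T[:3, 3] = t
        return cls(timestamp=timestamp, T=T)

    @classmethod
    def identity(cls, timestamp: float = 0.0) -> "ProbePose":
        return cls(timestamp=timestamp, T=np.eye(4))


@dataclass
class BScan:
    """One 2D OCT intensity image with its acquisition pose.

    ``pixels`` is indexed ``[axial_row, lateral_column]`` (row 0 is the
    shallowest depth). Intensities are non-negative, normalized floats.
    """

    pixels: np.ndarray
    alpha_res: PixelResolution
    pose: ProbePose

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a non-empty 2D array")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")
        self.alpha_res = PixelResolution(*self.alpha_res)
        if min(self.alpha_res) <= 0:
            raise ValueError("all pixel resolutions must be positive")

    @property
    def height_px(self) -> int:
        """Axial pixel count."""
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        """Lateral pixel count."""
        return self.pixels.shape[1]

    @property
    def lateral_fov(self) -> float:
        """Physical lateral field of view ``W_OCT`` in mm."""
        return self.width_px * self.alpha_res.lateral

    @property
    def axial_fov(self) -> float:
        """Physical axial field of view ``H_OCT`` in mm."""
        return self.height_px * self.alpha_res.axial


@dataclass
class TissueVolume:
    """Voxelized intensity grid in the base frame.

    ``voxels`` is indexed ``[ix, iy, iz]`` along base-frame x, y, z. Voxels
    never touched by any pixel are NaN; ``counts`` records how many pixels
    were averaged into each voxel (0 marks empty).
    """

    voxels: np.ndarray
    counts: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel size must be positive on all axes")
        if self.voxels.shape != self.counts.shape:
            raise ValueError("voxels and counts must share a shape")

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0


def probe_points(j: np.ndarray, k: np.ndarray, width_px: int, alpha_res: PixelResolution) -> np.ndarray:
    """Probe-frame coordinates (mm) of pixel indices ``(j, k)``.

    The lateral index is centered on the B-scan (origin at the top center);
    the elevational coordinate of an in-plane pixel is zero.
    """
    j = np.asarray(j, dtype=float)
    k = np.asarray(k, dtype=float)
    x = np.zeros(np.broadcast(j, k).shape)
    y = (j - width_px / 2.0) * alpha_res.lateral
    z = k * alpha_res.axial
    return np.stack(np.broadcast_arrays(x, y, z), axis=-1)


def pixel_to_base(j: int, k: int, bscan: BScan) -> np.ndarray:
    """Map pixel ``(j, k)`` of a posed B-scan to a base-frame point in mm.

    ``j`` is the lateral column, ``k`` the axial row. The pixel is scaled by
    the per-axis resolution, expressed in the probe frame and pushed through
    the pose transform.
    """
    if not (0 <= j < bscan.width_px):
        raise IndexError(f"lateral index {j} out of range [0, {bscan.width_px})")
    if not (0 <= k < bscan.height_px):
        raise IndexError(f"axial index {k} out of range [0, {bscan.height_px})")
    p = probe_points(j, k, bscan.width_px, bscan.alpha_res)
    return bscan.pose.rotation @ p + bscan.pose.translation


def _all_base_points(bscan: BScan) -> np.ndarray:
    """Base-frame coordinates of every pixel, shape (H, W, 3)."""
    kk, jj = np.meshgrid(
        np.arange(bscan.height_px), np.arange(bscan.width_px), indexing="ij"
    )
    p = probe_points(jj, kk, bscan.width_px, bscan.alpha_res)
    return p @ bscan.pose.rotation.T + bscan.pose.translation


def voxel_index(points: np.ndarray, origin: np.ndarray, voxel_size: np.ndarray) -> np.ndarray:
    """Nearest-center voxel index of base-frame points.

    Voxel ``(0,0,0)`` is centered at ``origin``; a point belongs to the voxel
    whose center is nearest (round-half-up on each axis). Rounding rather
    than flooring keeps grid-aligned pixels from straddling bin edges due to
    floating-point jitter.
    """
    return np.rint((points - origin) / voxel_size).astype(np.int64)


def voxelize(
    scans: Sequence[BScan],
    voxel_size: Sequence[float] | None = None,
) -> TissueVolume:
    """Bin pose-transformed pixels of a scan sequence into a 3D grid.

    Every pixel of every B-scan is mapped to the base frame and assigned to
    the voxel with the nearest center. Colliding pixels are averaged; voxels
    receiving no pixel are NaN with a zero count. Grid bounds are computed
    from the transformed points, not preallocated.

    Parameters
    ----------
    scans : sequence of BScan
        All scans must share ``alpha_res``.
    voxel_size : length-3 sequence, optional
        mm per voxel along base x, y, z. Defaults to
        ``(elevational, lateral, axial)`` resolution of the scans, which are
        the natural pitches of a downward-looking scan.
    """
    scans = list(scans)
    if not scans:
        raise ValueError("voxelize requires at least one B-scan")
    res0 = scans[0].alpha_res
    for s in scans[1:]:
        if s.alpha_res != res0:
            raise ValueError("all scans must share alpha_res")
    if voxel_size is None:
        voxel_size = (res0.elevational, res0.lateral, res0.axial)
    voxel_size = np.asarray(voxel_size, dtype=float)
    if np.any(voxel_size <= 0):
        raise ValueError("voxel size must be positive")

    points = np.concatenate([_all_base_points(s).reshape(-1, 3) for s in scans])
    values = np.concatenate([s.pixels.reshape(-1) for s in scans])

    origin = points.min(axis=0)
    idx = voxel_index(points, origin, voxel_size)
    shape = tuple(idx.max(axis=0) + 1)

    sums = np.zeros(shape)
    counts = np.zeros(shape, dtype=np.int64)
    np.add.at(sums, tuple(idx.T), values)
    np.add.at(counts, tuple(idx.T), 1)

    voxels = np.full(shape, np.nan)
    occ = counts > 0
    voxels[occ] = sums[occ] / counts[occ]
    return TissueVolume(voxels=voxels, counts=counts, voxel_size=voxel_size, origin=origin)
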