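"""Per-slice lumen detection, mask cleanup and centerline diameter measurement.

The trained segmentation network of the original system is replaced by a
classical intensity/shape segmenter behind a pluggable interface: externally
supplied mask stacks bypass the internal segmenter entirely, so the diameter
mapping stays testable either way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import exposure, measure, morphology

from .geometry import BScan, pixel_to_base, voxelize
from .parameter_maps import default_surface_threshold, detect_surface_rows

__all__ = [
    "SegmenterConfig",
    "MaskVolume",
    "LumenMeasurement",
    "enhance_contrast",
    "segment_lumens",
    "clean_mask",
    "measure_diameters",
    "build_mask_volume",
    "measurements_table",
]


@dataclass(frozen=True)
class SegmenterConfig:
    """Tunables of the classical lumen segmenter."""

    clip_limit: float = 0.02
    tile_size: int = 8
    dark_fraction: float = 0.6  # candidate pixels fall below this fraction of background
    depth_band_mm: tuple[float, float] = (0.05, 1.5)  # band below the surface searched
    min_area_px: int = 5
    max_area_px: int = 4000
    max_eccentricity: float = 0.99
    close_area_px: int = 25
    open_area_px: int = 9


@dataclass
class MaskVolume:
    """Binary lumen-mask grid aligned with a tissue volume."""

    voxels: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    provenance: str = "internal-segmenter"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)


@dataclass(frozen=True)
class LumenMeasurement:
    """One segmented lumen in one slice."""

    slice_index: int
    component_id: int
    diameter_um: float
    centerline_px: int
    centroid: tuple[float, float, float]  # base-frame mm


def enhance_contrast(
    slice_: np.ndarray, clip_limit: float = 0.02, tile_size: int = 8
) -> np.ndarray:
    """CLAHE followed by range normalization to [0, 1].

    A perfectly constant slice is returned as a constant (zeros) rather than
    fed to the equalizer, whose output is undefined at zero dynamic range.
    """
    slice_ = np.asarray(slice_, dtype=float)
    lo, hi = slice_.min(), slice_.max()
    if hi - lo == 0:
        return np.zeros_like(slice_)
    norm = (slice_ - lo) / (hi - lo)
    kernel = max(2, min(tile_size, min(slice_.shape) // 2))
    eq = exposure.equalize_adapthist(norm, kernel_size=kernel, clip_limit=clip_limit)
    lo2, hi2 = eq.min(), eq.max()
    if hi2 - lo2 == 0:
        return eq
    return (eq - lo2) / (hi2 - lo2)


def segment_lumens(
    slice_: np.ndarray,
    surface_rows: np.ndarray,
    alpha_ax: float,
    config: SegmenterConfig = SegmenterConfig(),
) -> np.ndarray:
    """Classical lumen segmentation of one enhanced slice.

    Candidate lumens are connected dark regions (below ``dark_fraction`` of
    the local tissue background) lying below the detected surface inside the
    configured depth band; components are gated by area and eccentricity.
    Columns with no surface contribute nothing; a slice with no surface at
    all yields an empty mask.
    """
    slice_ = np.asarray(slice_, dtype=float)
    H, W = slice_.shape
    surface_rows = np.asarray(surface_rows)
    has_surface = surface_rows >= 0
    if not has_surface.any():
        return np.zeros((H, W), dtype=bool)

    rows = np.arange(H)[:, None]
    srow = np.where(has_surface, surface_rows, H)[None, :]
    lo = srow + config.depth_band_mm[0] / alpha_ax
    hi = srow + config.depth_band_mm[1] / alpha_ax
    band = (rows >= lo) & (rows <= hi) & has_surface[None, :]
    if not band.any():
        return np.zeros((H, W), dtype=bool)

    background = np.median(slice_[band])
    dark = band & (slice_ < config.dark_fraction * background)

    labels = measure.label(dark, connectivity=2)
    out = np.zeros((H, W), dtype=bool)
    for region in measure.regionprops(labels):
        if not (config.min_area_px <= region.area <= config.max_area_px):
            continue
        if region.eccentricity > config.max_eccentricity:
            continue
        # lumens clipped by the lateral FOV edge have unknown extent: drop them
        if region.bbox[1] == 0 or region.bbox[3] == W:
            continue
        out[labels == region.label] = True
    return out


def clean_mask(mask: np.ndarray, close_area: int = 25, open_area: int = 9) -> np.ndarray:
    """Area closing (fill small holes) then area opening (drop small specks)."""
    mask = np.asarray(mask, dtype=bool)
    closed = morphology.area_closing(mask.astype(np.uint8), area_threshold=close_area)
    opened = morphology.area_opening(closed, area_threshold=open_area)
    return opened.astype(bool)


def measure_diameters(
    mask: np.ndarray,
    alpha_mm_per_px: float,
    slice_index: int = 0,
    centroid_fn=None,
) -> list[LumenMeasurement]:
    """Centerline diameters of every connected component of a binary slice.

    Per 8-connected component the medial-axis skeleton and in-component
    distance transform are computed. Rasterized boundaries grow spurious
    skeleton branches whose distance values tail off toward 1, so the
    measurement core is the ridge top of the distance transform (component
    pixels within half a pixel of the maximum distance); the diameter is
    twice the mean core distance, converted to um via the (isotropic
    in-plane) pixel pitch. Single-pixel components report ``2 * alpha`` by
    convention.

    ``centroid_fn(row, col) -> (x, y, z)`` maps the component centroid to
    base-frame mm; defaults to ``(col, row, 0)`` in pixel units.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    labels = measure.label(mask, connectivity=2)
    out = []
    for region in measure.regionprops(labels):
        # work on the padded bounding box: EDT and skeleton are local
        r0, c0, r1, c1 = region.bbox
        comp = np.pad(labels[r0:r1, c0:c1] == region.label, 1)
        dist = ndimage.distance_transform_edt(comp)
        on_skel = morphology.skeletonize(comp)
        core = comp & (dist >= dist.max() - 0.5)
        radius_px = float(dist[core].mean())
        radius_px = max(radius_px, 1.0)  # 1-px component convention: diameter 2*alpha
        r, c = region.centroid
        centroid = centroid_fn(r, c) if centroid_fn else (float(c), float(r), 0.0)
        out.append(
            LumenMeasurement(
                slice_index=slice_index,
                component_id=int(region.label),
                diameter_um=2.0 * radius_px * alpha_mm_per_px * 1000.0,
                centerline_px=int(on_skel.sum()),
                centroid=tuple(float(v) for v in centroid),
            )
        )
    return out


def _slice_masks_internal(
    frames: Sequence[BScan], config: SegmenterConfig
) -> list[np.ndarray]:
    masks = []
    for f in frames:
        thr = default_surface_threshold(f.pixels)
        rows = detect_surface_rows(f.pixels, thr)
        enhanced = enhance_contrast(f.pixels, config.clip_limit, config.tile_size)
        raw = segment_lumens(enhanced, rows, f.alpha_res.axial, config)
        masks.append(clean_mask(raw, config.close_area_px, config.open_area_px))
    return masks


def build_mask_volume(
    log,
    config: SegmenterConfig = SegmenterConfig(),
    external_masks: Optional[Sequence[np.ndarray]] = None,
) -> tuple[MaskVolume, list[LumenMeasurement]]:
    """Segment every frame, voxelize the masks and collect measurements.

    ``log`` is a flat or nested (per-scanline) sequence of pose-tagged
    B-scans. When ``external_masks`` is given (one binary mask per frame, in
    log order) the internal segmenter is skipped. The mask volume shares the
    voxel grid convention of :func:`roctscan.geometry.voxelize`; a voxel is
    set when at least half of the pixels binned into it are lumen.
    """
    frames: list[BScan] = []
    stack = list(log)
    if stack and isinstance(stack[0], BScan):
        frames = stack
    else:
        for sl in stack:
            frames.extend(sl)
    if not frames:
        raise ValueError("acquisition log is empty")

    if external_masks is not None:
        masks = [np.asarray(m, dtype=bool) for m in external_masks]
        if len(masks) != len(frames):
            raise ValueError("external mask count does not match frame count")
        provenance = "external-masks"
    else:
        masks = _slice_masks_internal(frames, config)
        provenance = "internal-segmenter"

    measurements: list[LumenMeasurement] = []
    for i, (f, m) in enumerate(zip(frames, masks)):
        if f.alpha_res.lateral != f.alpha_res.axial:
            alpha = float(np.sqrt(f.alpha_res.lateral * f.alpha_res.axial))
        else:
            alpha = f.alpha_res.lateral

        def centroid_fn(r, c, f=f):
            return tuple(pixel_to_base(int(round(c)), int(round(r)), f))

        measurements.extend(
            measure_diameters(m, alpha, slice_index=i, centroid_fn=centroid_fn)
        )

    mask_scans = [
        BScan(pixels=m.astype(float), alpha_res=f.alpha_res, pose=f.pose)
        for f, m in zip(frames, masks)
    ]
    vol = voxelize(mask_scans)
    voxels = np.nan_to_num(vol.voxels) >= 0.5
    return (
        MaskVolume(
            voxels=voxels,
            voxel_size=vol.voxel_size,
            origin=vol.origin,
            provenance=provenance,
        ),
        measurements,
    )


def measurements_table(measurements: Sequence[LumenMeasurement]) -> pd.DataFrame:
    """Measurement list as a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "slice": m.slice_index,
                "component": m.component_id,
                "diameter_um": m.diameter_um,
                "centerline_px": m.centerline_px,
                "centroid_x_mm": m.centroid[0],
                "centroid_y_mm": m.centroid[1],
                "centroid_z_mm": m.centroid[2],
            }
            for m in measurements
        ]
    )
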