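"""Post-scan parameterization: DEPM, ATCM, DIAM assembly and map stitching.

All en-face maps live on a regular base-frame grid: rows follow the
elevational (travel, base-x) axis, columns the lateral (base-y) axis.
Per-scanline maps are assembled from the pose-tagged frame log; the lateral
pitch equals the B-scan lateral resolution and the elevational pitch is
derived from the pose log (frame spacing), never from nominal constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .geometry import BScan

__all__ = [
    "ParameterMap",
    "ExtinctionFit",
    "default_surface_threshold",
    "extract_surface_depth",
    "fit_extinction",
    "build_depm",
    "build_atcm",
    "diameter_grid",
    "build_diam",
    "stitch",
]

MAP_KINDS = ("DEPM", "ATCM", "DIAM")
MAP_UNITS = {"DEPM": "mm", "ATCM": "1/mm", "DIAM": "um"}

#: Rows skipped below the detected surface before the fit window (specular peak).
SURFACE_SKIP_PX = 2
#: Fits with r^2 below this are flagged invalid.
MIN_R2 = 0.2


@dataclass
class ParameterMap:
    """A 2D en-face map (DEPM, ATCM or DIAM) on a base-frame grid.

    ``grid`` is indexed ``[elevational, lateral]``; ``res`` is the
    (elevational, lateral) pixel pitch in mm; ``origin`` is the base-frame
    (x, y) of pixel (0, 0). ``validity`` marks pixels that carry data.
    """

    kind: str
    grid: np.ndarray
    res: tuple[float, float]
    origin: tuple[float, float]
    validity: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}")
        self.grid = np.asarray(self.grid, dtype=float)
        self.validity = np.asarray(self.validity, dtype=bool)
        if self.grid.shape != self.validity.shape:
            raise ValueError("grid and validity must share a shape")
        if min(self.res) <= 0:
            raise ValueError("map resolution must be positive")
        if not self.units:
            self.units = MAP_UNITS[self.kind]
        if self.kind == "ATCM" and np.any(self.grid[self.validity] < 0):
            raise ValueError("ATCM values must be non-negative where valid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass
class ExtinctionFit:
    """Result of a single-scattering fit on one A-scan.

    ``mu_t`` is the extinction coefficient in mm^-1 (clamped to >= 0);
    ``window`` the (z_start, z_end) depth span below the image origin in mm;
    ``r2`` the goodness of the log-linear fit; ``valid`` is False when the
    window left the image, the fit was poor, or the slope was clamped.
    """

    mu_t: float
    window: tuple[float, float]
    r2: float
    valid: bool = True


def default_surface_threshold(pixels: np.ndarray, top_fraction: float = 0.05, n_sigma: float = 5.0) -> float:
    """Background-derived intensity threshold for surface detection.

    Estimates background statistics from the top ``top_fraction`` of axial
    rows (assumed above the tissue) and returns mean + ``n_sigma`` std,
    floored at a small positive value so an all-zero background still yields
    a usable threshold. When the estimate reaches the image maximum the top
    rows are evidently not background (tissue or saturation at the top of
    the frame); the threshold falls back to the mid-level of the intensity
    range so such frames still report a surface.
    """
    n = max(1, int(np.ceil(pixels.shape[0] * top_fraction)))
    top = pixels[:n]
    thr = float(max(top.mean() + n_sigma * top.std(), 1e-6))
    if thr >= pixels.max():
        thr = max(0.5 * float(pixels.min() + pixels.max()), 1e-6)
    return thr


def detect_surface_rows(pixels: np.ndarray, threshold: float) -> np.ndarray:
    """Per-column row index of the shallowest suprathreshold pixel (-1 if none)."""
    supra = pixels >= threshold
    has = supra.any(axis=0)
    rows = np.where(has, supra.argmax(axis=0), -1)
    return rows


def extract_surface_depth(bscan: BScan, threshold: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-column surface depth of a B-scan in mm, with validity flags.

    The surface of a column is its shallowest pixel at or above ``threshold``
    (default: :func:`default_surface_threshold`); the returned depth is the
    row index times the axial resolution. Columns with no suprathreshold
    pixel are flagged invalid (depth NaN).
    """
    if threshold is None:
        threshold = default_surface_threshold(bscan.pixels)
    rows = detect_surface_rows(bscan.pixels, threshold)
    valid = rows >= 0
    depth = np.where(valid, rows * bscan.alpha_res.axial, np.nan)
    return depth, valid


def fit_extinction(
    a_scan: np.ndarray,
    surface_row: int,
    window_mm: float,
    alpha_ax: float,
    skip_px: int = SURFACE_SKIP_PX,
) -> ExtinctionFit:
    """Fit the single-scattering decay model to one A-scan.

    Ordinary least squares on ``ln I(z) = c - 2 mu_t z`` over a depth window
    anchored ``skip_px`` rows below the detected surface (skipping the
    specular surface peak) and extending ``window_mm``. Non-positive
    intensities are floored to the smallest positive normal float before the
    log. A negative fitted ``mu_t`` is clamped to zero and flagged; so are
    fits with fewer than 4 samples in-image or r^2 below :data:`MIN_R2`.
    """
    a_scan = np.asarray(a_scan, dtype=float)
    n = a_scan.size
    k0 = int(surface_row) + skip_px
    k1 = k0 + int(np.round(window_mm / alpha_ax))
    window = (k0 * alpha_ax, k1 * alpha_ax)
    k1 = min(k1, n)
    if k1 - k0 < 4:
        return ExtinctionFit(mu_t=0.0, window=window, r2=0.0, valid=False)

    z = np.arange(k0, k1) * alpha_ax
    y = np.log(np.clip(a_scan[k0:k1], np.finfo(float).tiny, None))
    # constant signal (up to log round-off): zero slope, zero attenuation
    if np.ptp(y) < 1e-12:
        return ExtinctionFit(mu_t=0.0, window=window, r2=1.0, valid=True)
    zc = z - z.mean()
    yc = y - y.mean()
    denom = float(zc @ zc)
    slope = float(zc @ yc) / denom
    ss_tot = float(yc @ yc)
    ss_res = ss_tot - slope**2 * denom
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    mu = -slope / 2.0
    valid = r2 >= MIN_R2
    if mu < 0:
        return ExtinctionFit(mu_t=0.0, window=window, r2=r2, valid=False)
    return ExtinctionFit(mu_t=mu, window=window, r2=r2, valid=valid)


def _fit_extinction_columns(
    pixels: np.ndarray,
    surface_rows: np.ndarray,
    window_mm: float,
    alpha_ax: float,
    skip_px: int = SURFACE_SKIP_PX,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-column extinction fit for one B-scan.

    Identical model to :func:`fit_extinction`, evaluated for all columns at
    once (windows share their length; columns whose window leaves the image
    or whose surface is undetected come back invalid).
    """
    H, W = pixels.shape
    wlen = int(np.round(window_mm / alpha_ax))
    k0 = surface_rows + skip_px
    ok = (surface_rows >= 0) & (k0 + wlen <= H) & (wlen >= 4)

    mu = np.zeros(W)
    valid = np.zeros(W, dtype=bool)
    if not np.any(ok):
        return mu, valid

    cols = np.nonzero(ok)[0]
    rows = k0[cols][None, :] + np.arange(wlen)[:, None]  # (wlen, ncols)
    I = pixels[rows, cols[None, :]]
    z = rows * alpha_ax
    y = np.log(np.clip(I, np.finfo(float).tiny, None))
    zc = z - z.mean(axis=0)
    yc = y - y.mean(axis=0)
    denom = np.sum(zc * zc, axis=0)
    slope = np.sum(zc * yc, axis=0) / denom
    ss_tot = np.sum(yc * yc, axis=0)
    ss_res = ss_tot - slope**2 * denom
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)

    flat = np.ptp(y, axis=0) < 1e-12  # constant columns: mu 0, valid
    m = np.where(flat, 0.0, -slope / 2.0)
    v = ((r2 >= MIN_R2) & (m >= 0)) | flat
    mu[cols] = np.clip(m, 0.0, None)
    valid[cols] = v
    return mu, valid


# ---------------------------------------------------------------------------
# per-scanline map assembly


def _flatten_log(log) -> list[list[BScan]]:
    """Normalize an acquisition log to a list of scanline frame lists."""
    log = list(log)
    if not log:
        raise ValueError("acquisition log is empty")
    if isinstance(log[0], BScan):
        return [log]
    return [list(sl) for sl in log]


def _scanline_grid(frames: Sequence[BScan]) -> tuple[tuple[float, float], tuple[float, float], int]:
    """Grid geometry of one scanline: (res, origin, n_lat).

    The elevational pitch comes from the recorded pose x-coordinates; the
    lateral pitch is the B-scan lateral resolution. Column index increases
    with base-frame y, so lateral pixel order is flipped relative to the
    image column order (the downward rotation negates the lateral axis).
    """
    xs = np.array([f.pose.translation[0] for f in frames])
    a_lat = frames[0].alpha_res.lateral
    W = frames[0].width_px
    if len(frames) > 1:
        d_elev = float(np.median(np.diff(xs)))
        if d_elev <= 0:
            raise ValueError("pose log must advance monotonically along x")
    else:
        d_elev = frames[0].alpha_res.elevational
    ty = frames[0].pose.translation[1]
    # image column j sits at y = ty - (j - W/2) * a_lat; min over j is at j = W-1
    y0 = ty - (W - 1 - W / 2.0) * a_lat
    return (d_elev, a_lat), (float(xs[0]), float(y0)), W


def _per_column_map(
    frames: Sequence[BScan],
    kind: str,
    column_fn: Callable[[BScan], tuple[np.ndarray, np.ndarray]],
) -> ParameterMap:
    frames = list(frames)
    res, origin, W = _scanline_grid(frames)
    grid = np.full((len(frames), W), np.nan)
    validity = np.zeros((len(frames), W), dtype=bool)
    for i, f in enumerate(frames):
        values, valid = column_fn(f)
        # flip: map column m corresponds to image column j = W-1-m
        grid[i] = values[::-1]
        validity[i] = valid[::-1]
    grid = np.where(validity, grid, np.nan)
    return ParameterMap(kind=kind, grid=np.nan_to_num(grid), res=res, origin=origin, validity=validity)


def build_depm(log, threshold: float | None = None) -> ParameterMap:
    """Build the depth-encoded (surface altitude) map from an acquisition log.

    Each column's detected surface point is expressed in the base frame; the
    map stores absolute surface altitude (base-frame z, mm) per en-face
    pixel, so probe altitude motion is compensated. A nested log (scanlines)
    is mapped per scanline and stitched.
    """
    scanlines = _flatten_log(log)

    def column_fn(f: BScan):
        depth, valid = extract_surface_depth(f, threshold)
        altitude = f.pose.translation[2] - depth
        return altitude, valid

    maps = [_per_column_map(sl, "DEPM", column_fn) for sl in scanlines]
    return maps[0] if len(maps) == 1 else stitch(maps)


def build_atcm(log, window_mm: float = 1.0, threshold: float | None = None) -> ParameterMap:
    """Build the attenuation-coefficient map from an acquisition log.

    Every A-scan is compressed to a single extinction coefficient by the
    single-scattering fit over a near-surface window (default 1 mm) and
    placed at its pose-resolved en-face coordinate. Columns with no surface
    or an unusable fit are invalid.
    """
    scanlines = _flatten_log(log)

    def column_fn(f: BScan):
        thr = threshold if threshold is not None else default_surface_threshold(f.pixels)
        rows = detect_surface_rows(f.pixels, thr)
        return _fit_extinction_columns(f.pixels, rows, window_mm, f.alpha_res.axial)

    maps = [_per_column_map(sl, "ATCM", column_fn) for sl in scanlines]
    return maps[0] if len(maps) == 1 else stitch(maps)


# ---------------------------------------------------------------------------
# DIAM


def diameter_grid(
    measurements,
    proj_shape: tuple[int, int],
    res: tuple[float, float],
    origin: tuple[float, float],
    k: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """k-by-k grid of mean lumen diameter over the en-face projection.

    Each measurement's base-frame centroid is binned into one of k x k
    equal blocks of the projection; the block value is the mean diameter
    (um) of the lumens inside it. Blocks with no lumen are invalid.
    """
    if k > min(proj_shape):
        raise ValueError("k must not exceed the projection size")
    sums = np.zeros((k, k))
    counts = np.zeros((k, k), dtype=int)
    for m in measurements:
        ix = (m.centroid[0] - origin[0]) / res[0]
        iy = (m.centroid[1] - origin[1]) / res[1]
        gx = int(np.clip(ix / proj_shape[0] * k, 0, k - 1))
        gy = int(np.clip(iy / proj_shape[1] * k, 0, k - 1))
        sums[gx, gy] += m.diameter_um
        counts[gx, gy] += 1
    valid = counts > 0
    grid = np.zeros((k, k))
    grid[valid] = sums[valid] / counts[valid]
    return grid, valid


def _fill_nearest(grid: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill invalid cells with the nearest valid cell value."""
    if valid.all():
        return grid
    if not valid.any():
        return np.zeros_like(grid)
    idx = ndimage.distance_transform_edt(~valid, return_distances=False, return_indices=True)
    return grid[tuple(idx)]


def build_diam(mask_volume, measurements, k: int = 10) -> ParameterMap:
    """Build the lumen-diameter map from a mask volume and its measurements.

    The top-view projection of the mask volume is partitioned into k x k
    blocks; lumen diameters are averaged per block and the block grid is
    bicubically upsampled back to the projection size. Blocks with no lumen
    stay invalid: they are filled from the nearest valid block before
    interpolation and masked out again afterwards.
    """
    proj_shape = mask_volume.voxels.shape[:2]
    res = (float(mask_volume.voxel_size[0]), float(mask_volume.voxel_size[1]))
    origin = (float(mask_volume.origin[0]), float(mask_volume.origin[1]))
    grid, valid = diameter_grid(measurements, proj_shape, res, origin, k=k)

    filled = _fill_nearest(grid, valid)
    up = resize(filled, proj_shape, order=3, mode="edge", anti_aliasing=False)
    vup = resize(valid.astype(float), proj_shape, order=0, mode="edge", anti_aliasing=False) > 0.5
    up = np.where(vup, np.clip(up, 0.0, None), 0.0)
    return ParameterMap(kind="DIAM", grid=up, res=res, origin=origin, validity=vup, units="um")


# ---------------------------------------------------------------------------
# stitching


def stitch(maps: Sequence[ParameterMap]) -> ParameterMap:
    """Average per-scanline maps into one large-area map.

    Maps are placed on a common grid by their base-frame origins; pixels
    covered by several maps take the unweighted mean of the valid
    contributors, pixels covered once are copied, and validity is the union.
    Running sums and counts make the blend order-free.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("no maps to stitch")
    kind = maps[0].kind
    res = maps[0].res
    for m in maps[1:]:
        if m.kind != kind:
            raise ValueError("cannot stitch maps of different kinds")
        if not np.allclose(m.res, res, rtol=1e-6):
            raise ValueError("cannot stitch maps with different resolutions")

    origins = np.array([m.origin for m in maps])
    g_origin = origins.min(axis=0)
    ends = np.array(
        [[m.origin[0] + m.shape[0] * res[0], m.origin[1] + m.shape[1] * res[1]] for m in maps]
    )
    shape = tuple(np.rint((ends.max(axis=0) - g_origin) / np.array(res)).astype(int))

    sums = np.zeros(shape)
    counts = np.zeros(shape, dtype=int)
    for m in maps:
        off = np.rint((np.array(m.origin) - g_origin) / np.array(res)).astype(int)
        sl = (slice(off[0], off[0] + m.shape[0]), slice(off[1], off[1] + m.shape[1]))
        sums[sl] += np.where(m.validity, m.grid, 0.0)
        counts[sl] += m.validity
    valid = counts > 0
    grid = np.zeros(shape)
    grid[valid] = sums[valid] / counts[valid]
    return ParameterMap(
        kind=kind,
        grid=grid,
        res=res,
        origin=(float(g_origin[0]), float(g_origin[1])),
        validity=valid,
        units=maps[0].units,
    )


def plot_map(pmap: ParameterMap, ax=None, cmap: str = "viridis"):
    """Thin plotting helper (lazy matplotlib import); invalid pixels masked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    data = np.ma.masked_where(~pmap.validity, pmap.grid)
    extent = (
        pmap.origin[1],
        pmap.origin[1] + pmap.shape[1] * pmap.res[1],
        pmap.origin[0] + pmap.shape[0] * pmap.res[0],
        pmap.origin[0],
    )
    im = ax.imshow(data, cmap=cmap, extent=extent, aspect="auto")
    ax.set_xlabel("base y (mm)")
    ax.set_ylabel("base x (mm)")
    ax.set_title(f"{pmap.kind} ({pmap.units})")
    return im
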