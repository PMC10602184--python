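"""Synthetic-data generator: virtual samples and a single-scattering B-scan synthesizer.

A :class:`VirtualSample` is a height field ``h(x, y)`` (surface altitude in
the base frame, mm), an extinction field ``mu_t(x, y, z)`` (mm^-1) and a set
of dark tubular/spherical inclusions. :func:`synthesize_bscan` renders the
image a downward-looking probe would record: per lateral column, rows above
the surface carry background noise, rows below follow
``I(z) = I0 * exp(-2 * integral(mu_t) dz)`` discretized per axial pixel,
optionally multiplied by unit-mean gamma speckle. Inclusion voxels are
multiplied by their intensity factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .geometry import BScan, PixelResolution, ProbePose

__all__ = [
    "SpeckleModel",
    "Lumen",
    "VirtualSample",
    "HeightGrid",
    "make_letter_phantom",
    "make_layered_kidney",
    "make_lumen_field",
    "synthesize_bscan",
    "BLOCK_GLYPHS",
]


@dataclass(frozen=True)
class SpeckleModel:
    """Multiplicative gamma speckle plus additive background noise.

    ``enabled=False`` renders a noiseless image (background rows are zero).
    The gamma distribution has unit mean and shape ``shape`` (variance
    ``1/shape``).
    """

    enabled: bool = False
    shape: float = 16.0
    background_level: float = 0.0
    background_std: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class Lumen:
    """A dark inclusion: a sphere, or an infinite tube when ``axis`` is set.

    ``factor`` multiplies the intensity of pixels inside the inclusion and
    must lie in [0, 1). ``axis`` is a base-frame direction; a tube extends
    infinitely along it through ``center``.
    """

    center: tuple[float, float, float]
    radius: float
    factor: float = 0.1
    axis: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("lumen radius must be positive")
        if not (0 <= self.factor < 1):
            raise ValueError("lumen intensity factor must lie in [0, 1)")

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership for base-frame points of shape (..., 3)."""
        d = points - np.asarray(self.center)
        if self.axis is not None:
            a = np.asarray(self.axis, dtype=float)
            a = a / np.linalg.norm(a)
            d = d - np.tensordot(d, a, axes=([-1], [0]))[..., None] * a
        return np.einsum("...i,...i->...", d, d) <= self.radius**2


@dataclass
class VirtualSample:
    """A scannable virtual tissue sample.

    ``height_field(x, y)`` and ``extinction_field(x, y, z)`` are vectorized
    callables in base-frame mm; ``truth`` holds generator-side ground truth
    for parameter-recovery tests (height grids, lumen tables, ...).
    """

    height_field: Callable[[np.ndarray, np.ndarray], np.ndarray]
    extinction_field: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    lumens: list[Lumen] = field(default_factory=list)
    I0: float = 0.9
    noise: SpeckleModel = field(default_factory=SpeckleModel)
    truth: dict = field(default_factory=dict)

    def height(self, x, y) -> np.ndarray:
        h = np.asarray(self.height_field(np.asarray(x, float), np.asarray(y, float)), float)
        if not np.all(np.isfinite(h)):
            raise ValueError("height field must be finite over the queried footprint")
        return h

    def extinction(self, x, y, z) -> np.ndarray:
        mu = np.asarray(
            self.extinction_field(np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)),
            float,
        )
        if np.any(mu < 0):
            raise ValueError("extinction must be non-negative everywhere")
        return mu

    def lumen_table(self) -> pd.DataFrame:
        """Ground-truth inclusion table (center mm, radius mm, diameter mm)."""
        rows = [
            {
                "lumen_id": i,
                "cx_mm": l.center[0],
                "cy_mm": l.center[1],
                "cz_mm": l.center[2],
                "radius_mm": l.radius,
                "diameter_mm": l.diameter,
                "factor": l.factor,
            }
            for i, l in enumerate(self.lumens)
        ]
        return pd.DataFrame(rows)


class HeightGrid:
    """Nearest-sample lookup of a rasterized height field.

    The grid covers ``[0, footprint_x) x [0, footprint_y)`` at a uniform
    ``pitch``; queries outside the footprint clamp to the border cell.
    """

    def __init__(self, grid: np.ndarray, pitch: float):
        self.grid = np.asarray(grid, dtype=float)
        self.pitch = float(pitch)

    def __call__(self, x, y):
        ix = np.clip(np.floor(np.asarray(x) / self.pitch).astype(int), 0, self.grid.shape[0] - 1)
        iy = np.clip(np.floor(np.asarray(y) / self.pitch).astype(int), 0, self.grid.shape[1] - 1)
        return self.grid[ix, iy]


# Blocky glyphs on a 3x5 cell grid (column-major strings, '#' = raised).
BLOCK_GLYPHS: dict[str, list[str]] = {
    "W": ["#####", "...#.", "#####"],
    "P": ["#####", "#.#..", "###.."],
    "I": ["#...#", "#####", "#...#"],
    "U": ["#####", "....#", "#####"],
    "M": ["#####", ".#...", "#####"],
    "A": ["#####", "#.#..", "#####"],
    "S": ["###.#", "#.#.#", "#.###"],
    "O": ["#####", "#...#", "#####"],
}


def _rasterize_rect(mask: np.ndarray, rect: tuple[float, float, float, float], pitch: float) -> None:
    x0, y0, w, h = rect
    i0 = int(np.round(x0 / pitch))
    i1 = int(np.round((x0 + w) / pitch))
    j0 = int(np.round(y0 / pitch))
    j1 = int(np.round((y0 + h) / pitch))
    mask[max(i0, 0) : i1, max(j0, 0) : j1] = True


def _glyph_rects(
    char: str, origin: tuple[float, float], size: tuple[float, float]
) -> list[tuple[float, float, float, float]]:
    cells = BLOCK_GLYPHS[char.upper()]
    ncx, ncy = len(cells), len(cells[0])
    cw, ch = size[0] / ncx, size[1] / ncy
    rects = []
    for cx, col in enumerate(cells):
        for cy, c in enumerate(col):
            if c == "#":
                rects.append((origin[0] + cx * cw, origin[1] + cy * ch, cw, ch))
    return rects


def make_letter_phantom(
    footprint: tuple[float, float],
    letters: Sequence[dict],
    extrusion_height: float,
    pitch: float = 0.05,
    mu_t: float = 1.5,
    noise: SpeckleModel | None = None,
) -> VirtualSample:
    """Build a flat phantom with glyph-shaped extrusions.

    Each glyph spec is a dict with either ``rect: (x0, y0, w, h)`` for a raw
    rectangle or ``char`` plus ``origin`` and ``size`` for a blocky letter
    from :data:`BLOCK_GLYPHS`. The height field takes the value 0 on the base
    plane and ``extrusion_height`` inside glyph masks; extinction is uniform.

    Ground truth stored in ``truth``: the rasterized height grid, its pitch,
    and per-glyph bounding boxes.
    """
    if extrusion_height <= 0:
        raise ValueError("extrusion height must be positive")
    letters = list(letters)
    if not letters:
        raise ValueError("at least one glyph is required")
    nx = int(np.round(footprint[0] / pitch))
    ny = int(np.round(footprint[1] / pitch))
    mask = np.zeros((nx, ny), dtype=bool)
    bboxes = []
    for spec in letters:
        if "rect" in spec:
            rects = [tuple(spec["rect"])]
        else:
            rects = _glyph_rects(spec["char"], tuple(spec["origin"]), tuple(spec["size"]))
        for r in rects:
            _rasterize_rect(mask, r, pitch)
        xs = [r[0] for r in rects] + [r[0] + r[2] for r in rects]
        ys = [r[1] for r in rects] + [r[1] + r[3] for r in rects]
        bboxes.append((min(xs), min(ys), max(xs), max(ys)))

    grid = np.where(mask, float(extrusion_height), 0.0)
    hf = HeightGrid(grid, pitch)
    mu = float(mu_t)
    return VirtualSample(
        height_field=hf,
        extinction_field=lambda x, y, z: np.full(np.broadcast(x, y, z).shape, mu),
        noise=noise or SpeckleModel(),
        truth={
            "height_grid": grid,
            "pitch": pitch,
            "glyph_mask": mask,
            "glyph_bboxes": bboxes,
            "extrusion_height": float(extrusion_height),
            "mu_t": mu,
        },
    )


def make_layered_kidney(
    footprint: tuple[float, float],
    surface_profile: Callable[[np.ndarray, np.ndarray], np.ndarray] | float,
    layer_extinctions: Sequence[tuple[float, float]],
    lumen_spec: Sequence[Lumen] | None = None,
    I0: float = 0.9,
    noise: SpeckleModel | None = None,
) -> VirtualSample:
    """Depth-stratified tissue with optional dark inclusions.

    ``layer_extinctions`` lists ``(thickness_mm, mu_t)`` pairs from the
    surface downward; the last layer extends to infinite depth. The surface
    profile is a callable ``h(x, y)`` or a constant altitude. Inclusion
    ground truth is retrievable via ``truth['lumen_table']``.
    """
    if callable(surface_profile):
        hf = surface_profile
    else:
        h0 = float(surface_profile)
        hf = lambda x, y: np.full(np.broadcast(x, y).shape, h0)  # noqa: E731

    layers = [(float(t), float(m)) for t, m in layer_extinctions]
    if any(m < 0 for _, m in layers):
        raise ValueError("layer extinctions must be non-negative")
    edges = np.cumsum([t for t, _ in layers])
    mus = np.array([m for _, m in layers])

    def extinction(x, y, z):
        depth = np.asarray(hf(np.asarray(x, float), np.asarray(y, float)), float) - np.asarray(z, float)
        li = np.searchsorted(edges, depth, side="right")
        li = np.clip(li, 0, len(mus) - 1)
        out = mus[li]
        return np.where(depth < 0, 0.0, out)

    lumens = list(lumen_spec or [])
    sample = VirtualSample(
        height_field=hf,
        extinction_field=extinction,
        lumens=lumens,
        I0=I0,
        noise=noise or SpeckleModel(),
        truth={"footprint": tuple(footprint), "layers": layers},
    )
    sample.truth["lumen_table"] = sample.lumen_table()
    return sample


def make_lumen_field(
    n: int,
    footprint: tuple[float, float],
    diameter_range: tuple[float, float],
    depth_range: tuple[float, float],
    surface_altitude: float = 0.0,
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0),
    factor: float = 0.1,
    seed: int = 0,
    margin: float = 0.5,
) -> list[Lumen]:
    """Randomly place ``n`` parallel tube inclusions with known diameters.

    Tubes run along ``axis`` (default: the travel direction); centers are
    uniform over the footprint interior and a depth band below the surface.
    Regeneration with the same seed yields an identical field.
    """
    rng = np.random.default_rng(seed)
    lumens = []
    for _ in range(n):
        d = rng.uniform(*diameter_range)
        cx = rng.uniform(margin, footprint[0] - margin)
        cy = rng.uniform(margin, footprint[1] - margin)
        depth = rng.uniform(*depth_range)
        lumens.append(
            Lumen(center=(cx, cy, surface_altitude - depth), radius=d / 2.0, factor=factor, axis=axis)
        )
    return lumens


def _pose_rng(noise: SpeckleModel, pose: ProbePose) -> np.random.Generator:
    """Deterministic per-pose RNG: seed mixed with the pose translation bits."""
    t_bits = np.asarray(pose.translation, dtype="<f8").tobytes()
    words = np.frombuffer(t_bits, dtype="<u4")
    return np.random.default_rng(np.random.SeedSequence([int(noise.seed), *map(int, words)]))


def synthesize_bscan(
    sample: VirtualSample,
    pose: ProbePose,
    width_px: int,
    height_px: int,
    alpha_res: PixelResolution,
    rng: np.random.Generator | None = None,
) -> BScan:
    """Render the B-scan a downward-looking probe records at ``pose``.

    Per lateral column the probe ray is traced straight down from the image
    origin; the surface row is where the ray meets the sample height field.
    Columns whose surface lies deeper than the axial FOV stay empty
    (background only); a probe below the surface yields saturated, flagged
    columns. Deterministic given (sample, pose, noise seed).
    """
    alpha_res = PixelResolution(*alpha_res)
    R = pose.rotation
    if not np.allclose(R[:, 2], [0.0, 0.0, -1.0], atol=1e-9):
        raise ValueError("synthesize_bscan requires a downward-looking pose (axial axis -> -z)")

    j = np.arange(width_px)
    lateral = (j - width_px / 2.0) * alpha_res.lateral
    col_xy = (R[:2, :2] @ np.stack([np.zeros(width_px), lateral])).T + pose.translation[:2]
    z_top = pose.translation[2]

    h = sample.height(col_xy[:, 0], col_xy[:, 1])
    dist = z_top - h  # mm from image origin down to the surface, per column

    if rng is None and sample.noise.enabled:
        rng = _pose_rng(sample.noise, pose)

    img = np.zeros((height_px, width_px))
    if sample.noise.enabled and sample.noise.background_level > 0:
        bg = sample.noise.background_level + sample.noise.background_std * rng.standard_normal(img.shape)
        img += np.clip(bg, 0.0, None)

    below = dist < 0
    if np.any(below):
        img[:, below] = 1.0

    k = np.arange(height_px)
    depth_mm = k[:, None] * alpha_res.axial  # depth of each row below the image origin
    sub = depth_mm - dist[None, :]  # depth below the local surface; <0 above surface
    in_tissue = (sub >= 0) & ~below[None, :]

    if np.any(in_tissue):
        zb = z_top - depth_mm  # base-frame altitude of each pixel
        xb = np.broadcast_to(col_xy[:, 0], (height_px, width_px))
        yb = np.broadcast_to(col_xy[:, 1], (height_px, width_px))
        mu = sample.extinction(xb, yb, np.broadcast_to(zb, (height_px, width_px)))
        mu = np.where(in_tissue, mu, 0.0)
        # per-axial-pixel cumulative attenuation, anchored at the surface pixel
        att = np.cumsum(mu, axis=0) * alpha_res.axial
        signal = sample.I0 * np.exp(-2.0 * att)
        for lum in sample.lumens:
            pts = np.stack([xb, yb, np.broadcast_to(zb, xb.shape)], axis=-1)
            inside = lum.contains(pts)
            signal = np.where(inside, signal * lum.factor, signal)
        if sample.noise.enabled:
            speckle = rng.gamma(sample.noise.shape, 1.0 / sample.noise.shape, size=img.shape)
            signal = signal * speckle
        img = np.where(in_tissue, signal, img)

    return BScan(pixels=np.clip(img, 0.0, None), alpha_res=alpha_res, pose=pose)
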