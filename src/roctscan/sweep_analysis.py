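"""Velocity-sweep degradation analysis by frame decimation.

Scanning faster at a fixed frame rate coarsens the elevational frame
spacing; the sweep emulates this by decimating a recorded acquisition log at
fractional strides, rebuilding the en-face map at each virtual speed and
scoring it against the baseline map with a windowed structure-similarity
metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity
from skimage.transform import resize

from .geometry import BScan
from .parameter_maps import ParameterMap

__all__ = [
    "SweepSpec",
    "QualityCurve",
    "frames_at_velocity",
    "speedup",
    "decimate_frames",
    "decimate_log",
    "quality_curve",
]


def _default_velocities() -> list[float]:
    return [0.6 + 0.5 * i for i in range(10)]


@dataclass(frozen=True)
class SweepSpec:
    """Velocity sweep: baseline speed, swept speeds and the fixed frame rate."""

    v0: float = 0.6
    v_list: tuple[float, ...] = tuple(_default_velocities())
    fps: float = 20.0
    n0: int = 0  # baseline frame count (bookkeeping; 0 = unknown)

    def __post_init__(self) -> None:
        if self.v0 <= 0:
            raise ValueError("baseline velocity must be positive")
        vs = tuple(float(v) for v in self.v_list)
        if any(v < self.v0 for v in vs):
            raise ValueError("swept velocities must be >= the baseline velocity")
        if any(b <= a for a, b in zip(vs, vs[1:])):
            raise ValueError("velocity list must be strictly increasing")
        object.__setattr__(self, "v_list", vs)

    @classmethod
    def from_range(cls, v0: float = 0.6, vmax: float = 5.1, step: float = 0.5, fps: float = 20.0) -> "SweepSpec":
        n = int(math.floor((vmax - v0) / step + 0.5)) + 1
        return cls(v0=v0, v_list=tuple(v0 + step * i for i in range(n)), fps=fps)


@dataclass
class QualityCurve:
    """Map-quality score per swept velocity, normalized to 1 at baseline."""

    velocities: np.ndarray
    scores: np.ndarray
    n_frames: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"velocity_mm_s": self.velocities, "n_frames": self.n_frames, "quality": self.scores}
        )


def frames_at_velocity(n0: int, v0: float, v: float, fps: float = 20.0) -> int:
    """Frame count over the same trajectory at speed ``v`` instead of ``v0``.

    The trajectory length and frame rate are fixed, so the count scales
    inversely with speed: ``floor(n0 * v0 / v)``. Only decimation
    (``v >= v0``) is supported.
    """
    if v0 <= 0:
        raise ValueError("baseline velocity must be positive")
    if v < v0:
        raise ValueError("frames_at_velocity models decimation only (v >= v0)")
    return math.floor(n0 * v0 / v)


def speedup(v0: float, v: float) -> float:
    """Theoretical scan acceleration factor ``v / v0``."""
    if v0 <= 0:
        raise ValueError("baseline velocity must be positive")
    return v / v0


def decimation_indices(n: int, v0: float, v: float) -> np.ndarray:
    """Frame indices retained when decimating ``n`` frames from v0 to v.

    An accumulator walks the index axis in steps of ``v / v0`` starting at
    frame 0 and keeps the floor of each position; the retained count is
    within one frame of :func:`frames_at_velocity`.
    """
    if v < v0:
        raise ValueError("decimation requires v >= v0")
    stride = v / v0
    idx = []
    pos = 0.0
    while int(math.floor(pos)) < n:
        idx.append(int(math.floor(pos)))
        pos += stride
    return np.asarray(idx, dtype=int)


def decimate_frames(frames: Sequence, v0: float, v: float) -> list:
    """Keep frames at a fractional stride of ``v / v0``, starting at frame 0."""
    frames = list(frames)
    return [frames[i] for i in decimation_indices(len(frames), v0, v)]


def decimate_log(log: Sequence[Sequence[BScan]], v0: float, v: float) -> list[list[BScan]]:
    """Per-scanline frame decimation of a nested acquisition log."""
    return [decimate_frames(sl, v0, v) for sl in log]


def _filled(pmap: ParameterMap) -> np.ndarray:
    return np.where(pmap.validity, pmap.grid, 0.0)


def _ssim_vs_baseline(baseline: np.ndarray, candidate: np.ndarray, win: int) -> float:
    data_range = float(baseline.max() - baseline.min())
    if data_range == 0:
        data_range = 1.0
    win = min(win, min(baseline.shape) - (1 - min(baseline.shape) % 2))
    if win % 2 == 0:
        win -= 1
    win = max(win, 3)
    return float(structural_similarity(baseline, candidate, win_size=win, data_range=data_range))


def quality_curve(
    map_builder: Callable[[Sequence[Sequence[BScan]]], ParameterMap],
    log: Sequence[Sequence[BScan]],
    spec: SweepSpec,
    win_size: int = 7,
    normalize: bool = True,
) -> QualityCurve:
    """Map-quality degradation across the velocity sweep.

    For each swept velocity the log is decimated per scanline, the map is
    rebuilt and replicated back to the baseline geometry along the
    elevational axis by zero-order hold on the retained frame indices (each
    kept frame stands in for the baseline rows it replaced, so decimation
    artifacts are measured, not smoothed away), then compared to the
    baseline map with the mean local structure-similarity metric. With
    ``normalize`` the curve is divided by its baseline-velocity value;
    scores are clipped to [0, 1].
    """
    log = [list(sl) for sl in log]
    base_map = map_builder(log)
    base = _filled(base_map)

    scores, counts = [], []
    for v in spec.v_list:
        dec = decimate_log(log, spec.v0, v)
        pm = map_builder(dec)
        if pm.kind != base_map.kind:
            raise ValueError("map kind changed across the sweep")
        cand_small = _filled(pm)
        kept = decimation_indices(len(log[0]), spec.v0, v)
        if (
            cand_small.shape[1] == base.shape[1]
            and base.shape[0] == len(log[0])
            and cand_small.shape[0] == len(kept)
            and all(len(sl) == len(log[0]) for sl in log)
        ):
            hold = np.searchsorted(kept, np.arange(base.shape[0]), side="right") - 1
            cand = cand_small[np.clip(hold, 0, cand_small.shape[0] - 1)]
        else:
            # irregular geometry: fall back to nearest-neighbor resizing
            cand = resize(cand_small, base.shape, order=0, mode="edge", anti_aliasing=False)
        scores.append(_ssim_vs_baseline(base, cand, win_size))
        counts.append(sum(len(sl) for sl in dec))

    scores = np.asarray(scores, dtype=float)
    if normalize:
        ref = scores[int(np.argmin(np.abs(np.asarray(spec.v_list) - spec.v0)))]
        if ref != 0:
            scores = scores / ref
    scores = np.clip(scores, 0.0, 1.0)
    return QualityCurve(
        velocities=np.asarray(spec.v_list, dtype=float),
        scores=scores,
        n_frames=np.asarray(counts, dtype=int),
    )
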