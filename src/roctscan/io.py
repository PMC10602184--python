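"""Acquisition and map readers/writers.

On-disk layout of an acquisition directory::

    images.tif    multi-page grayscale stack (float32, uint8 or uint16),
                  one page per frame, OR frames/ with PNG files
    poses.csv     timestamp, r11..r33 (row-major rotation), tx, ty, tz (mm);
                  one row per frame, defining frame order and count
    meta.yaml     alpha_res (lateral/axial/elevational mm/px), width_px,
                  height_px, scanline_lengths (frames per scanline)

Intensities are normalized to [0, 1] floats at load regardless of source bit
depth, so threshold semantics do not depend on the storage format.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .geometry import BScan, PixelResolution, ProbePose
from .parameter_maps import ParameterMap

__all__ = [
    "AcquisitionError",
    "FrameCountMismatch",
    "MalformedPoseRow",
    "MissingMetadata",
    "write_acquisition",
    "read_acquisition",
    "write_map",
    "read_map",
]

POSE_COLUMNS = [
    "timestamp",
    "r11", "r12", "r13",
    "r21", "r22", "r23",
    "r31", "r32", "r33",
    "tx", "ty", "tz",
]


class AcquisitionError(RuntimeError):
    pass


class FrameCountMismatch(AcquisitionError):
    pass


class MalformedPoseRow(AcquisitionError):
    pass


class MissingMetadata(AcquisitionError):
    pass


def _flatten(log) -> tuple[list[BScan], list[int]]:
    stack = list(log)
    if stack and isinstance(stack[0], BScan):
        return stack, [len(stack)]
    frames, lengths = [], []
    for sl in stack:
        sl = list(sl)
        frames.extend(sl)
        lengths.append(len(sl))
    return frames, lengths


def _pose_row(pose: ProbePose) -> list[float]:
    return [pose.timestamp, *pose.rotation.reshape(-1).tolist(), *pose.translation.tolist()]


def write_acquisition(log, directory, dtype: str = "float32", overwrite: bool = False) -> Path:
    """Write an acquisition log (flat or per-scanline) to a directory.

    ``dtype`` selects the image storage: ``float32`` (lossless for the
    internal [0, 1] scale), ``uint8`` or ``uint16`` (quantized). Refuses to
    overwrite an existing images file unless ``overwrite`` is set.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames, lengths = _flatten(log)
    if not frames:
        raise AcquisitionError("cannot write an empty acquisition")

    img_path = directory / "images.tif"
    if img_path.exists() and not overwrite:
        raise AcquisitionError(f"{img_path} already exists (pass overwrite=True)")

    stack = np.stack([f.pixels for f in frames])
    if dtype == "float32":
        data = stack.astype(np.float32)
    elif dtype == "uint8":
        data = np.round(np.clip(stack, 0, 1) * 255).astype(np.uint8)
    elif dtype == "uint16":
        data = np.round(np.clip(stack, 0, 1) * 65535).astype(np.uint16)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(img_path, data)

    with open(directory / "poses.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(POSE_COLUMNS)
        for f in frames:
            writer.writerow(f"{v:.12g}" for v in _pose_row(f.pose))

    res = frames[0].alpha_res
    meta = {
        "alpha_res": {
            "lateral": float(res.lateral),
            "axial": float(res.axial),
            "elevational": float(res.elevational),
        },
        "width_px": int(frames[0].width_px),
        "height_px": int(frames[0].height_px),
        "scanline_lengths": [int(n) for n in lengths],
        "image_dtype": dtype,
    }
    with open(directory / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return directory


def _normalize(stack: np.ndarray) -> np.ndarray:
    if stack.dtype == np.uint8:
        return stack.astype(float) / 255.0
    if stack.dtype == np.uint16:
        return stack.astype(float) / 65535.0
    return stack.astype(float)


def _load_images(directory: Path) -> np.ndarray:
    img_path = directory / "images.tif"
    if img_path.exists():
        stack = tifffile.imread(img_path)
        if stack.ndim == 2:
            stack = stack[None]
        return _normalize(stack)
    frames_dir = directory / "frames"
    if frames_dir.is_dir():
        import imageio.v3 as iio

        paths = sorted(frames_dir.glob("*.png"))
        if not paths:
            raise AcquisitionError(f"no PNG frames in {frames_dir}")
        return _normalize(np.stack([iio.imread(p) for p in paths]))
    raise AcquisitionError(f"no images.tif or frames/ directory in {directory}")


def read_acquisition(directory) -> list[list[BScan]]:
    """Read an acquisition directory back into a per-scanline frame log.

    The pose CSV is the single source of frame order and count; a mismatch
    with the image stack raises :class:`FrameCountMismatch`.
    """
    directory = Path(directory)
    meta_path = directory / "meta.yaml"
    if not meta_path.exists():
        raise MissingMetadata(f"missing metadata sidecar {meta_path}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    try:
        res = PixelResolution(
            lateral=float(meta["alpha_res"]["lateral"]),
            axial=float(meta["alpha_res"]["axial"]),
            elevational=float(meta["alpha_res"]["elevational"]),
        )
        lengths = [int(n) for n in meta["scanline_lengths"]]
    except (KeyError, TypeError) as exc:
        raise MissingMetadata(f"malformed metadata in {meta_path}: {exc}") from exc

    poses = []
    with open(directory / "poses.csv", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != POSE_COLUMNS:
            raise MalformedPoseRow(f"unexpected pose CSV header {reader.fieldnames}")
        for ln, row in enumerate(reader, start=2):
            try:
                vals = [float(row[c]) for c in POSE_COLUMNS]
            except (TypeError, ValueError, KeyError) as exc:
                raise MalformedPoseRow(f"bad pose row at line {ln}") from exc
            T = np.eye(4)
            T[:3, :3] = np.array(vals[1:10]).reshape(3, 3)
            T[:3, 3] = vals[10:13]
            poses.append(ProbePose(timestamp=vals[0], T=T))

    stack = _load_images(directory)
    if len(stack) != len(poses):
        raise FrameCountMismatch(
            f"{len(stack)} image frames vs {len(poses)} pose rows"
        )
    if sum(lengths) != len(poses):
        raise FrameCountMismatch(
            f"scanline_lengths sum {sum(lengths)} vs {len(poses)} pose rows"
        )

    frames = [BScan(pixels=img, alpha_res=res, pose=p) for img, p in zip(stack, poses)]
    log, start = [], 0
    for n in lengths:
        log.append(frames[start : start + n])
        start += n
    return log


def write_map(pmap: ParameterMap, path_stem) -> Path:
    """Write a map as float32 TIFF + uint8 validity TIFF + YAML sidecar."""
    stem = Path(path_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(stem.with_suffix(".tif"), pmap.grid.astype(np.float32))
    tifffile.imwrite(
        Path(str(stem) + "_validity.tif"), pmap.validity.astype(np.uint8) * 255
    )
    sidecar = {
        "kind": pmap.kind,
        "units": pmap.units,
        "res_mm": [float(pmap.res[0]), float(pmap.res[1])],
        "origin_mm": [float(pmap.origin[0]), float(pmap.origin[1])],
    }
    with open(stem.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    return stem.with_suffix(".tif")


def read_map(path_stem) -> ParameterMap:
    stem = Path(path_stem)
    grid = tifffile.imread(stem.with_suffix(".tif")).astype(float)
    validity = tifffile.imread(Path(str(stem) + "_validity.tif")) > 0
    with open(stem.with_suffix(".yaml")) as fh:
        sidecar = yaml.safe_load(fh)
    return ParameterMap(
        kind=sidecar["kind"],
        grid=grid,
        res=tuple(sidecar["res_mm"]),
        origin=tuple(sidecar["origin_mm"]),
        validity=validity,
        units=sidecar.get("units", ""),
    )
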