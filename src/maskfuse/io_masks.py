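"""Reading and writing binary masks as PNG slices or NIfTI volumes.

Binarization rules are fixed and deterministic:

* 8-bit grayscale PNG: pixel value > 127 maps to foreground;
* NIfTI: voxel value > 0.5 maps to foreground.

NIfTI orientation headers are deliberately ignored beyond axis order — a
volume of shape ``(H, W, Z)`` is split along its third axis, ascending, with
index 0 taken as the bottom of the head. The fusion and evaluation methods
are orientation-agnostic, but callers combining files from different sources
must ensure consistent slice ordering themselves.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from PIL import Image

from .types import BinaryMask, MaskSeries, ShapeError

__all__ = [
    "read_mask",
    "write_mask",
    "read_series",
    "write_series_png",
    "write_series_nifti",
]

PNG_THRESHOLD = 127  # strictly-greater-than, on 8-bit grayscale
NIFTI_THRESHOLD = 0.5


def read_mask(path: str | os.PathLike, format: str | None = None) -> BinaryMask:
    """Read one 2-D binary mask from a PNG file or single-slice NIfTI.

    ``format`` is ``"png"`` or ``"nifti-slice"``; if omitted it is inferred
    from the file extension.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "png":
        return _read_png(path)
    if fmt == "nifti-slice":
        arr = _load_nifti_array(path)
        if arr.ndim == 3 and arr.shape[2] == 1:
            arr = arr[:, :, 0]
        if arr.ndim != 2:
            raise ShapeError(
                f"{path}: expected a single 2-D slice, got shape {arr.shape}"
            )
        return BinaryMask((arr > NIFTI_THRESHOLD).astype(np.uint8))
    raise ValueError(f"unknown format {fmt!r}")


def write_mask(
    mask: BinaryMask, path: str | os.PathLike, format: str | None = None
) -> None:
    """Write one mask; PNG foreground is stored as 255, NIfTI as 1."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "png":
        img = Image.fromarray((mask.pixels * 255).astype(np.uint8), mode="L")
        try:
            img.save(path, format="PNG")
        except OSError as exc:
            raise OSError(f"cannot write PNG to {path}: {exc}") from exc
    elif fmt == "nifti-slice":
        _save_nifti(mask.pixels[:, :, np.newaxis], path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_series(
    source: str | os.PathLike | Sequence[str | os.PathLike],
    series_id: str | None = None,
) -> MaskSeries:
    """Read an ordered mask series.

    ``source`` may be a list of per-slice image paths (order preserved), a
    directory of PNGs (lexicographic file order defines slice order), or a
    NIfTI volume split along its third axis.
    """
    if isinstance(source, (str, os.PathLike)):
        path = Path(source)
        if path.is_dir():
            paths = sorted(path.glob("*.png"))
            if not paths:
                raise FileNotFoundError(f"no PNG slices found in {path}")
            return _series_from_paths(paths, series_id or path.name)
        if _infer_format(path) == "nifti-slice":
            arr = _load_nifti_array(path)
            if arr.ndim != 3:
                raise ShapeError(f"{path}: expected a 3-D volume, got {arr.shape}")
            slices = [
                BinaryMask((arr[:, :, k] > NIFTI_THRESHOLD).astype(np.uint8))
                for k in range(arr.shape[2])
            ]
            return MaskSeries(slices, series_id or path.stem)
        return MaskSeries([read_mask(path)], series_id or path.stem)
    paths = [Path(p) for p in source]
    if not paths:
        raise ValueError("need at least one slice path")
    return _series_from_paths(paths, series_id or paths[0].parent.name)


def write_series_png(series: MaskSeries, directory: str | os.PathLike) -> list[Path]:
    """Write one zero-padded PNG per slice; returns the paths in slice order."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, mask in enumerate(series):
        p = directory / f"slice_{i + 1:03d}.png"
        write_mask(mask, p, "png")
        paths.append(p)
    return paths


def write_series_nifti(series: MaskSeries, path: str | os.PathLike) -> Path:
    """Write the series as one NIfTI volume, third axis = slice index."""
    vol = np.moveaxis(series.stack(), 0, 2)
    _save_nifti(vol, Path(path))
    return Path(path)


def _series_from_paths(paths: Sequence[Path], series_id: str) -> MaskSeries:
    slices = []
    shape0: tuple[int, int] | None = None
    for i, p in enumerate(paths):
        m = read_mask(p)
        if shape0 is None:
            shape0 = m.shape
        elif m.shape != shape0:
            raise ShapeError(
                f"slice {i + 1} ({p}) has shape {m.shape}, expected {shape0}"
            )
        slices.append(m)
    return MaskSeries(slices, series_id)


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".png"):
        return "png"
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti-slice"
    raise ValueError(f"cannot infer mask format from {path.name!r}")


def _read_png(path: Path) -> BinaryMask:
    try:
        img = Image.open(path)
    except OSError as exc:
        raise OSError(f"cannot read PNG at {path}: {exc}") from exc
    with img:
        arr = np.asarray(img.convert("L"))
    if arr.ndim != 2:
        raise ShapeError(f"{path}: expected 2-D grayscale image, got {arr.shape}")
    return BinaryMask((arr > PNG_THRESHOLD).astype(np.uint8))


def _load_nifti_array(path: Path) -> np.ndarray:
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise OSError(f"cannot read NIfTI at {path}: {exc}") from exc
    return np.asarray(img.get_fdata())


def _save_nifti(vol: np.ndarray, path: Path) -> None:
    img = nib.Nifti1Image(vol.astype(np.uint8), affine=np.eye(4))
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise OSError(f"cannot write NIfTI to {path}: {exc}") from exc
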