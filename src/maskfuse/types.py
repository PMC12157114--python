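"""Core containers: single-slice binary masks and ordered slice stacks.

Conventions used throughout the package:

* pixel grid is indexed ``(row, col)``, 0-based, row 0 at the top of the image;
* foreground (brain) is 1, background is 0;
* slices are ordered bottom-of-head first; user-facing slice indices are
  1-based (slice 1 = bottom), internal list indices are 0-based;
* geometry is abstract pixels — no physical spacing is attached, and distances
  are reported in pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = ["BinaryMask", "MaskSeries", "ShapeError"]


class ShapeError(ValueError):
    """Raised when masks or series do not have compatible dimensions."""


@dataclass(frozen=True)
class BinaryMask:
    """A single slice's foreground/background labeling.

    Parameters
    ----------
    pixels
        2-D array coercible to values {0, 1}; stored as ``uint8``.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ShapeError(f"mask must be 2-D, got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ShapeError(f"mask must be at least 1x1, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"mask values must be exactly 0 or 1, got {uniq}")
        object.__setattr__(self, "pixels", arr.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def bool(self) -> np.ndarray:
        """Pixels as a boolean array (foreground True)."""
        return self.pixels.astype(bool)

    def foreground_count(self) -> int:
        return int(self.pixels.sum())

    def is_empty(self) -> bool:
        return not self.pixels.any()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.shape == other.shape and bool(
            np.array_equal(self.pixels, other.pixels)
        )

    def __hash__(self) -> int:
        return hash((self.shape, self.pixels.tobytes()))


@dataclass
class MaskSeries:
    """Ordered stack of equally sized binary masks for one head series.

    ``slices[0]`` is the bottom of the head; the public 1-based index of a
    slice is its list position plus one.
    """

    slices: list[BinaryMask]
    series_id: str = "series"

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise ShapeError("a series needs at least one slice")
        shape0 = self.slices[0].shape
        for i, s in enumerate(self.slices):
            if s.shape != shape0:
                raise ShapeError(
                    f"slice {i + 1} has shape {s.shape}, expected {shape0}"
                )

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self) -> Iterator[BinaryMask]:
        return iter(self.slices)

    def __getitem__(self, idx: int) -> BinaryMask:
        return self.slices[idx]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) shared by all slices."""
        return self.slices[0].shape

    def stack(self) -> np.ndarray:
        """Slices as one ``(n_slices, height, width)`` uint8 array."""
        return np.stack([s.pixels for s in self.slices])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MaskSeries):
            return NotImplemented
        return len(self) == len(other) and all(
            a == b for a, b in zip(self.slices, other.slices)
        )


def require_same_shape(a: BinaryMask, b: BinaryMask) -> None:
    if a.shape != b.shape:
        raise ShapeError(f"mask shapes differ: {a.shape} vs {b.shape}")


def require_same_series(a: MaskSeries, b: MaskSeries) -> None:
    if len(a) != len(b):
        raise ShapeError(f"series lengths differ: {len(a)} vs {len(b)}")
    if a.shape != b.shape:
        raise ShapeError(f"series slice shapes differ: {a.shape} vs {b.shape}")
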