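"""Evaluation indexes: pixel confusion counts, IoU, and exact Hausdorff distance.

IoU (Jaccard index) is overlap pixels over union pixels. The Hausdorff
distance is computed between the two masks' contours, each taken as a set of
boundary pixels: ``HD(A, B) = max(h(A, B), h(B, A))`` with the directed
distance ``h(A, B) = max_{a in A} min_{b in B} ||a - b||``. Both directed
distances are evaluated exactly (no percentile or rank approximation), in
pixel units.

Empty-mask conventions
----------------------
A whole-head series includes slices with no brain tissue, where the ground
truth is entirely background, so the degenerate cases must be defined:

* both masks empty → IoU = 1.0 and HD = 0.0 (a perfect all-background
  prediction scores perfectly);
* exactly one mask empty → IoU = 0.0 by the formula, and HD is *undefined*
  (``HD_UNDEFINED`` = NaN): there is no boundary to measure against. Undefined
  slices are excluded from mean HD and reported via ``n_undefined_hd`` rather
  than silently dropped or replaced by an arbitrary large constant.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .types import BinaryMask, MaskSeries, require_same_series, require_same_shape

__all__ = [
    "ConfusionCounts",
    "EvalResult",
    "SliceEval",
    "HD_UNDEFINED",
    "confusion_counts",
    "iou",
    "boundary_pixels",
    "directed_hausdorff",
    "hausdorff",
    "evaluate_series",
    "hd_is_defined",
]

#: Sentinel for a Hausdorff distance that cannot be measured (one empty mask).
HD_UNDEFINED = float("nan")


def hd_is_defined(hd: float) -> bool:
    return not math.isnan(hd)


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies of a predicted mask against ground truth.

    ``fp`` is the slice's contribution to a model's over-segmentation total
    (num_overseg); ``fn`` contributes to its missed-pixel total (num_miss).
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )

    def iou(self) -> float:
        union = self.tp + self.fp + self.fn
        if union == 0:
            return 1.0
        return self.tp / union


@dataclass(frozen=True)
class SliceEval:
    slice_index: int  # 1-based, bottom of head = 1
    iou: float
    hd: float  # NaN when undefined


@dataclass
class EvalResult:
    """Per-slice and aggregate scores for one predicted series vs ground truth.

    ``mean_iou`` is the unweighted mean of per-slice IoU; ``pooled_iou`` is
    the IoU of the confusion counts summed over all slices (so large slices
    weigh more). ``mean_hd`` averages only the slices where HD is defined.
    """

    series_id: str
    per_slice: list[SliceEval]
    mean_iou: float
    pooled_iou: float
    mean_hd: float  # NaN if no slice has a defined HD
    n_undefined_hd: int

    def to_rows(self) -> list[dict]:
        """Rows for the per-slice CSV report."""
        return [
            {
                "series_id": self.series_id,
                "slice_index": s.slice_index,
                "iou": s.iou,
                "hd": "" if not hd_is_defined(s.hd) else s.hd,
                "hd_defined": hd_is_defined(s.hd),
            }
            for s in self.per_slice
        ]

    def summary(self) -> dict:
        return {
            "series_id": self.series_id,
            "mean_iou": self.mean_iou,
            "pooled_iou": self.pooled_iou,
            "mean_hd": None if not hd_is_defined(self.mean_hd) else self.mean_hd,
            "n_undefined_hd": self.n_undefined_hd,
            "n_slices": len(self.per_slice),
        }


def confusion_counts(pred: BinaryMask, gt: BinaryMask) -> ConfusionCounts:
    """Pixel-wise tp/fp/fn/tn of ``pred`` against ``gt``."""
    require_same_shape(pred, gt)
    p = pred.bool()
    g = gt.bool()
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def iou(pred: BinaryMask, gt: BinaryMask) -> float:
    """Intersection over union in [0, 1]; 1.0 when both masks are empty."""
    return confusion_counts(pred, gt).iou()


def boundary_pixels(mask: BinaryMask) -> np.ndarray:
    """Contour of the mask as an ``(n, 2)`` array of (row, col) coordinates.

    A foreground pixel is on the boundary iff at least one of its 4-neighbors
    is background, with positions outside the image counting as background —
    so foreground touching the image border is always boundary.
    """
    fg = mask.bool()
    if not fg.any():
        return np.empty((0, 2), dtype=np.intp)
    interior = ndimage.binary_erosion(
        fg, structure=_CROSS, border_value=0
    )
    return np.argwhere(fg & ~interior)


_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


def directed_hausdorff(A: np.ndarray, B: np.ndarray) -> float:
    """Exact ``max_{a in A} min_{b in B}`` Euclidean distance, pixel units.

    ``A`` and ``B`` are ``(n, 2)`` coordinate arrays. Either set empty →
    ``HD_UNDEFINED``.
    """
    A = np.asarray(A, dtype=float).reshape(-1, 2)
    B = np.asarray(B, dtype=float).reshape(-1, 2)
    if len(A) == 0 or len(B) == 0:
        return HD_UNDEFINED
    # all-pairs squared distances; exact max-min, no approximation
    d2 = cdist(A, B, metric="sqeuclidean")
    return float(np.sqrt(d2.min(axis=1).max()))


def hausdorff(pred: BinaryMask, gt: BinaryMask) -> float:
    """Symmetric Hausdorff distance between the two masks' contours.

    Both masks empty → 0.0; exactly one empty → ``HD_UNDEFINED``.
    """
    require_same_shape(pred, gt)
    a = boundary_pixels(pred)
    b = boundary_pixels(gt)
    if len(a) == 0 and len(b) == 0:
        return 0.0
    if len(a) == 0 or len(b) == 0:
        return HD_UNDEFINED
    return max(directed_hausdorff(a, b), directed_hausdorff(b, a))


def evaluate_series(preds: MaskSeries, gts: MaskSeries) -> EvalResult:
    """Per-slice IoU/HD plus aggregates for one predicted series."""
    require_same_series(preds, gts)
    per_slice: list[SliceEval] = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    hds: list[float] = []
    n_undef = 0
    for i, (p, g) in enumerate(zip(preds, gts)):
        cc = confusion_counts(p, g)
        pooled = pooled + cc
        hd = hausdorff(p, g)
        if hd_is_defined(hd):
            hds.append(hd)
        else:
            n_undef += 1
        per_slice.append(SliceEval(i + 1, cc.iou(), hd))
    mean_iou = float(np.mean([s.iou for s in per_slice]))
    mean_hd = float(np.mean(hds)) if hds else HD_UNDEFINED
    return EvalResult(
        series_id=preds.series_id,
        per_slice=per_slice,
        mean_iou=mean_iou,
        pooled_iou=pooled.iou(),
        mean_hd=mean_hd,
        n_undefined_hd=n_undef,
    )


def write_eval_csv(results: list[EvalResult], path: str | os.PathLike) -> None:
    """Per-slice CSV: series_id, slice_index, iou, hd, hd_defined."""
    import pandas as pd

    rows = [r for res in results for r in res.to_rows()]
    pd.DataFrame(
        rows, columns=["series_id", "slice_index", "iou", "hd", "hd_defined"]
    ).to_csv(path, index=False)


def write_eval_summary(results: list[EvalResult], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump([r.summary() for r in results], fh, indent=2, sort_keys=True)
        fh.write("\n")
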