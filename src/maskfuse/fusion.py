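"""Adaptive result fusion for binary segmentation masks.

Each segmentation model is profiled on a labeled calibration set by totaling
its over-segmented pixels (``num_overseg``, false positives) and missed
brain pixels (``num_miss``, false negatives). The fusion rule follows from
the dominant error direction:

* models that over-segment (``num_overseg > num_miss``) are combined by
  **intersection**, which can only remove false positives;
* models that under-segment (``num_miss > num_overseg``) are combined by
  **union**, which can only recover missed pixels.

When two models disagree in direction, a third model breaks the tie by
pairing with whichever model shares its direction. If no two models agree
(including exact-equality "neutral" profiles), the plan defaults to
intersection over all models — U-Net-family segmenters in practice produce
more false positives than misses — and the rationale string records that the
default was taken.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from enum import Enum
from functools import reduce
from typing import Sequence

import numpy as np

from .metrics import confusion_counts
from .types import BinaryMask, MaskSeries, ShapeError, require_same_series

__all__ = [
    "ErrorDirection",
    "ModelErrorProfile",
    "FusionPlan",
    "accumulate_profile",
    "select_strategy",
    "fuse",
    "fuse_series",
]


class ErrorDirection(str, Enum):
    OVER = "OVER"  # num_overseg > num_miss
    UNDER = "UNDER"  # num_miss > num_overseg
    NEUTRAL = "NEUTRAL"  # exactly equal


@dataclass(frozen=True)
class ModelErrorProfile:
    """A model's aggregated error counts over a labeled calibration set."""

    model_id: str
    num_overseg: int
    num_miss: int
    n_slices: int = 0

    @property
    def direction(self) -> ErrorDirection:
        if self.num_overseg > self.num_miss:
            return ErrorDirection.OVER
        if self.num_miss > self.num_overseg:
            return ErrorDirection.UNDER
        return ErrorDirection.NEUTRAL


@dataclass(frozen=True)
class FusionPlan:
    """The chosen set operation and the models it applies to."""

    operation: str  # "union" | "intersection"
    model_ids: tuple[str, ...]
    rationale: str

    def __post_init__(self) -> None:
        if self.operation not in ("union", "intersection"):
            raise ValueError(f"operation must be union|intersection, got {self.operation!r}")
        if len(self.model_ids) < 2:
            raise ValueError("a fusion plan needs at least two models")
        if len(set(self.model_ids)) != len(self.model_ids):
            raise ValueError("model_ids must be distinct")

    def to_json(self) -> str:
        return json.dumps(
            {
                "operation": self.operation,
                "model_ids": list(self.model_ids),
                "rationale": self.rationale,
            },
            indent=2,
        )


def accumulate_profile(
    preds: MaskSeries, gts: MaskSeries, model_id: str
) -> ModelErrorProfile:
    """Sum per-slice fp into ``num_overseg`` and fn into ``num_miss``."""
    require_same_series(preds, gts)
    overseg = 0
    miss = 0
    for p, g in zip(preds, gts):
        cc = confusion_counts(p, g)
        overseg += cc.fp
        miss += cc.fn
    return ModelErrorProfile(model_id, overseg, miss, n_slices=len(preds))


def select_strategy(profiles: Sequence[ModelErrorProfile]) -> FusionPlan:
    """Choose union vs intersection from the models' error directions.

    Intersection over all over-segmenting models when at least two
    over-segment; union over all under-segmenting models when at least two
    under-segment; otherwise intersection over all models as the audited
    default for an unresolvable tie.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two model profiles to plan a fusion")
    ids = [p.model_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate model_ids in profiles: {ids}")

    trace = "; ".join(
        f"{p.model_id}: num_overseg={p.num_overseg}, num_miss={p.num_miss}"
        f" -> {p.direction.value}"
        for p in profiles
    )
    over = [p for p in profiles if p.direction is ErrorDirection.OVER]
    under = [p for p in profiles if p.direction is ErrorDirection.UNDER]

    if len(over) >= 2:
        return FusionPlan(
            "intersection",
            tuple(p.model_id for p in over),
            f"{trace}. {len(over)} models over-segment: intersection over them.",
        )
    if len(under) >= 2:
        return FusionPlan(
            "union",
            tuple(p.model_id for p in under),
            f"{trace}. {len(under)} models under-segment: union over them.",
        )
    return FusionPlan(
        "intersection",
        tuple(ids),
        f"{trace}. tie-unresolved default: intersection over all models.",
    )


def fuse(masks: Sequence[BinaryMask], operation: str) -> BinaryMask:
    """Pixel-wise AND (intersection) or OR (union) of two or more masks."""
    if len(masks) < 2:
        raise ValueError("fusion needs at least two masks")
    shape0 = masks[0].shape
    for i, m in enumerate(masks):
        if m.shape != shape0:
            raise ShapeError(f"mask {i} has shape {m.shape}, expected {shape0}")
    arrays = [m.bool() for m in masks]
    if operation == "intersection":
        out = reduce(np.logical_and, arrays)
    elif operation == "union":
        out = reduce(np.logical_or, arrays)
    else:
        raise ValueError(f"operation must be union|intersection, got {operation!r}")
    return BinaryMask(out.astype(np.uint8))


def fuse_series(
    series_by_model: dict[str, MaskSeries], plan: FusionPlan
) -> MaskSeries:
    """Apply the plan slice-by-slice over the selected models' series."""
    missing = [m for m in plan.model_ids if m not in series_by_model]
    if missing:
        raise ValueError(f"fusion plan references absent model series: {missing}")
    selected = [series_by_model[m] for m in plan.model_ids]
    first = selected[0]
    for s in selected[1:]:
        require_same_series(first, s)
    fused = [
        fuse([s[i] for s in selected], plan.operation) for i in range(len(first))
    ]
    label = f"fusion_{plan.operation}_" + "+".join(plan.model_ids)
    return MaskSeries(fused, series_id=label)
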