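"""Synthetic head-series phantoms and simulated segmenter outputs.

The phantom emulates the slice-wise anatomy of a whole-head CT series: the
brain cross-section is small on the bottom slices, largest in the middle,
and shrinks to nothing at the top of the head; slices past the vertex are
all background. Low slices additionally carry *distractor* structures
(periorbital / skull-base look-alikes) disjoint from the brain region, which
biased segmenters preferentially mistake for brain.

Brain regions are perturbed ellipses (low-frequency radial noise), not
anatomical atlases: the fusion method only consumes masks, so one dominant
component with a smooth boundary is the realism that matters.

Simulated segmenters apply, in order: boundary jitter, uniform dilation or
erosion, spurious foreground blobs sampled outside the true region
(preferentially on distractors), and dropout bites. Dilation and blobs
produce only false positives; erosion and bites only false negatives — so a
dilate-only profile has ``num_miss = 0`` and an erode-only profile has
``num_overseg = 0`` exactly, by construction. Every generator is a pure
function of its explicit seed.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io_masks import write_series_nifti, write_series_png
from .types import BinaryMask, MaskSeries, require_same_series

__all__ = [
    "PhantomConfig",
    "SegmenterProfile",
    "default_area_profile",
    "generate_phantom_series",
    "simulate_model_output",
    "paper_like_profiles",
    "benchmark_bundle",
]

DEFAULT_SEED = 20210101


def default_area_profile(n_slices: int) -> list[float]:
    """Unimodal per-slice area factors: small at the bottom, maximal mid-head,
    zero on the final (above-vertex) slice."""
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    factors = [
        math.sin(math.pi * (i + 1) / (n_slices + 1)) for i in range(n_slices)
    ]
    factors[-1] = 0.0  # top slice is past the vertex: no brain tissue
    return factors


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and randomness of one phantom head series."""

    n_slices: int = 31
    height: int = 128
    width: int = 128
    base_radius: float = 42.0  # mid-head brain radius, pixels
    area_profile: tuple[float, ...] | None = None  # None -> default unimodal
    distractor_rate: float = 0.8  # per-slice blob probability, lowest quartile
    seed: int = DEFAULT_SEED

    def resolved_area_profile(self) -> list[float]:
        if self.area_profile is None:
            return default_area_profile(self.n_slices)
        prof = list(self.area_profile)
        if len(prof) != self.n_slices:
            raise ValueError(
                f"area_profile length {len(prof)} != n_slices {self.n_slices}"
            )
        if any(not (0.0 <= f <= 1.0) for f in prof):
            raise ValueError("area_profile factors must lie in [0, 1]")
        return prof


@dataclass(frozen=True)
class SegmenterProfile:
    """Controllable error profile of one simulated segmentation model.

    ``dilate_px``/``erode_px`` give a uniform over-/under-segmentation bias
    (mutually exclusive); ``blob_rate`` is the expected number of spurious
    foreground blobs per slice (radius ``blob_radius``), placed outside the
    true region and preferentially on distractor structures; ``dropout_rate``
    is the per-slice probability of losing one bite of radius ``blob_radius``
    out of the true region; ``jitter`` is the flip probability for pixels in
    the one-pixel band around the true boundary.
    """

    model_id: str
    dilate_px: int = 0
    erode_px: int = 0
    blob_rate: float = 0.0
    blob_radius: int = 4
    dropout_rate: float = 0.0
    jitter: float = 0.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.dilate_px > 0 and self.erode_px > 0:
            raise ValueError("a profile cannot both dilate and erode")
        if self.dilate_px < 0 or self.erode_px < 0:
            raise ValueError("dilate_px/erode_px must be >= 0")


def generate_phantom_series(
    config: PhantomConfig,
) -> tuple[MaskSeries, MaskSeries]:
    """Build the ground-truth brain series and the distractor series.

    Deterministic given ``config.seed``. Slice ``i``'s brain region is a
    perturbed ellipse whose area is proportional to ``area_profile[i]``;
    factor-zero slices are empty. Distractor masks mark non-brain structures
    disjoint from the brain on the lowest quartile of slices.
    """
    profile = config.resolved_area_profile()
    nonzero = [f for f in profile if f > 0]
    if nonzero and config.base_radius * math.sqrt(min(nonzero)) < 1.0:
        raise ValueError(
            "degenerate geometry: brain radius < 1 px at the smallest "
            f"nonzero area factor {min(nonzero):.4f}"
        )
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rows = np.arange(h)[:, None] - cy
    cols = np.arange(w)[None, :] - cx

    gt_slices: list[BinaryMask] = []
    distractor_slices: list[BinaryMask] = []
    low_quartile = max(1, config.n_slices // 4)
    for i, f in enumerate(profile):
        if f <= 0:
            gt = np.zeros((h, w), dtype=np.uint8)
        else:
            r0 = config.base_radius * math.sqrt(f)
            # low-frequency radial perturbation keeps one smooth component
            amps = rng.normal(0.0, 0.04, size=3)
            phases = rng.uniform(0.0, 2.0 * math.pi, size=3)
            ecc = rng.uniform(0.85, 1.0)  # slight ellipse
            jy = rng.uniform(-2.0, 2.0)
            jx = rng.uniform(-2.0, 2.0)
            rr = rows - jy
            cc = cols - jx
            rho_e = np.hypot(rr / ecc, cc)
            th = np.arctan2(rr, cc)
            r_t = r0 * (
                1.0
                + sum(
                    a * np.cos((k + 2) * th + p)
                    for k, (a, p) in enumerate(zip(amps, phases))
                )
            )
            gt = (rho_e <= r_t).astype(np.uint8)
        dist = np.zeros((h, w), dtype=np.uint8)
        if i < low_quartile and rng.uniform() < config.distractor_rate:
            dist = _distractor_blobs(gt, rng, h, w, config.base_radius)
        gt_slices.append(BinaryMask(gt))
        distractor_slices.append(BinaryMask(dist))
    return (
        MaskSeries(gt_slices, series_id="gt"),
        MaskSeries(distractor_slices, series_id="distractors"),
    )


def _distractor_blobs(
    gt: np.ndarray, rng: np.random.Generator, h: int, w: int, base_radius: float
) -> np.ndarray:
    """1-3 small round structures away from (and clipped against) the brain."""
    out = np.zeros((h, w), dtype=np.uint8)
    n = int(rng.integers(1, 4))
    margin = 3.0
    for _ in range(n):
        r = rng.uniform(0.08, 0.18) * base_radius + 2.0
        for _attempt in range(20):
            y = rng.uniform(r, h - 1 - r)
            x = rng.uniform(r, w - 1 - r)
            yy = np.arange(h)[:, None] - y
            xx = np.arange(w)[None, :] - x
            blob = (np.hypot(yy, xx) <= r)
            near = ndimage.binary_dilation(gt.astype(bool), iterations=int(margin))
            if not (blob & near).any():
                out[blob] = 1
                break
    return out


def simulate_model_output(
    gt: MaskSeries, distractors: MaskSeries, profile: SegmenterProfile
) -> MaskSeries:
    """Apply one segmenter's error profile to the ground truth, slice-wise.

    Deterministic given ``profile.seed``. An all-zero profile is the
    identity.
    """
    require_same_series(gt, distractors)
    rng = np.random.default_rng(profile.seed)
    out: list[BinaryMask] = []
    for g, d in zip(gt, distractors):
        fg = g.bool()
        pred = fg.copy()

        if profile.jitter > 0 and fg.any():
            band = ndimage.binary_dilation(fg) ^ ndimage.binary_erosion(fg)
            flips = band & (rng.uniform(size=fg.shape) < profile.jitter)
            pred ^= flips

        if profile.dilate_px > 0:
            pred = ndimage.binary_dilation(pred, iterations=profile.dilate_px)
        elif profile.erode_px > 0:
            pred = ndimage.binary_erosion(pred, iterations=profile.erode_px)

        n_blobs = int(rng.poisson(profile.blob_rate)) if profile.blob_rate > 0 else 0
        for _ in range(n_blobs):
            pred |= _spurious_blob(fg, d.bool(), rng, profile.blob_radius)

        if profile.dropout_rate > 0 and fg.any():
            if rng.uniform() < profile.dropout_rate:
                pred &= ~_bite(fg, rng, profile.blob_radius)

        out.append(BinaryMask(pred.astype(np.uint8)))
    return MaskSeries(out, series_id=profile.model_id)


def _spurious_blob(
    gt: np.ndarray, distractor: np.ndarray, rng: np.random.Generator, radius: int
) -> np.ndarray:
    """One false-alarm blob, clipped to stay disjoint from the true region."""
    h, w = gt.shape
    on_distractor = distractor.any() and rng.uniform() < 0.7
    if on_distractor:
        pts = np.argwhere(distractor)
        y, x = pts[rng.integers(len(pts))]
    else:
        bg = np.argwhere(~gt)
        if len(bg) == 0:
            return np.zeros_like(gt, dtype=bool)
        y, x = bg[rng.integers(len(bg))]
    yy = np.arange(h)[:, None] - y
    xx = np.arange(w)[None, :] - x
    blob = np.hypot(yy, xx) <= radius
    return blob & ~gt  # exact fp accounting: blobs never overlap true tissue


def _bite(gt: np.ndarray, rng: np.random.Generator, radius: int) -> np.ndarray:
    """A disk centered on a random true-foreground pixel."""
    pts = np.argwhere(gt)
    y, x = pts[rng.integers(len(pts))]
    h, w = gt.shape
    yy = np.arange(h)[:, None] - y
    xx = np.arange(w)[None, :] - x
    return np.hypot(yy, xx) <= radius


def paper_like_profiles(seed: int = DEFAULT_SEED) -> list[SegmenterProfile]:
    """Three simulated segmenters mimicking the U-Net family's reported biases.

    All three over-segment (more false positives than misses), with
    different severity: a moderately over-segmenting model with
    distractor-linked false alarms; a heavily over-segmenting model that
    bleeds at the skull base; and a strong model with few, small false
    alarms. Derived seeds keep the three models' randomness independent.
    """
    return [
        SegmenterProfile(
            "unet",
            dilate_px=1,
            blob_rate=0.6,
            blob_radius=4,
            dropout_rate=0.10,
            jitter=0.15,
            seed=(seed * 3 + 1) % (2**31),
        ),
        SegmenterProfile(
            "unet2p",
            dilate_px=2,
            blob_rate=1.5,
            blob_radius=5,
            dropout_rate=0.05,
            jitter=0.15,
            seed=(seed * 3 + 2) % (2**31),
        ),
        SegmenterProfile(
            "unet3p",
            dilate_px=1,
            blob_rate=0.2,
            blob_radius=3,
            dropout_rate=0.10,
            jitter=0.10,
            seed=(seed * 3 + 3) % (2**31),
        ),
    ]


def benchmark_bundle(
    config: PhantomConfig,
    profiles: Sequence[SegmenterProfile],
    out_dir: str | os.PathLike,
    formats: Sequence[str] = ("png",),
) -> dict:
    """Write a full synthetic benchmark to disk and return its manifest.

    Layout: ``gt/`` and one directory per model with per-slice PNGs (and/or
    a ``<name>.nii`` volume), ``distractors/``, and ``manifest.json`` echoing
    the full configuration so the bundle can be regenerated byte-identically.
    """
    if len(profiles) < 2:
        raise ValueError("a benchmark bundle needs at least two segmenter profiles")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gt, distractors = generate_phantom_series(config)
    series = {"gt": gt, "distractors": distractors}
    for prof in profiles:
        series[prof.model_id] = simulate_model_output(gt, distractors, prof)

    paths: dict[str, dict[str, str]] = {}
    for name, s in series.items():
        entry: dict[str, str] = {}
        if "png" in formats:
            write_series_png(s, out_dir / name)
            entry["png_dir"] = name
        if "nifti" in formats:
            write_series_nifti(s, out_dir / f"{name}.nii")
            entry["nifti"] = f"{name}.nii"
        paths[name] = entry

    manifest = {
        "phantom_config": {
            **asdict(config),
            "area_profile": config.resolved_area_profile(),
        },
        "profiles": [asdict(p) for p in profiles],
        "formats": list(formats),
        "series": paths,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
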