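"""Mask refinement: Gaussian smoothing followed by re-binarization.

The default filter is a 9x9 Gaussian kernel with unit standard deviation;
the smoothed real-valued image is thresholded at 0.5. On a binary mask this
removes isolated foreground specks (their smoothed response is at most the
kernel's center weight, well below 0.5) and fills single-pixel holes (the
complementary response), while leaving large constant regions untouched.

Borders use reflect padding so constant masks are exact fixed points even at
the image edge; with zero padding, foreground touching the border would be
eroded. The threshold comparison is strictly-greater-than, which fixes the
measure-zero case of a response exactly equal to the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import BinaryMask, MaskSeries

__all__ = ["SmoothingKernel", "gaussian_kernel", "smooth_binarize", "smooth_binarize_series"]

DEFAULT_SIZE = 9
DEFAULT_SIGMA = 1.0
DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class SmoothingKernel:
    """A normalized, reflection-symmetric smoothing kernel."""

    size: int
    sigma: float
    weights: np.ndarray

    @property
    def center_weight(self) -> float:
        c = self.size // 2
        return float(self.weights[c, c])


def gaussian_kernel(size: int = DEFAULT_SIZE, sigma: float = DEFAULT_SIGMA) -> SmoothingKernel:
    """Sampled 2-D Gaussian, normalized to sum 1.

    ``weights[i, j] ∝ exp(-((i-c)² + (j-c)²) / (2σ²))`` with c the center
    index. ``size`` must be odd and ≥ 1; ``sigma`` positive.
    """
    if size < 1 or size % 2 == 0:
        raise ValueError(f"kernel size must be odd and >= 1, got {size}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    c = size // 2
    idx = np.arange(size) - c
    g1 = np.exp(-(idx**2) / (2.0 * sigma**2))
    w = np.outer(g1, g1)
    w /= w.sum()
    return SmoothingKernel(size=size, sigma=float(sigma), weights=w)


def smooth_binarize(
    mask: BinaryMask,
    kernel: SmoothingKernel | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> BinaryMask:
    """Convolve the mask (as reals in {0,1}) with the kernel, then threshold.

    Reflect padding at borders; output pixel is foreground iff its smoothed
    response is strictly greater than ``threshold``.
    """
    if kernel is None:
        kernel = gaussian_kernel()
    response = ndimage.convolve(
        mask.pixels.astype(np.float64), kernel.weights, mode="reflect"
    )
    return BinaryMask((response > threshold).astype(np.uint8))


def smooth_binarize_series(
    series: MaskSeries,
    kernel: SmoothingKernel | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> MaskSeries:
    if kernel is None:
        kernel = gaussian_kernel()
    return MaskSeries(
        [smooth_binarize(m, kernel, threshold) for m in series],
        series_id=f"{series.series_id}_filtered",
    )
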