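"""Slice images, subtraction, and lesion-intensity normalization/quantization.

The texture stages all operate on gray levels, not raw MR intensities.  Each
lesion is reduced to a :class:`QuantizedROI`: the masked pixels are normalized
to the window mu +/- 3 sigma (mu, sigma computed over the mask) and the window
is mapped linearly onto ``2**n_bits`` integer levels.  Values outside the
window are clipped, never discarded, so the mask geometry stays intact for
co-occurrence and run-length neighbor pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "SliceImage",
    "NormalizationParams",
    "QuantizedROI",
    "subtract",
    "normalize_quantize",
]

PHASES = ("pre", "post", "subtraction")


@dataclass
class SliceImage:
    """A single 2D grayscale slice tagged with its contrast phase."""

    grid: np.ndarray
    phase: str
    patient_id: str = ""
    pixel_spacing: Optional[float] = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2 or min(self.grid.shape) < 2:
            raise ValueError("slice image must be 2D with at least 2 rows and 2 cols")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("slice image contains non-finite values")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}; expected one of {PHASES}")

    @property
    def shape(self) -> tuple:
        return self.grid.shape


@dataclass
class NormalizationParams:
    mu: float
    sigma: float
    n_bits: int = 8

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 1 <= self.n_bits <= 16:
            raise ValueError("n_bits must be in [1, 16]")


@dataclass
class QuantizedROI:
    """Masked lesion pixels as integer gray levels in [0, n_levels - 1]."""

    grid: np.ndarray
    mask: np.ndarray
    n_levels: int
    params: NormalizationParams
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.grid.shape != self.mask.shape:
            raise ValueError("grid and mask shapes differ")
        if not self.mask.any():
            raise ValueError("mask is empty")
        vals = self.grid[self.mask]
        if vals.min() < 0 or vals.max() > self.n_levels - 1:
            raise ValueError("masked levels outside [0, n_levels - 1]")

    @property
    def levels(self) -> np.ndarray:
        """Masked gray levels as a flat integer array."""
        return self.grid[self.mask]


def subtract(post: SliceImage, pre: SliceImage) -> SliceImage:
    """Pixel-wise ``post - pre`` subtraction image.

    Both slices must belong to the same patient and share a shape; phases are
    not checked beyond that so the antisymmetric identity
    ``subtract(a, b).grid == -subtract(b, a).grid`` holds.
    """
    if post.shape != pre.shape:
        raise ValueError(f"shape mismatch: {post.shape} vs {pre.shape}")
    if post.patient_id != pre.patient_id:
        raise ValueError(
            f"patient mismatch: {post.patient_id!r} vs {pre.patient_id!r}"
        )
    return SliceImage(
        grid=post.grid - pre.grid,
        phase="subtraction",
        patient_id=post.patient_id,
        pixel_spacing=post.pixel_spacing,
    )


def normalize_quantize(image: SliceImage, mask: np.ndarray, n_bits: int = 8) -> QuantizedROI:
    """Normalize masked pixels to mu +/- 3 sigma and quantize to integer levels.

    The window [mu - 3 sigma, mu + 3 sigma] maps linearly onto levels
    0 ... 2**n_bits - 1 using floor assignment; the top edge maps (inclusively)
    to the maximum level and out-of-window values are clipped to the edge
    levels.  A zero-variance ROI is flagged degenerate and set to the middle
    level 2**(n_bits - 1).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape does not match image")
    if not mask.any():
        raise ValueError("mask is empty")
    vals = image.grid[mask]
    mu = float(vals.mean())
    sigma = float(vals.std(ddof=0))
    n_levels = 2 ** n_bits
    out = np.zeros(image.shape, dtype=np.int32)
    if sigma == 0.0:
        out[mask] = n_levels // 2
        return QuantizedROI(
            grid=out,
            mask=mask,
            n_levels=n_levels,
            params=NormalizationParams(mu=mu, sigma=sigma, n_bits=n_bits),
            degenerate=True,
        )
    lo = mu - 3.0 * sigma
    span = 6.0 * sigma
    t = np.clip((vals - lo) / span, 0.0, 1.0)
    levels = np.minimum(np.floor(t * n_levels).astype(np.int32), n_levels - 1)
    out[mask] = levels
    return QuantizedROI(
        grid=out,
        mask=mask,
        n_levels=n_levels,
        params=NormalizationParams(mu=mu, sigma=sigma, n_bits=n_bits),
    )
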