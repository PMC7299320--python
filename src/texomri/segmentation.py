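"""Semi-automatic lesion delineation on the subtraction image.

The delineation pipeline mirrors common semi-automatic lesion workflows in
breast DCE-MRI: an operator supplies a loose region of interest around the
enhancing lesion, then within the ROI an Otsu threshold binarizes the pixels,
morphological erosion removes tendrils, the largest eight-connected component
is kept as the unique lesion candidate, and a matching dilation restores the
margin.  The resulting contour is reused verbatim on the co-registered pre-
and post-contrast slices.

Binarization polarity is foreground = above threshold, since contrast uptake
renders lesions bright on subtraction images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.morphology import disk, footprint_rectangle

from .preprocessing import SliceImage

__all__ = [
    "ROIPolygon",
    "MorphologyParams",
    "SegmentationError",
    "otsu_threshold",
    "largest_component8",
    "segment_lesion",
    "transfer_mask",
]

_EIGHT = np.ones((3, 3), dtype=bool)


class SegmentationError(RuntimeError):
    """Raised when the delineation pipeline cannot produce a lesion mask."""


@dataclass
class ROIPolygon:
    """Operator-drawn region of interest as an ordered (row, col) vertex list."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (row, col)")
        if len(self.vertices) < 3:
            raise ValueError("a polygon needs at least 3 vertices")

    def rasterize(self, shape: tuple) -> np.ndarray:
        """Filled binary mask of the polygon interior on a grid of `shape`."""
        r = self.vertices[:, 0]
        c = self.vertices[:, 1]
        if r.min() < 0 or c.min() < 0 or r.max() > shape[0] - 1 or c.max() > shape[1] - 1:
            raise ValueError("ROI polygon extends outside the image")
        rr, cc = draw_polygon(r, c, shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        return mask


@dataclass
class MorphologyParams:
    erosion_radius: int = 2
    dilation_radius: int = 2
    structuring_element: str = "disk"

    def __post_init__(self) -> None:
        if self.erosion_radius < 0 or self.dilation_radius < 0:
            raise ValueError("morphology radii must be non-negative")
        if self.structuring_element not in ("disk", "square"):
            raise ValueError("structuring_element must be 'disk' or 'square'")

    def footprint(self, radius: int) -> np.ndarray:
        if self.structuring_element == "disk":
            return disk(radius)
        side = 2 * radius + 1
        return footprint_rectangle((side, side))


def otsu_threshold(pixels: Sequence[float], n_bins: int = 256) -> float:
    """Threshold maximizing between-class variance over a histogram of `pixels`.

    The histogram spans the observed min-max range with `n_bins` bins; the
    candidate thresholds are the interior bin edges and the lowest qualifying
    edge wins ties.  Raises on constant input, where no split exists.
    """
    x = np.asarray(pixels, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 pixels")
    if n_bins < 2:
        raise ValueError("need at least 2 histogram bins")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        raise ValueError("constant input: Otsu threshold undefined")
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    w = counts.astype(float) / counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    # Cumulative class probability / mean below each interior edge.
    omega = np.cumsum(w)[:-1]
    mu_cum = np.cumsum(w * centers)[:-1]
    mu_total = float(np.sum(w * centers))
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu_cum) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    best = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer
    return float(edges[best + 1])


def largest_component8(mask: np.ndarray) -> np.ndarray:
    """Largest eight-connected foreground component of a binary mask.

    Ties are broken in favor of the component whose first pixel comes earliest
    in raster order, which is exactly the labelling order of
    ``scipy.ndimage.label``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SegmentationError("empty mask: no foreground component")
    labels, n = ndimage.label(mask, structure=_EIGHT)
    sizes = np.bincount(labels.ravel())[1:]
    # np.argmax keeps the lowest label on ties; scipy labels in raster order.
    keep = int(np.argmax(sizes)) + 1
    return labels == keep


def segment_lesion(
    subtraction: SliceImage,
    roi: ROIPolygon,
    params: MorphologyParams | None = None,
    n_bins: int = 256,
) -> np.ndarray:
    """Delineate the lesion inside `roi` on a subtraction slice.

    Pipeline: restrict to the ROI interior -> Otsu threshold on the ROI pixels
    -> binarize (foreground above threshold) -> erode -> keep the largest
    eight-connected component -> dilate -> clip to the ROI.

    Raises :class:`SegmentationError` with diagnostics if the foreground
    vanishes at any stage (e.g. erosion removes everything).
    """
    params = params or MorphologyParams()
    roi_mask = roi.rasterize(subtraction.shape)
    if not roi_mask.any():
        raise SegmentationError("ROI rasterizes to an empty region")
    thr = otsu_threshold(subtraction.grid[roi_mask], n_bins=n_bins)
    binary = (subtraction.grid > thr) & roi_mask
    if not binary.any():
        raise SegmentationError(f"no pixels above Otsu threshold {thr:.4g}")
    if params.erosion_radius > 0:
        binary = ndimage.binary_erosion(
            binary, structure=params.footprint(params.erosion_radius)
        )
        if not binary.any():
            raise SegmentationError(
                f"mask vanished after erosion (radius={params.erosion_radius})"
            )
    lesion = largest_component8(binary)
    if params.dilation_radius > 0:
        lesion = ndimage.binary_dilation(
            lesion, structure=params.footprint(params.dilation_radius)
        )
    lesion &= roi_mask  # dilation must not leak outside the operator's ROI
    if not lesion.any():
        raise SegmentationError("mask empty after clipping to ROI")
    return lesion


def transfer_mask(mask: np.ndarray, target: SliceImage) -> np.ndarray:
    """Bind a lesion mask to a co-registered slice of identical shape."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != target.shape:
        raise ValueError(f"shape mismatch: mask {mask.shape} vs image {target.shape}")
    return mask.copy()
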