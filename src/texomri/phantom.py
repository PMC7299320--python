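"""Synthetic DCE-MRI cohort generator and deterministic texture fixtures.

The generator emulates the study conditions the analysis assumes: a cohort of
92 single-slice breast DCE-MRI cases (52 FISH-positive, 40 FISH-negative),
each with one enhancing lesion.  Lesion texture is a stationary Gaussian
random field (white noise smoothed with a Gaussian kernel whose width is the
correlation length, rescaled to a target marginal variance).  Intensities are
emitted on a 16-bit-like floating scale, matching MR dynamic range before the
pipeline's own 8-bit quantization.

Phase construction:

    pre  = background + lesion * pre_texture(class)   + noise_pre
    post = pre - noise_pre + lesion * (gain * background + enh_texture(class))
           + noise_post

so the subtraction image ``post - pre`` isolates the enhancement component
plus independent noise.  The class contrast is concentrated in the
enhancement texture (under the defaults its correlation length differs by
class), is diluted in the post-contrast image by the shared, equally strong
pre-contrast texture, and is absent from the pre-contrast image —
reproducing the phase ordering (subtraction > post > pre) the downstream
analysis is meant to detect.

Because the pipeline normalizes each lesion to mu +/- 3 sigma before any
feature is computed, purely additive class mean shifts cancel; class
separation is therefore carried by the textural parameters, and the
``class_separation`` dial interpolates the negative class's enhancement
texture toward the positive class's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from scipy import ndimage

from .preprocessing import NormalizationParams, QuantizedROI, SliceImage
from .segmentation import ROIPolygon

__all__ = [
    "TextureParams",
    "PhantomConfig",
    "CohortCase",
    "generate_cohort",
    "make_fixture",
    "null_config",
]


@dataclass(frozen=True)
class TextureParams:
    """Stationary Gaussian-random-field parameters for one class and phase.

    correlation_length : Gaussian smoothing kernel sigma, pixels.
    field_variance     : marginal variance of the field, intensity^2.
    mean_shift         : constant intensity added inside the lesion.
    """

    correlation_length: float
    field_variance: float
    mean_shift: float


def _default_texture() -> Dict[str, Dict[str, TextureParams]]:
    return {
        "positive": {
            "pre": TextureParams(2.0, 3600.0, 60.0),
            "enh": TextureParams(2.4, 3600.0, 0.0),
        },
        "negative": {
            "pre": TextureParams(2.0, 3600.0, 60.0),
            "enh": TextureParams(1.6, 3600.0, 0.0),
        },
    }


@dataclass
class PhantomConfig:
    n_positive: int = 52
    n_negative: int = 40
    image_size: Tuple[int, int] = (64, 64)
    lesion_radius_range: Tuple[float, float] = (8.0, 13.0)
    background_level: float = 400.0
    enhancement_gain: float = 1.0
    texture: Dict[str, Dict[str, TextureParams]] = field(default_factory=_default_texture)
    noise_sd: float = 20.0
    roi_margin: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("class sizes must be non-negative")
        if min(self.image_size) <= 0:
            raise ValueError("image size must be positive")
        r_max = self.lesion_radius_range[1]
        if 2 * (r_max + self.roi_margin + 2) >= min(self.image_size):
            raise ValueError("lesion radius range exceeds the image frame")


@dataclass
class CohortCase:
    patient_id: str
    pre: SliceImage
    post: SliceImage
    true_mask: np.ndarray
    seed_roi: ROIPolygon
    label: str  # "positive" | "negative"


def _random_field(
    shape: Tuple[int, int], params: TextureParams, rng: np.random.Generator
) -> np.ndarray:
    """Smoothed white noise rescaled to the requested marginal variance."""
    white = rng.standard_normal(shape)
    if params.correlation_length > 0:
        smooth = ndimage.gaussian_filter(white, sigma=params.correlation_length, mode="reflect")
    else:
        smooth = white
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd * np.sqrt(params.field_variance)
    return smooth + params.mean_shift


def _circle_polygon(center: Tuple[float, float], radius: float, n_vertices: int = 24) -> ROIPolygon:
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    verts = np.stack(
        [center[0] + radius * np.sin(theta), center[1] + radius * np.cos(theta)], axis=1
    )
    return ROIPolygon(verts)


def generate_cohort(config: PhantomConfig) -> List[CohortCase]:
    """Generate a synthetic cohort of co-registered pre/post slice pairs.

    Identical seeds give byte-identical cohorts; each case holds its ground
    truth lesion mask and a loose circular seed ROI (the true boundary plus a
    fixed margin) standing in for the operator's hand-drawn region.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.image_size
    cases: List[CohortCase] = []
    labels = ["positive"] * config.n_positive + ["negative"] * config.n_negative
    for idx, label in enumerate(labels):
        pid = f"P{idx + 1:03d}"
        radius = rng.uniform(*config.lesion_radius_range)
        margin = radius + config.roi_margin + 2.0
        cr = rng.uniform(margin, rows - 1 - margin)
        cc = rng.uniform(margin, cols - 1 - margin)
        yy, xx = np.mgrid[0:rows, 0:cols]
        true_mask = (yy - cr) ** 2 + (xx - cc) ** 2 <= radius ** 2

        tex = config.texture[label]
        pre_field = _random_field(config.image_size, tex["pre"], rng)
        enh_field = _random_field(config.image_size, tex["enh"], rng)
        noise_pre = rng.normal(0.0, config.noise_sd, size=config.image_size)
        noise_post = rng.normal(0.0, config.noise_sd, size=config.image_size)

        base = config.background_level + true_mask * pre_field
        enhancement = true_mask * (
            config.enhancement_gain * config.background_level + enh_field
        )
        pre = base + noise_pre
        post = base + enhancement + noise_post

        cases.append(
            CohortCase(
                patient_id=pid,
                pre=SliceImage(pre, "pre", pid),
                post=SliceImage(post, "post", pid),
                true_mask=true_mask,
                seed_roi=_circle_polygon((cr, cc), radius + config.roi_margin),
                label=label,
            )
        )
    return cases


def null_config(seed: int = 0, **kwargs) -> PhantomConfig:
    """A cohort with identical texture parameters in both classes.

    Under this configuration no feature carries class information, so the
    whole downstream pipeline should behave at chance level (screening keeps
    about alpha of the features; cross-validated AUC sits near 0.5).
    """
    tex = _default_texture()
    tex["negative"] = dict(tex["positive"])
    return PhantomConfig(seed=seed, texture=tex, **kwargs)


def separated_config(class_separation: float, seed: int = 0, **kwargs) -> PhantomConfig:
    """Scale the class contrast in the enhancement texture.

    ``class_separation`` linearly interpolates the negative class's
    enhancement-texture parameters between the positive class's values (0,
    no contrast) and the default negative values (1, the default contrast);
    values above 1 extrapolate to stronger contrast.
    """
    tex = _default_texture()
    pos, neg = tex["positive"]["enh"], tex["negative"]["enh"]
    s = float(class_separation)
    tex["negative"]["enh"] = TextureParams(
        correlation_length=pos.correlation_length
        + s * (neg.correlation_length - pos.correlation_length),
        field_variance=pos.field_variance + s * (neg.field_variance - pos.field_variance),
        mean_shift=pos.mean_shift + s * (neg.mean_shift - pos.mean_shift),
    )
    return PhantomConfig(seed=seed, texture=tex, **kwargs)


_FIXTURES = ("constant", "checkerboard", "gradient", "two_blob", "impulse")


def make_fixture(pattern: str, size: Tuple[int, int] = (4, 4), levels: int = 256) -> QuantizedROI:
    """Deterministic integer test image with a full mask.

    Patterns: ``constant`` (all mid-level), ``checkerboard`` (alternating
    0 / levels-1 with ``levels=2`` giving 0/1), ``gradient`` (levels increase
    along columns), ``two_blob`` (a dark square blob and a bright one twice
    its area on a mid background), ``impulse`` (single bright pixel on zeros).
    """
    rows, cols = size
    if rows < 2 or cols < 2:
        raise ValueError("fixture size must be at least 2x2")
    if pattern not in _FIXTURES:
        raise ValueError(f"unknown pattern {pattern!r}; choose from {_FIXTURES}")
    hi = levels - 1
    if pattern == "constant":
        grid = np.full(size, levels // 2, dtype=np.int32)
    elif pattern == "checkerboard":
        yy, xx = np.mgrid[0:rows, 0:cols]
        grid = ((yy + xx) % 2 * hi).astype(np.int32)
    elif pattern == "gradient":
        ramp = np.linspace(0, hi, cols).astype(np.int32)
        grid = np.tile(ramp, (rows, 1))
    elif pattern == "two_blob":
        grid = np.full(size, levels // 2, dtype=np.int32)
        a = max(rows // 8, 1)  # small blob side; big blob has twice the area
        r0, c0 = rows // 4, cols // 4
        grid[r0 : r0 + a, c0 : c0 + a] = 0
        r1, c1 = (2 * rows) // 3, (2 * cols) // 3
        grid[r1 : r1 + a, c1 : c1 + 2 * a] = hi
    else:  # impulse
        grid = np.zeros(size, dtype=np.int32)
        grid[rows // 2, cols // 2] = hi
    mask = np.ones(size, dtype=bool)
    params = NormalizationParams(mu=float(grid.mean()), sigma=float(grid.std()), n_bits=max(1, int(np.ceil(np.log2(levels)))))
    return QuantizedROI(grid=grid, mask=mask, n_levels=levels, params=params)
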