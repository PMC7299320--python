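"""The 488-feature texture inventory: histogram, GLCM, GRLM and DWT features.

All features are computed on a :class:`~texomri.preprocessing.QuantizedROI`
(masked, normalized, integer gray levels) and only pixel pairs / runs lying
entirely inside the lesion mask contribute.

Inventory under the default configuration:

===========  =====  ==========================================================
family       count  composition
===========  =====  ==========================================================
histogram        4  mean, variance, skewness, kurtosis of the masked levels
GLCM           380  19 statistics x 4 distances x (4 directions + their mean)
GRLM            44  11 run-length statistics x 4 directions
DWT             60  5 subband summaries x 4 decomposition levels x 3 wavelets
total          488
===========  =====  ==========================================================

GLCM feature names carry the raw pixel offset, e.g. ``S(0,1) CON`` is the
contrast at offset (drow=0, dcol=1); the per-distance directional mean is
named ``S(d,mean)``.  Offsets for distance d are (0,d), (-d,d), (-d,0),
(-d,-d), i.e. the four principal directions of the co-occurrence literature.

The co-occurrence matrices are held sparsely (only occupied cells), which
keeps 256-level matrices on small lesions cheap; every statistic below is a
sum over occupied cells or over the |i-j| / i+j marginals.  Logarithms are
natural; entropy terms treat 0 log 0 as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pywt
from scipy import stats

from .preprocessing import QuantizedROI

__all__ = [
    "GLCMConfig",
    "GRLMConfig",
    "DWTConfig",
    "GLCM_FEATURE_NAMES",
    "GRLM_FEATURE_NAMES",
    "histogram_features",
    "glcm",
    "glcm_features",
    "grlm_features",
    "dwt_features",
    "extract_all",
    "feature_names",
]

GLCM_FEATURE_NAMES = (
    "ACOR", "CON", "COR", "CP", "CS", "DIS", "ASM", "ENT", "IDM", "MP",
    "SOS", "SA", "SV", "SE", "DV", "DE", "IMC", "IDN", "IDMN",
)

GRLM_FEATURE_NAMES = (
    "RLN", "GLN", "LRE", "SRE", "FIR", "LGRE", "HGRE",
    "SRLGE", "SRHGE", "LRLGE", "LRHGE",
)

# Offset (drow, dcol) templates per distance d, in fixed report order.
_OFFSET_TEMPLATES = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

# GRLM directions: degrees -> unit offset along which runs are traced.
_GRLM_DIRECTIONS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

_DWT_SUBBANDS = ("HH", "DH", "HD", "LL", "LLM")  # horiz, vert, diag, approx energy, approx mean


@dataclass
class GLCMConfig:
    distances: Tuple[int, ...] = (1, 2, 3, 4)
    n_levels: int = 256
    symmetric: bool = True
    include_directional_mean: bool = True

    def offsets(self, d: int) -> List[Tuple[int, int]]:
        return [(dr * d, dc * d) for dr, dc in _OFFSET_TEMPLATES]


@dataclass
class GRLMConfig:
    directions: Tuple[int, ...] = (0, 45, 90, 135)
    n_levels: int = 256


@dataclass
class DWTConfig:
    wavelets: Tuple[str, ...] = ("haar", "db2", "sym4")
    n_levels: int = 4
    boundary_mode: str = "periodization"


class EmptyPairsError(ValueError):
    """No valid pixel pair exists for a requested GLCM offset."""


# --------------------------------------------------------------------------
# histogram


def histogram_features(q: QuantizedROI) -> Dict[str, float]:
    """First four moments of the masked gray-level distribution.

    Variance uses the n denominator; skewness and excess kurtosis are the
    Fisher moment coefficients and are defined as 0 for a constant ROI.
    """
    levels = q.levels.astype(float)
    if levels.size < 2:
        raise ValueError("need at least 2 masked pixels")
    var = float(levels.var(ddof=0))
    if var == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(levels, bias=True))
        kurt = float(stats.kurtosis(levels, fisher=True, bias=True))
    return {
        "Mean": float(levels.mean()),
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
    }


# --------------------------------------------------------------------------
# GLCM


@dataclass
class SparseGLCM:
    """Normalized co-occurrence matrix stored as occupied cells only."""

    i: np.ndarray  # row gray levels of occupied cells
    j: np.ndarray  # col gray levels
    p: np.ndarray  # probabilities, sum to 1
    n_levels: int

    def dense(self) -> np.ndarray:
        out = np.zeros((self.n_levels, self.n_levels))
        out[self.i, self.j] = self.p
        return out


def glcm(q: QuantizedROI, offset: Tuple[int, int], symmetric: bool = True) -> SparseGLCM:
    """Co-occurrence distribution of gray-level pairs at a pixel offset.

    Only pairs with both endpoints inside the mask count; with ``symmetric``
    the transpose is added before normalization.
    """
    dr, dc = offset
    if dr == 0 and dc == 0:
        raise ValueError("offset must be non-zero")
    rows, cols = q.grid.shape
    rr, cc = np.nonzero(q.mask)
    r2, c2 = rr + dr, cc + dc
    ok = (r2 >= 0) & (r2 < rows) & (c2 >= 0) & (c2 < cols)
    rr, cc, r2, c2 = rr[ok], cc[ok], r2[ok], c2[ok]
    ok = q.mask[r2, c2]
    if not ok.any():
        raise EmptyPairsError(f"no valid pixel pairs for offset {offset}")
    gi = q.grid[rr[ok], cc[ok]].astype(np.int64)
    gj = q.grid[r2[ok], c2[ok]].astype(np.int64)
    if symmetric:
        gi, gj = np.concatenate([gi, gj]), np.concatenate([gj, gi])
    keys = gi * q.n_levels + gj
    uniq, counts = np.unique(keys, return_counts=True)
    p = counts / counts.sum()
    return SparseGLCM(i=uniq // q.n_levels, j=uniq % q.n_levels, p=p, n_levels=q.n_levels)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def _glcm_statistics(m: SparseGLCM) -> Dict[str, float]:
    i = m.i.astype(float)
    j = m.j.astype(float)
    p = m.p
    L = m.n_levels

    px = np.bincount(m.i, weights=p, minlength=L)
    py = np.bincount(m.j, weights=p, minlength=L)
    mu_x = float(np.sum(i * p))
    mu_y = float(np.sum(j * p))
    sd_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * p)))
    sd_y = float(np.sqrt(np.sum((j - mu_y) ** 2 * p)))

    diff = i - j
    adiff = np.abs(diff).astype(np.int64)
    p_diff = np.bincount(adiff, weights=p, minlength=L)
    ksum = (m.i + m.j).astype(np.int64)
    p_sum = np.bincount(ksum, weights=p, minlength=2 * L - 1)

    acor = float(np.sum(i * j * p))
    con = float(np.sum(diff ** 2 * p))
    cor = 0.0 if sd_x == 0 or sd_y == 0 else (acor - mu_x * mu_y) / (sd_x * sd_y)
    dev = i + j - mu_x - mu_y
    cp = float(np.sum(dev ** 4 * p))
    cs = float(np.sum(dev ** 3 * p))
    dis = float(np.sum(np.abs(diff) * p))
    asm = float(np.sum(p ** 2))
    ent = _entropy(p)
    idm = float(np.sum(p / (1.0 + diff ** 2)))
    mp = float(p.max())
    sos = float(np.sum((i - mu_x) ** 2 * p))

    k_sum = np.arange(2 * L - 1, dtype=float)
    sa = float(np.sum(k_sum * p_sum))
    sv = float(np.sum((k_sum - sa) ** 2 * p_sum))
    se = _entropy(p_sum)

    k_diff = np.arange(L, dtype=float)
    mu_d = float(np.sum(k_diff * p_diff))
    dv = float(np.sum((k_diff - mu_d) ** 2 * p_diff))
    de = _entropy(p_diff)

    hx = _entropy(px)
    hy = _entropy(py)
    # HXY1 over occupied cells only (p log(px*py); zero-p terms vanish)
    pxy = px[m.i] * py[m.j]
    ok = pxy > 0
    hxy1 = float(-np.sum(p[ok] * np.log(pxy[ok])))
    denom = max(hx, hy)
    imc = 0.0 if denom == 0 else (ent - hxy1) / denom

    idn = float(np.sum(p / (1.0 + np.abs(diff) / L)))
    idmn = float(np.sum(p / (1.0 + diff ** 2 / L ** 2)))

    return {
        "ACOR": acor, "CON": con, "COR": cor, "CP": cp, "CS": cs,
        "DIS": dis, "ASM": asm, "ENT": ent, "IDM": idm, "MP": mp,
        "SOS": sos, "SA": sa, "SV": sv, "SE": se, "DV": dv, "DE": de,
        "IMC": imc, "IDN": idn, "IDMN": idmn,
    }


def glcm_features(q: QuantizedROI, cfg: GLCMConfig | None = None) -> Dict[str, float]:
    """380 co-occurrence features: 19 statistics per offset plus directional means."""
    cfg = cfg or GLCMConfig()
    out: Dict[str, float] = {}
    for d in cfg.distances:
        per_offset: List[Dict[str, float]] = []
        for dr, dc in cfg.offsets(d):
            m = glcm(q, (dr, dc), symmetric=cfg.symmetric)
            statsd = _glcm_statistics(m)
            per_offset.append(statsd)
            for name in GLCM_FEATURE_NAMES:
                out[f"S({dr},{dc}) {name}"] = statsd[name]
        if cfg.include_directional_mean:
            for name in GLCM_FEATURE_NAMES:
                out[f"S({d},mean) {name}"] = float(
                    np.mean([s[name] for s in per_offset])
                )
    return out


# --------------------------------------------------------------------------
# GRLM


def _mask_lines(mask: np.ndarray, grid: np.ndarray, direction: int):
    """Yield (values, inside) 1D line profiles along a run direction."""
    rows, cols = mask.shape
    if direction == 0:
        for r in range(rows):
            yield grid[r], mask[r]
    elif direction == 90:
        for c in range(cols):
            yield grid[:, c], mask[:, c]
    elif direction == 135:  # main diagonals (dr=1, dc=1)
        for off in range(-(rows - 1), cols):
            yield grid.diagonal(off), mask.diagonal(off)
    elif direction == 45:  # anti-diagonals (dr=-1, dc=1)
        fg, fm = grid[::-1], mask[::-1]
        for off in range(-(rows - 1), cols):
            yield fg.diagonal(off), fm.diagonal(off)
    else:
        raise ValueError(f"unsupported GRLM direction {direction}")


def _run_length_matrix(q: QuantizedROI, direction: int) -> np.ndarray:
    """Run-length counts R[level, run_length-1]; runs truncate at mask edges."""
    max_len = int(np.ceil(np.hypot(*q.grid.shape)))
    R = np.zeros((q.n_levels, max_len), dtype=np.int64)
    for vals, inside in _mask_lines(q.mask, q.grid, direction):
        vals = np.asarray(vals)
        inside = np.asarray(inside)
        if not inside.any():
            continue
        # break points where the mask ends or the level changes
        n = len(vals)
        idx = 0
        while idx < n:
            if not inside[idx]:
                idx += 1
                continue
            j = idx + 1
            while j < n and inside[j] and vals[j] == vals[idx]:
                j += 1
            R[vals[idx], j - idx - 1] += 1
            idx = j
    return R


def grlm_features(q: QuantizedROI, cfg: GRLMConfig | None = None) -> Dict[str, float]:
    """44 run-length features: 11 statistics in each of 4 directions.

    Gray levels enter the low/high emphasis weights as ``level + 1`` so the
    zero level carries a finite weight.
    """
    cfg = cfg or GRLMConfig()
    n_pixels = int(q.mask.sum())
    out: Dict[str, float] = {}
    for direction in cfg.directions:
        R = _run_length_matrix(q, direction)
        levels, lengths = np.nonzero(R)
        counts = R[levels, lengths].astype(float)
        nr = counts.sum()
        g = (levels + 1).astype(float)
        rl = (lengths + 1).astype(float)
        gl_marg = np.bincount(levels, weights=counts)
        rl_marg = np.bincount(lengths, weights=counts)
        vals = {
            "RLN": float(np.sum(rl_marg ** 2) / nr),
            "GLN": float(np.sum(gl_marg ** 2) / nr),
            "LRE": float(np.sum(counts * rl ** 2) / nr),
            "SRE": float(np.sum(counts / rl ** 2) / nr),
            "FIR": float(nr / n_pixels),
            "LGRE": float(np.sum(counts / g ** 2) / nr),
            "HGRE": float(np.sum(counts * g ** 2) / nr),
            "SRLGE": float(np.sum(counts / (g ** 2 * rl ** 2)) / nr),
            "SRHGE": float(np.sum(counts * g ** 2 / rl ** 2) / nr),
            "LRLGE": float(np.sum(counts * rl ** 2 / g ** 2) / nr),
            "LRHGE": float(np.sum(counts * (g * rl) ** 2) / nr),
        }
        for name in GRLM_FEATURE_NAMES:
            out[f"{name}_{direction}"] = vals[name]
    return out


# --------------------------------------------------------------------------
# DWT


def _padded_bbox_image(q: QuantizedROI, multiple: int) -> np.ndarray:
    """Mask bounding box with outside-mask pixels mean-filled, padded to a
    size multiple so every decomposition level is well defined."""
    rr, cc = np.nonzero(q.mask)
    r0, r1 = rr.min(), rr.max() + 1
    c0, c1 = cc.min(), cc.max() + 1
    sub = q.grid[r0:r1, c0:c1].astype(float)
    submask = q.mask[r0:r1, c0:c1]
    fill = float(q.grid[q.mask].mean())
    img = np.where(submask, sub, fill)
    tr = int(np.ceil(img.shape[0] / multiple)) * multiple
    tc = int(np.ceil(img.shape[1] / multiple)) * multiple
    if (tr, tc) != img.shape:
        out = np.full((tr, tc), fill)
        out[: img.shape[0], : img.shape[1]] = img
        img = out
    return img


def dwt_features(q: QuantizedROI, cfg: DWTConfig | None = None) -> Dict[str, float]:
    """Multiresolution subband summaries: 5 values per level per wavelet.

    Per level the features are the horizontal- (HH), vertical- (DH) and
    diagonal-detail (HD) subband energies and the approximation energy (LL),
    each normalized by the total energy of the analyzed image, plus the mean
    of the approximation coefficients (LLM).  With the default periodization
    boundary and orthogonal wavelets the subband energies at a full
    decomposition sum to the total image energy (Parseval).
    """
    cfg = cfg or DWTConfig()
    img = _padded_bbox_image(q, multiple=2 ** cfg.n_levels)
    total_energy = float(np.sum(img ** 2))
    if total_energy == 0.0:
        total_energy = 1.0  # all-zero ROI: every normalized energy is 0
    out: Dict[str, float] = {}
    for wavelet in cfg.wavelets:
        current = img
        for level in range(1, cfg.n_levels + 1):
            if min(current.shape) < 2:
                warnings.warn(
                    f"image too small for DWT level {level}; emitting NaN sentinels"
                )
                for sub in _DWT_SUBBANDS:
                    out[f"{wavelet} {sub}_{level}"] = float("nan")
                continue
            cA, (cH, cV, cD) = pywt.dwt2(current, wavelet, mode=cfg.boundary_mode)
            out[f"{wavelet} HH_{level}"] = float(np.sum(cH ** 2)) / total_energy
            out[f"{wavelet} DH_{level}"] = float(np.sum(cV ** 2)) / total_energy
            out[f"{wavelet} HD_{level}"] = float(np.sum(cD ** 2)) / total_energy
            out[f"{wavelet} LL_{level}"] = float(np.sum(cA ** 2)) / total_energy
            out[f"{wavelet} LLM_{level}"] = float(np.mean(cA))
            current = cA
    return out


# --------------------------------------------------------------------------
# assembly


def feature_names(
    glcm_cfg: GLCMConfig | None = None,
    grlm_cfg: GRLMConfig | None = None,
    dwt_cfg: DWTConfig | None = None,
) -> List[str]:
    """The canonical ordered feature-name list (488 under defaults)."""
    glcm_cfg = glcm_cfg or GLCMConfig()
    grlm_cfg = grlm_cfg or GRLMConfig()
    dwt_cfg = dwt_cfg or DWTConfig()
    names = ["Mean", "Variance", "Skewness", "Kurtosis"]
    for d in glcm_cfg.distances:
        for dr, dc in glcm_cfg.offsets(d):
            names += [f"S({dr},{dc}) {n}" for n in GLCM_FEATURE_NAMES]
        if glcm_cfg.include_directional_mean:
            names += [f"S({d},mean) {n}" for n in GLCM_FEATURE_NAMES]
    for direction in grlm_cfg.directions:
        names += [f"{n}_{direction}" for n in GRLM_FEATURE_NAMES]
    for wavelet in dwt_cfg.wavelets:
        for level in range(1, dwt_cfg.n_levels + 1):
            names += [f"{wavelet} {sub}_{level}" for sub in _DWT_SUBBANDS]
    return names


def extract_features(
    q: QuantizedROI,
    glcm_cfg: GLCMConfig | None = None,
    grlm_cfg: GRLMConfig | None = None,
    dwt_cfg: DWTConfig | None = None,
) -> Dict[str, float]:
    """All features of one quantized lesion, in canonical order."""
    out: Dict[str, float] = {}
    out.update(histogram_features(q))
    out.update(glcm_features(q, glcm_cfg))
    out.update(grlm_features(q, grlm_cfg))
    out.update(dwt_features(q, dwt_cfg))
    return out


def extract_all(
    pre_q: QuantizedROI,
    post_q: QuantizedROI,
    sub_q: QuantizedROI,
    glcm_cfg: GLCMConfig | None = None,
    grlm_cfg: GRLMConfig | None = None,
    dwt_cfg: DWTConfig | None = None,
) -> Dict[str, Dict[str, float]]:
    """Feature vector per phase for one patient's three co-registered ROIs."""
    out = {}
    for phase, q in (("pre", pre_q), ("post", post_q), ("subtraction", sub_q)):
        try:
            out[phase] = extract_features(q, glcm_cfg, grlm_cfg, dwt_cfg)
        except Exception as exc:  # tag the offending phase
            raise type(exc)(f"[phase={phase}] {exc}") from exc
    return out
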