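"""Color, texture and shape descriptors of an ROI triplet.

Three external-property descriptors are computed per fruit, each the
concatenation over the stalk/middle/tip ROIs:

* **color** (18-dim): per-ROI means of H, S (HSV), a*, b* (CIE L*a*b*)
  and c, h (CIE L*ch) — brightness-free color attributes.
* **texture** (177-dim): per-ROI 59-bin uniform-pattern LBP histogram,
  L1-normalized.
* **shape** (972-dim): per-ROI 324-dim HOG descriptor (4 x 4 cells of
  12 x 12 px, 2 x 2-cell blocks on a 3 x 3 grid with one-cell stride,
  Prewitt gradients, 9 unsigned-orientation bins over [0, pi), per-block
  L1 normalization).

Conventions the encodings depend on (fixed here because no standard
pins them down): grayscale is ITU-R BT.601 luma rounded to the nearest
integer; LBP neighbors are ordered clockwise from the top-left with ties
(neighbor == center) counting as 1; LBP skips the 1-px patch border;
hue means are plain arithmetic means (banana hues sit far from the
0/360 wrap); HOG votes are hard-assigned to the single bin containing
the pixel's orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color as skcolor

from .roi import ROI_SIZE, ROITriplet

COLOR_DIM_PER_ROI = 6
TEXTURE_DIM_PER_ROI = 59
HOG_CELL = 12
HOG_CELLS = 4  # 4 x 4 cells per ROI
HOG_BINS = 9
HOG_BLOCK_GRID = 3  # 3 x 3 blocks of 2 x 2 cells, one-cell stride
SHAPE_DIM_PER_ROI = HOG_BINS * 4 * HOG_BLOCK_GRID * HOG_BLOCK_GRID  # 324

_EPS = 1e-12


@dataclass(frozen=True)
class FeatureVector:
    """A descriptor with provenance metadata."""

    values: np.ndarray
    kind: str  # "color" | "texture" | "shape"
    source_label: str | None = None


# ---------------------------------------------------------------------------
# color spaces
# ---------------------------------------------------------------------------

def rgb_to_hsv(patch: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hexcone RGB -> HSV; H in degrees [0, 360), S and V in [0, 1].

    Achromatic pixels get H = 0 by convention.
    """
    hsv = skcolor.rgb2hsv(np.asarray(patch, dtype=np.uint8))
    return hsv[..., 0] * 360.0, hsv[..., 1], hsv[..., 2]


def rgb_to_lab(patch: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """sRGB (D65) -> CIE L*a*b* via linearized RGB and XYZ."""
    lab = skcolor.rgb2lab(np.asarray(patch, dtype=np.uint8))
    return lab[..., 0], lab[..., 1], lab[..., 2]


def lab_to_lch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Chroma c = sqrt(a*^2 + b*^2); hue h = atan2(b*, a*) in degrees [0, 360)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.hypot(a, b)
    h = np.degrees(np.arctan2(b, a)) % 360.0
    return c, h


def color_feature(triplet: ROITriplet) -> FeatureVector:
    """18-dim color descriptor: per-ROI means of (H, S, a*, b*, c, h)."""
    parts = []
    for patch in triplet.patches:
        h_deg, s, _v = rgb_to_hsv(patch)
        _l, a, b = rgb_to_lab(patch)
        c, h_lch = lab_to_lch(a, b)
        parts.append(
            [plane.mean() for plane in (h_deg, s, a, b, c, h_lch)]
        )
    values = np.asarray(parts, dtype=float).ravel()
    return FeatureVector(values=values, kind="color", source_label=triplet.source_label)


# ---------------------------------------------------------------------------
# grayscale + LBP texture
# ---------------------------------------------------------------------------

def to_gray(patch: np.ndarray) -> np.ndarray:
    """ITU-R BT.601 luma, rounded to the nearest integer (uint8-range ints)."""
    patch = np.asarray(patch, dtype=float)
    y = 0.299 * patch[..., 0] + 0.587 * patch[..., 1] + 0.114 * patch[..., 2]
    return np.rint(y).astype(np.int32)


#: Neighbor offsets, clockwise from the top-left; bit k-1 has weight 2^(k-1).
_LBP_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)


def lbp_code(patch3x3: np.ndarray) -> int:
    """8-bit LBP code of a 3 x 3 gray patch (neighbor >= center -> bit set)."""
    p = np.asarray(patch3x3)
    if p.shape != (3, 3):
        raise ValueError("lbp_code expects a 3 x 3 patch")
    center = p[1, 1]
    code = 0
    for k, (dr, dc) in enumerate(_LBP_OFFSETS):
        if p[1 + dr, 1 + dc] >= center:
            code |= 1 << k
    return code


def lbp_codes(gray: np.ndarray) -> np.ndarray:
    """LBP codes of every interior pixel (the 1-px border is skipped)."""
    g = np.asarray(gray)
    center = g[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.int32)
    for k, (dr, dc) in enumerate(_LBP_OFFSETS):
        nb = g[1 + dr : g.shape[0] - 1 + dr, 1 + dc : g.shape[1] - 1 + dc]
        codes |= (nb >= center).astype(np.int32) << k
    return codes


def _circular_transitions(code: int) -> int:
    bits = [(code >> k) & 1 for k in range(8)]
    return sum(bits[k] != bits[(k + 1) % 8] for k in range(8))


def uniform_lookup() -> np.ndarray:
    """Map each of the 256 LBP codes to one of 59 histogram bins.

    Codes with at most two circular 0<->1 transitions are "uniform"; the
    58 uniform codes get dedicated bins 0..57 in ascending code order,
    and the remaining 198 codes share bin 58.
    """
    table = np.full(256, 58, dtype=np.int32)
    uniform = [c for c in range(256) if _circular_transitions(c) <= 2]
    for bin_idx, code in enumerate(uniform):
        table[code] = bin_idx
    return table


_UNIFORM_TABLE = uniform_lookup()


def uplbp_histogram(gray: np.ndarray, normalize: bool = True) -> np.ndarray:
    """59-bin uniform-pattern histogram of one gray ROI."""
    codes = lbp_codes(gray)
    hist = np.bincount(_UNIFORM_TABLE[codes].ravel(), minlength=59).astype(float)
    if normalize:
        total = hist.sum()
        if total > 0:
            hist /= total
    return hist


def texture_feature(triplet: ROITriplet, normalize: bool = True) -> FeatureVector:
    """177-dim UP-LBP descriptor: three concatenated 59-bin histograms."""
    values = np.concatenate(
        [uplbp_histogram(to_gray(p), normalize=normalize) for p in triplet.patches]
    )
    return FeatureVector(values=values, kind="texture", source_label=triplet.source_label)


# ---------------------------------------------------------------------------
# HOG shape
# ---------------------------------------------------------------------------

_PREWITT_X = np.array([[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]], dtype=float)
_PREWITT_Y = _PREWITT_X.T


def hog_descriptor(roi_gray: np.ndarray) -> np.ndarray:
    """324-dim HOG of a 48 x 48 gray patch.

    Prewitt gradients with replicate-padded borders; unsigned orientation
    atan2(Gy, Gx) folded into [0, pi); per-cell 9-bin magnitude-weighted
    histograms with hard bin assignment; 2 x 2-cell blocks on a 3 x 3
    grid (one-cell stride), each 36-vector L1-normalized with an epsilon
    guard (an all-zero-gradient block stays all-zero).
    """
    g = np.asarray(roi_gray, dtype=float)
    if g.shape != (ROI_SIZE, ROI_SIZE):
        raise ValueError(f"hog_descriptor expects a {ROI_SIZE} x {ROI_SIZE} patch")
    gx = ndimage.convolve(g, _PREWITT_X, mode="nearest")
    gy = ndimage.convolve(g, _PREWITT_Y, mode="nearest")
    mag = np.hypot(gx, gy)
    theta = np.arctan2(gy, gx) % np.pi  # unsigned orientation in [0, pi)
    bins = np.minimum((theta / (np.pi / HOG_BINS)).astype(int), HOG_BINS - 1)

    cell_hist = np.zeros((HOG_CELLS, HOG_CELLS, HOG_BINS))
    for ci in range(HOG_CELLS):
        for cj in range(HOG_CELLS):
            sl = (
                slice(ci * HOG_CELL, (ci + 1) * HOG_CELL),
                slice(cj * HOG_CELL, (cj + 1) * HOG_CELL),
            )
            cell_hist[ci, cj] = np.bincount(
                bins[sl].ravel(), weights=mag[sl].ravel(), minlength=HOG_BINS
            )

    blocks = []
    for bi in range(HOG_BLOCK_GRID):
        for bj in range(HOG_BLOCK_GRID):
            v = cell_hist[bi : bi + 2, bj : bj + 2].ravel()
            blocks.append(v / (np.abs(v).sum() + _EPS))
    return np.concatenate(blocks)


def shape_feature(triplet: ROITriplet) -> FeatureVector:
    """972-dim shape descriptor: three concatenated 324-dim HOGs."""
    values = np.concatenate(
        [hog_descriptor(to_gray(p)) for p in triplet.patches]
    )
    return FeatureVector(values=values, kind="shape", source_label=triplet.source_label)


FEATURE_EXTRACTORS = {
    "color": color_feature,
    "texture": texture_feature,
    "shape": shape_feature,
}

FEATURE_DIMS = {"color": 18, "texture": 177, "shape": 972}
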