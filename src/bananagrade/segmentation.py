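"""Fruit/background segmentation via the red-blue chromatic map.

Fruit peel (green through yellow) always has R > B, while a pale cloth
background has R <= B, so the per-pixel difference I_RB = R - B is close
to bimodal: background collapses to ~0 and fruit sits well above it.
Otsu's criterion picks the split, and a morphological open (disk radius
10 px) followed by hole filling and a largest-component rule removes
speckle and the holes punched by brown spots (whose R ~ B makes them
vanish from the chromatic map).

Coordinate convention: x indexes rows (vertical, 0 at the top), y
indexes columns (horizontal, 0 at the left).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.morphology import disk


class FormatError(ValueError):
    """Input image does not have the expected layout."""


class NoForegroundError(ValueError):
    """Segmentation found no usable foreground region."""


@dataclass(frozen=True)
class RegionBounds:
    """Reference coordinates of the segmented fruit driving ROI placement.

    ``x_ref`` is the top row touched by the fruit; ``y_ref`` and
    ``y_ref_prime`` are its leftmost and rightmost columns.
    """

    x_ref: int
    y_ref: int
    y_ref_prime: int

    def __post_init__(self) -> None:
        if not (0 <= self.y_ref < self.y_ref_prime):
            raise NoForegroundError("region too small: y_ref must be < y_ref_prime")
        if self.x_ref < 0:
            raise NoForegroundError("x_ref must be >= 0")

    @property
    def span(self) -> int:
        return self.y_ref_prime - self.y_ref


def rb_chromatic_map(image: np.ndarray) -> np.ndarray:
    """Per-pixel R - B, clipped to [0, 255].

    Clipping (rather than shifting) maps the whole R <= B background to
    zero, sharpening the bimodality Otsu relies on.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise FormatError("expected an H x W x 3 RGB image")
    diff = image[..., 0].astype(np.int16) - image[..., 2].astype(np.int16)
    return np.clip(diff, 0, 255).astype(np.uint8)


def otsu_threshold(chromatic_map: np.ndarray) -> int:
    """8-bit Otsu threshold maximizing between-class variance.

    The split at threshold ``t`` places levels <= t in the background
    class; foreground is ``map > t``.  Ties in the criterion are broken
    by the lowest threshold.
    """
    values = np.asarray(chromatic_map, dtype=np.uint8)
    hist = np.bincount(values.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise NoForegroundError("constant map: no foreground/background split")
    total = hist.sum()
    p = hist / total
    omega = np.cumsum(p)  # class-0 weight for t = 0..255
    mu = np.cumsum(p * np.arange(256))
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    return int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer


def binarize(chromatic_map: np.ndarray, threshold: int) -> np.ndarray:
    """Foreground mask: map > threshold."""
    return np.asarray(chromatic_map) > threshold


def refine_mask(binary: np.ndarray, opening_radius: int = 10) -> np.ndarray:
    """Morphological cleanup of a raw Otsu mask.

    Opening with a disk (default radius 10 px) removes speckle, border-
    flood hole filling closes the gaps left by brown spots, and only the
    largest 8-connected component is kept (scenes contain one fruit).
    """
    binary = np.asarray(binary, dtype=bool)
    opened = ndimage.binary_opening(binary, structure=disk(opening_radius))
    if not opened.any():
        raise NoForegroundError("mask empty after opening")
    # hole filling = complement flood fill from the border, 4-connected bg
    filled = ndimage.binary_fill_holes(opened)
    labels = cc_label(filled, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def region_bounds(mask: np.ndarray) -> RegionBounds:
    """Top row and left/right columns of the foreground region."""
    mask = np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise NoForegroundError("empty mask")
    return RegionBounds(
        x_ref=int(rows[0]), y_ref=int(cols[0]), y_ref_prime=int(cols[-1])
    )


def segment(image: np.ndarray, opening_radius: int = 10) -> tuple[np.ndarray, RegionBounds]:
    """Full segmentation: chromatic map -> Otsu -> morphology -> bounds."""
    cmap = rb_chromatic_map(image)
    t = otsu_threshold(cmap)
    mask = refine_mask(binarize(cmap, t), opening_radius=opening_radius)
    return mask, region_bounds(mask)


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
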