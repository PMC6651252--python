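"""Three-ROI sampling from a segmented fruit.

One 48 x 48 patch is cut from each of three non-intersecting parts of
the fruit — stalk (ROI1), middle (ROI2) and tip (ROI3) — mirroring the
three sampling positions of destructive ripeness assays.  Placement is
driven by the segmented region's reference coordinates plus randomized
offsets:

    x_roi  = x_ref + a,                a ~ uniform integer [15, 35]
    y_roi  = y_ref + span * alpha,     alpha ~ U(0.1, 0.2)
    y_roi' = y_ref' - span * beta,     beta  ~ U(0.15, 0.25)

ROI1 originates at (x_roi, y_roi); ROI2 at (x_roi, floor((y_roi +
y_roi') / 2)); ROI3 at (x_roi - 48 clamped to >= 0, y_roi').  ``span``
is the fruit's horizontal extent y_ref' - y_ref; a "literal" variant
multiplying alpha/beta by (y_ref' + y_ref) instead is available for
comparison but exceeds the frame on right-shifted fruit.

The tip ROI's row origin sits partly above the fruit's top row by
construction (48 - a rows), so its mask coverage is bounded by a/48;
callers can treat low coverage as a warning or an error via
``min_coverage`` / ``strict``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .segmentation import RegionBounds

logger = logging.getLogger(__name__)

ROI_SIZE = 48

A_RANGE = (15, 35)  # integer, inclusive
ALPHA_RANGE = (0.1, 0.2)
BETA_RANGE = (0.15, 0.25)


class FruitTooSmallError(ValueError):
    """The segmented fruit cannot host the three 48 x 48 ROIs."""


@dataclass(frozen=True)
class ROITriplet:
    """Three 48 x 48 RGB patches (stalk, middle, tip) and their origins."""

    patches: tuple[np.ndarray, np.ndarray, np.ndarray]
    origins: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    source_label: str | None = None

    def __post_init__(self) -> None:
        for p in self.patches:
            if p.shape != (ROI_SIZE, ROI_SIZE, 3):
                raise ValueError("each ROI patch must be 48 x 48 x 3")


def roi_origins(
    bounds: RegionBounds,
    a: int,
    alpha: float,
    beta: float,
    variant: str = "span",
) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
    """Deterministic ROI origin arithmetic given the random offsets.

    ``variant='span'`` multiplies alpha/beta by the fruit's horizontal
    span (y_ref' - y_ref); ``variant='literal'`` uses the printed sum
    form (y_ref' + y_ref).
    """
    if variant == "span":
        mult = bounds.y_ref_prime - bounds.y_ref
    elif variant == "literal":
        mult = bounds.y_ref_prime + bounds.y_ref
    else:
        raise ValueError(f"unknown formula variant {variant!r}")
    x_roi = bounds.x_ref + int(a)
    y_roi = int(np.floor(bounds.y_ref + mult * alpha))
    y_roi_prime = int(np.floor(bounds.y_ref_prime - mult * beta))
    y_mid = (y_roi + y_roi_prime) // 2  # fractional ordinate floors
    x_tip = max(x_roi - ROI_SIZE, 0)  # verbatim x_roi - 48, clamped to frame
    return ((x_roi, y_roi), (x_roi, y_mid), (x_tip, y_roi_prime))


def _extract(image: np.ndarray, origin: tuple[int, int]) -> np.ndarray:
    r, c = origin
    H, W = image.shape[:2]
    if r < 0 or c < 0 or r + ROI_SIZE > H or c + ROI_SIZE > W:
        raise FruitTooSmallError(
            f"ROI at {origin} exceeds the {H} x {W} image bounds"
        )
    return image[r : r + ROI_SIZE, c : c + ROI_SIZE]


def mask_coverage(mask: np.ndarray, origin: tuple[int, int]) -> float:
    """Fraction of a 48 x 48 patch lying on the fruit mask."""
    r, c = origin
    H, W = mask.shape
    r1, c1 = min(r + ROI_SIZE, H), min(c + ROI_SIZE, W)
    if r >= H or c >= W:
        return 0.0
    inside = np.count_nonzero(mask[max(r, 0) : r1, max(c, 0) : c1])
    return inside / float(ROI_SIZE * ROI_SIZE)


def sample_rois(
    image: np.ndarray,
    bounds: RegionBounds,
    mask: np.ndarray | None = None,
    seed: int = 0,
    *,
    variant: str = "span",
    strict: bool = False,
    min_coverage: float = 0.0,
    source_label: str | None = None,
) -> ROITriplet:
    """Draw the random offsets and extract one stalk/middle/tip triplet.

    Raises
    ------
    FruitTooSmallError
        If any patch would exceed the image after clamping, if the fruit
        is narrower than three ROI widths, or (in ``strict`` mode) if
        the stalk and tip ordinates leave less than one ROI width
        between them or a patch falls below ``min_coverage`` on the mask.
    """
    image = np.asarray(image)
    if bounds.span < 3 * ROI_SIZE:
        raise FruitTooSmallError(
            f"fruit span {bounds.span} px cannot host three {ROI_SIZE} px ROIs"
        )
    rng = np.random.default_rng(seed)
    a = int(rng.integers(A_RANGE[0], A_RANGE[1] + 1))
    alpha = float(rng.uniform(*ALPHA_RANGE))
    beta = float(rng.uniform(*BETA_RANGE))
    origins = roi_origins(bounds, a, alpha, beta, variant=variant)
    if origins[2][1] - origins[0][1] < ROI_SIZE:
        msg = "stalk and tip ROIs overlap horizontally"
        if strict:
            raise FruitTooSmallError(msg)
        logger.warning(msg)
    patches = tuple(_extract(image, o) for o in origins)
    if mask is not None:
        for name, origin in zip(("stalk", "middle", "tip"), origins):
            cov = mask_coverage(mask, origin)
            if cov < min_coverage:
                msg = (
                    f"{name} ROI at {origin} covers only {cov:.0%} of the "
                    f"fruit mask (< {min_coverage:.0%})"
                )
                if strict:
                    raise FruitTooSmallError(msg)
                logger.warning(msg)
    return ROITriplet(patches=patches, origins=origins, source_label=source_label)
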