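"""Synthetic banana-scene generator.

Produces labeled single-fruit scenes with the statistical structure the
grading pipeline assumes: a curved elongated fruit whose pixels satisfy
R > B, on a pale cloth-like background satisfying R <= B, with
stage-dependent peel appearance (green, yellow-with-green, yellow,
yellow-with-brown-spots), additive Gaussian noise and a linear
illumination ramp.  Every scene carries a ground-truth mask so the
segmentation, ROI and feature stages are testable without real
photographs.

Four maturity stages are modeled:

MS1  all-green peel
MS2  mostly yellow peel with green patches
MS3  all-yellow peel
MS4  yellow peel with brown spots (spots have R ~ B, so they vanish
     from the red-blue chromatic map exactly like real brown spots)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

STAGES = ("MS1", "MS2", "MS3", "MS4")


class ConfigurationError(ValueError):
    """Raised when a scene configuration cannot host a valid fruit."""


@dataclass(frozen=True)
class StageAppearanceSpec:
    """Peel appearance parameters for one maturity stage.

    Parameters
    ----------
    stage:
        Maturity label, one of ``MS1``..``MS4``.
    hue_range:
        HSV hue interval in degrees for the peel base color.  Green
        stages use hues in [70, 140], yellow stages in [40, 65]; these
        are tunable implementation defaults, not measured values.
    green_patch_fraction:
        Fraction of peel area tinted green (used by MS2).
    spot_rate:
        Expected number of brown spots per scene (Poisson mean).
    spot_radius_range:
        (min, max) spot radius in pixels.
    defect_rate:
        Expected number of small dark defects per scene (any stage).
    """

    stage: str
    hue_range: tuple[float, float]
    green_patch_fraction: float = 0.0
    spot_rate: float = 0.0
    spot_radius_range: tuple[float, float] = (3.0, 7.0)
    defect_rate: float = 0.5
    saturation_range: tuple[float, float] = (0.6, 0.8)
    value_range: tuple[float, float] = (0.6, 0.8)
    #: peel micro-texture: longitudinal ridge striations (luminance
    #: sinusoid across the fruit's short axis, following the curved
    #: centerline) whose amplitude (gray levels) and wavelength (px) grow
    #: as the peel ripens, plus an isotropic low-amplitude mottle
    stripe_amplitude: float = 0.0
    stripe_wavelength: float = 6.0
    mottle_amplitude: float = 4.0
    mottle_scale: float = 3.0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.spot_rate < 0:
            raise ValueError("spot_rate must be >= 0")
        if not 0.0 <= self.green_patch_fraction <= 1.0:
            raise ValueError("green_patch_fraction must be in [0, 1]")


#: Default per-stage appearance.  Base hue descends monotonically with
#: ripeness (green -> yellow-green -> yellow -> deep yellow), giving the
#: stage-separated hue ranges the color pipeline assumes.  Green peels stay
#: below 105 deg so R - B is safely positive (at hue 120 R equals B and the
#: chromatic segmentation premise would break); MS4 spots are frequent
#: (Poisson mean 25) and carry R ~ B so they punch holes in the raw
#: chromatic mask.
DEFAULT_APPEARANCE: dict[str, StageAppearanceSpec] = {
    "MS1": StageAppearanceSpec(
        stage="MS1", hue_range=(75.0, 100.0),
        saturation_range=(0.6, 0.8), value_range=(0.5, 0.68),
        stripe_amplitude=2.5, stripe_wavelength=4.0,
    ),
    "MS2": StageAppearanceSpec(
        stage="MS2", hue_range=(56.0, 64.0), green_patch_fraction=0.28,
        saturation_range=(0.62, 0.82), value_range=(0.68, 0.82),
        stripe_amplitude=7.5, stripe_wavelength=6.0,
    ),
    "MS3": StageAppearanceSpec(
        stage="MS3", hue_range=(48.0, 55.0),
        saturation_range=(0.62, 0.82), value_range=(0.7, 0.84),
        stripe_amplitude=15.0, stripe_wavelength=8.0,
    ),
    "MS4": StageAppearanceSpec(
        stage="MS4", hue_range=(42.0, 47.0), spot_rate=25.0,
        saturation_range=(0.6, 0.8), value_range=(0.66, 0.8),
        stripe_amplitude=25.0, stripe_wavelength=10.0,
    ),
}

#: Hue used for the green tint of MS2 patches (degrees).  A yellow-green
#: (not deep green) keeps the patch's R - B contrast well inside the fruit
#: mode of the chromatic map, as on real part-green peels.
GREEN_PATCH_HUE = 80.0
#: Dark desaturated spot/defect color (R ~ B by construction).
SPOT_RGB = (78.0, 62.0, 76.0)
DEFECT_RGB = (70.0, 58.0, 68.0)


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, background and noise settings for scene synthesis."""

    image_height: int = 240
    image_width: int = 320
    background_level: float = 200.0
    background_blue_bias: float = 12.0
    noise_sigma: float = 3.0
    illumination_gradient: float = 0.08
    # fruit geometry: crescent = centerline arc +- half thickness
    fruit_half_thickness: int = 55
    fruit_margin: int = 30
    fruit_arc_amplitude: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 200 or self.image_width < 300:
            raise ConfigurationError(
                "image must be at least 200 x 300 to host three 48 x 48 ROIs"
            )
        if self.background_blue_bias < 0:
            raise ConfigurationError("background_blue_bias must be >= 0")


@dataclass(frozen=True)
class LabeledScene:
    """An 8-bit RGB image with its ground-truth fruit mask and stage label."""

    image: np.ndarray  # H x W x 3 uint8
    mask: np.ndarray  # H x W bool
    label: str


def _hsv_to_rgb(h_deg: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Vectorized hexcone HSV -> RGB, output in [0, 1]."""
    h = (np.asarray(h_deg, dtype=float) % 360.0) / 60.0
    s = np.asarray(s, dtype=float)
    v = np.asarray(v, dtype=float)
    i = np.floor(h).astype(int) % 6
    f = h - np.floor(h)
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))
    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    return np.stack([r, g, b], axis=-1)


def _fruit_mask_and_centerline(
    config: SceneConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Crescent fruit mask: a thick band around a parabolic centerline.

    The arc opens downward (both tips raised), mimicking a banana lying
    on its back; this is the layout the tip-ROI row offset assumes.
    Returns (mask, column indices of the fruit, centerline rows).
    """
    H, W = config.image_height, config.image_width
    y0, y1 = config.fruit_margin, W - config.fruit_margin - 1
    half = config.fruit_half_thickness
    amp = config.fruit_arc_amplitude
    base_row = H // 2 + int(amp) // 2
    if y1 - y0 < 3 * 48:
        raise ConfigurationError("fruit too narrow for three ROIs")
    cols = np.arange(y0, y1 + 1)
    u = (cols - (y0 + y1) / 2.0) / ((y1 - y0) / 2.0)
    center = base_row - amp * u * u  # tips (|u|=1) are highest
    if np.any(center - half < 1) or np.any(center + half > H - 2):
        raise ConfigurationError("fruit does not fit vertically in the frame")
    rows = np.arange(H)[:, None]
    band = np.zeros((H, W), dtype=bool)
    band[:, y0 : y1 + 1] = np.abs(rows - center[None, :]) <= half
    return band, cols, center


def _blend_disks(
    img: np.ndarray,
    mask: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
    color: tuple[float, float, float],
) -> None:
    """Paint soft-core disks onto ``img`` in place, restricted to ``mask``.

    Each disk has a flat core (half the radius) of the given color and a
    linear radial falloff to the underlying peel over the outer half, so
    spots carry strong deterministic gradients across most of their area
    (the texture signature of brown senescence spots) while the core keeps
    the color's chromatic properties exactly.
    """
    rr = np.arange(img.shape[0])[:, None]
    cc = np.arange(img.shape[1])[None, :]
    color_arr = np.asarray(color, dtype=float)
    for (r0, c0), rad in zip(centers, radii):
        d = np.hypot(rr - r0, cc - c0)
        w = np.clip(2.0 * (1.0 - d / rad), 0.0, 1.0)  # 1 inside r/2, 0 at r
        w = np.where(mask, w, 0.0)
        img[...] = w[..., None] * color_arr + (1.0 - w[..., None]) * img


def _interior_disks(
    rng: np.random.Generator,
    n: int,
    cols: np.ndarray,
    center: np.ndarray,
    half_thickness: int,
    radius_range: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Disk centers/radii placed on the central band of the peel face.

    Disks stay inside the fruit silhouette with a clear margin: on a real
    curved fruit, spots near the silhouette edge are foreshortened to
    near-invisibility, and interior placement is what makes them enclosed
    holes (not boundary bays) in the raw chromatic mask.
    """
    radii = rng.uniform(*radius_range, size=n)
    # keep the same clearance from the rounded fruit ends as from the
    # long silhouette edges
    margin = np.ceil(radii).astype(int) + half_thickness // 2
    idx = rng.integers(0, cols.size, size=n)
    idx = np.clip(idx, margin, cols.size - 1 - margin)
    c0 = cols[idx].astype(float)
    row_room = 0.5 * (half_thickness - radii)
    r0 = center[idx] + rng.uniform(-1.0, 1.0, size=n) * row_room
    return np.column_stack([r0, c0]), radii


def generate_scene(
    config: SceneConfig, spec: StageAppearanceSpec, seed: int
) -> LabeledScene:
    """Render one labeled scene; deterministic for a fixed (config, spec, seed)."""
    rng = np.random.default_rng(seed)
    H, W = config.image_height, config.image_width
    fruit, cols, center = _fruit_mask_and_centerline(config)

    # per-scene peel draw
    hue = rng.uniform(*spec.hue_range)
    sat = rng.uniform(*spec.saturation_range)
    val = rng.uniform(*spec.value_range)

    h_plane = np.full((H, W), hue)
    s_plane = np.full((H, W), sat)
    v_plane = np.full((H, W), val)

    # MS2 green patches: soft-edged elliptical blobs until the target
    # fraction is covered.  Peel color transitions are gradual (a ramp over
    # the blob's outer quarter), unlike the crisp borders of brown spots.
    if spec.green_patch_fraction > 0:
        target = spec.green_patch_fraction * fruit.sum()
        weight = np.zeros((H, W))
        rr = np.arange(H)[:, None]
        cc = np.arange(W)[None, :]
        for _ in range(64):
            if (weight >= 0.5).sum() >= target:
                break
            c0 = rng.uniform(cols[0], cols[-1])
            ci = int(np.clip(c0, cols[0], cols[-1]) - cols[0])
            r0 = rng.uniform(center[ci] - 30, center[ci] + 30)
            ar = rng.uniform(18, 40)
            br = rng.uniform(12, 26)
            q = np.sqrt(((rr - r0) / ar) ** 2 + ((cc - c0) / br) ** 2)
            w = np.clip((1.0 - q) / 0.25, 0.0, 1.0)  # ramp over the outer 25%
            weight = np.maximum(weight, np.where(fruit, w, 0.0))
        h_plane = weight * GREEN_PATCH_HUE + (1.0 - weight) * h_plane
        v_plane = weight * max(0.5, val - 0.08) + (1.0 - weight) * v_plane

    rgb = _hsv_to_rgb(h_plane, s_plane, v_plane) * 255.0

    # background cloth: pale gray with a blue bias so R <= B holds
    bg = np.empty((H, W, 3))
    bg[..., 0] = config.background_level - config.background_blue_bias / 2.0
    bg[..., 1] = config.background_level
    bg[..., 2] = config.background_level + config.background_blue_bias / 2.0
    img = np.where(fruit[..., None], rgb, bg)

    # brown spots (MS4): R ~ B so they disappear from the chromatic map.
    # Spots sit on the visible peel face, strictly inside the silhouette:
    # they punch enclosed holes in the raw chromatic mask (the failure mode
    # hole filling repairs) rather than bays in the outline.
    n_spots = rng.poisson(spec.spot_rate) if spec.spot_rate > 0 else 0
    if n_spots > 0:
        centers, radii = _interior_disks(
            rng, n_spots, cols, center, config.fruit_half_thickness,
            spec.spot_radius_range,
        )
        _blend_disks(img, fruit, centers, radii, SPOT_RGB)

    # occasional small dark defects, any stage
    n_def = rng.poisson(spec.defect_rate) if spec.defect_rate > 0 else 0
    if n_def > 0:
        centers, radii = _interior_disks(
            rng, n_def, cols, center, config.fruit_half_thickness, (2.0, 4.0)
        )
        _blend_disks(img, fruit, centers, radii, DEFECT_RGB)

    # peel micro-texture, added equally to all channels so the R - B
    # chromatic map is untouched: (i) longitudinal ridge striations
    # following the curved centerline, with random phase; (ii) a faint
    # isotropic mottle.  Ridge amplitude/wavelength grow with ripeness.
    texture = np.zeros((H, W))
    if spec.stripe_amplitude > 0:
        dist = np.full((H, W), np.nan)
        rows = np.arange(H)[:, None]
        dist[:, cols[0] : cols[-1] + 1] = rows - center[None, :]
        phase = rng.uniform(0.0, 2.0 * np.pi)
        stripes = spec.stripe_amplitude * np.sin(
            2.0 * np.pi * np.nan_to_num(dist) / spec.stripe_wavelength + phase
        )
        texture += stripes
    if spec.mottle_amplitude > 0:
        field = gaussian_filter(
            rng.standard_normal((H, W)), sigma=spec.mottle_scale
        )
        sd = field.std()
        if sd > 0:
            texture += field / sd * spec.mottle_amplitude
    img = img + np.where(fruit, texture, 0.0)[..., None]

    # linear illumination ramp across columns, then i.i.d. Gaussian noise
    g = config.illumination_gradient
    if g != 0:
        ramp = 1.0 - g / 2.0 + g * (np.arange(W) / max(W - 1, 1))
        img = img * ramp[None, :, None]
    if config.noise_sigma > 0:
        img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    scene = LabeledScene(image=img, mask=fruit, label=spec.stage)
    _check_scene_invariants(scene)
    return scene


def _check_scene_invariants(scene: LabeledScene) -> None:
    r = scene.image[..., 0].astype(int)
    b = scene.image[..., 2].astype(int)
    diff = r - b
    if np.median(diff[scene.mask]) <= 0:
        raise AssertionError("fruit pixels violate median(R - B) > 0")
    if np.median(diff[~scene.mask]) > 0:
        raise AssertionError("background pixels violate median(R - B) <= 0")


def generate_dataset(
    config: SceneConfig,
    n_per_stage: int,
    seed: int,
    appearance: dict[str, StageAppearanceSpec] | None = None,
) -> list[LabeledScene]:
    """Balanced dataset of ``4 * n_per_stage`` scenes.

    Per-scene seeds are derived from the master seed by counter offset,
    so any element is reproducible in isolation.
    """
    if n_per_stage < 1:
        raise ValueError("n_per_stage must be >= 1")
    appearance = appearance or DEFAULT_APPEARANCE
    scenes: list[LabeledScene] = []
    counter = 0
    for stage in STAGES:
        spec = appearance[stage]
        for _ in range(n_per_stage):
            scenes.append(generate_scene(config, spec, seed=seed + counter))
            counter += 1
    return scenes


def stage_index(label: str) -> int:
    """Map MS1..MS4 to 0..3."""
    return STAGES.index(label)
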