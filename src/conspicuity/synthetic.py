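"""Synthetic pop-out stimuli and synthetic observers.

Two stimulus families emulate classic visual-search displays:

* *control* arrays -- a jittered grid of red horizontal bars on a mid-gray
  canvas with one (or more) target bars deviating from the distractors in
  exactly one feature: a green bar (color), a near-black red bar
  (intensity), or a red bar rotated away from horizontal (orientation);
* *competitive* (CAT) arrays -- two targets, a green horizontal color
  singleton and a red oriented singleton, placed antipodally on a circle
  around the canvas center so neither enjoys an eccentricity advantage.

Bar side length follows the discrete ladder 7, 9, ..., 37 px (levels 1-16)
and targets land 250-360 px from the canvas center (scaled for smaller
canvases).  The synthetic observer samples fixations from a probability
field proportional to a known linear mix of the image's own three feature
maps, optionally contaminated with uniform outliers and positional jitter,
so every downstream stage can be validated against planted ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .density import (
    DensityMap,
    FixationRecord,
    SaccadicMap,
    build_density_map,
    build_saccadic_map,
)
from .errors import DataValidationError, PlacementError
from .features import (
    FEATURE_ORDER,
    ChannelConfig,
    FeatureMap,
    RasterImage,
    WeightVector,
    extract_feature_maps,
)
from .weights import FeatureMatrix, flatten_features

__all__ = [
    "RED",
    "GREEN",
    "DIM_RED",
    "bar_side_px",
    "TargetSpec",
    "StimulusSpec",
    "ObserverConfig",
    "SyntheticScene",
    "SyntheticDataset",
    "render_bar_stimulus",
    "render_cat_stimulus",
    "simulate_observer",
    "make_synthetic_dataset",
    "write_dataset",
]

RED = (1.0, 0.0, 0.0)
GREEN = (0.0, 1.0, 0.0)
#: Intensity target: distractor hue at near-minimum intensity.
DIM_RED = (0.1, 0.0, 0.0)
BLACK = (0.0, 0.0, 0.0)

#: Bars are rectangles of this length:thickness ratio inscribed in the bar box.
BAR_ASPECT = 4.0

#: Target eccentricity band on the reference 900-px canvas.
ECC_RANGE_PX = (250.0, 360.0)
REFERENCE_CANVAS = 900.0


def bar_side_px(bar_level: int) -> int:
    """Bar bounding-box side for a level on the 7..37 px ladder."""
    if not 1 <= bar_level <= 16:
        raise DataValidationError(f"bar_level must be in 1..16, got {bar_level}")
    return 7 + 2 * (bar_level - 1)


@dataclass(frozen=True)
class TargetSpec:
    """One feature-deviant target bar."""

    feature_kind: str  # "color" | "intensity" | "orientation"
    angle_deg: float = 90.0  # orientation targets only; 0 = horizontal
    eccentricity_px: float | None = None  # None -> sampled in the ecc band
    polar_angle_deg: float | None = None  # None -> sampled uniformly
    n_dots: int = 0  # 0-3 marker dots inside the glyph

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_ORDER:
            raise DataValidationError(f"unknown feature kind {self.feature_kind!r}")
        if not 0 <= self.n_dots <= 3:
            raise DataValidationError("n_dots must be 0..3")


@dataclass(frozen=True)
class StimulusSpec:
    """Parametric description of one bar-array trial."""

    canvas: tuple[int, int] = (900, 900)
    background: float = 0.5
    bar_level: int = 10
    grid_shape: tuple[int, int] = (8, 8)
    distractor_color: tuple[float, float, float] = RED
    targets: tuple[TargetSpec, ...] = (TargetSpec("orientation"),)
    jitter_frac: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        bar_side_px(self.bar_level)  # validates the ladder
        if not 0.0 <= self.background <= 1.0:
            raise DataValidationError("background gray must be in [0, 1]")
        if not self.targets:
            raise DataValidationError("at least one target is required")


@dataclass(frozen=True)
class ObserverConfig:
    """Synthetic eye-tracking cohort.

    Defaults mirror a typical free-viewing collection: 11 subjects whose
    first 5 saccades per image are analyzed; landing jitter defaults to 1%
    of the image diagonal and 5% of fixations are uniform outliers.
    """

    n_subjects: int = 11
    fixations_per_subject: int = 5
    position_noise_sd_px: float | None = None
    uniform_outlier_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.fixations_per_subject < 1:
            raise DataValidationError("observer needs >= 1 subject and fixation")
        if not 0.0 <= self.uniform_outlier_fraction <= 1.0:
            raise DataValidationError("outlier fraction must be in [0, 1]")


@dataclass
class SyntheticScene:
    """One rendered scene plus whatever ground truth was generated for it."""

    image: RasterImage
    target_positions: list[tuple[float, float]]  # (x, y) centroids
    seed: int
    target_kinds: list[str] = field(default_factory=list)
    true_weights: WeightVector | None = None
    maps: dict[str, FeatureMap] | None = None
    mix: np.ndarray | None = None  # exact X @ w, image-shaped
    fixations: list[FixationRecord] | None = None
    saccadic: SaccadicMap | None = None
    true_density: DensityMap | None = None

    @property
    def image_id(self) -> str:
        return self.image.image_id


@dataclass
class SyntheticDataset:
    """A bundle of scenes sharing one planted weight vector."""

    scenes: list[SyntheticScene]
    true_weights: WeightVector
    seed: int


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _paint_bar(
    pixels: np.ndarray,
    center_xy: tuple[float, float],
    length: float,
    thickness: float,
    angle_deg: float,
    color: Sequence[float],
) -> None:
    """Alpha-blend an anti-aliased rotated rectangle onto the canvas."""
    h, w = pixels.shape[:2]
    cx, cy = center_xy
    radius = math.hypot(length, thickness) / 2 + 1.5
    y0, y1 = max(0, int(cy - radius)), min(h, int(cy + radius) + 1)
    x0, x1 = max(0, int(cx - radius)), min(w, int(cx + radius) + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    th = math.radians(angle_deg)
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    cov_u = np.clip(length / 2 + 0.5 - np.abs(u), 0.0, 1.0)
    cov_v = np.clip(thickness / 2 + 0.5 - np.abs(v), 0.0, 1.0)
    alpha = (cov_u * cov_v)[..., None]
    pixels[y0:y1, x0:x1] = (1 - alpha) * pixels[y0:y1, x0:x1] + alpha * np.asarray(
        color
    )


def _paint_dot(
    pixels: np.ndarray,
    center_xy: tuple[float, float],
    radius: float,
    color: Sequence[float],
) -> None:
    h, w = pixels.shape[:2]
    cx, cy = center_xy
    r = radius + 1.5
    y0, y1 = max(0, int(cy - r)), min(h, int(cy + r) + 1)
    x0, x1 = max(0, int(cx - r)), min(w, int(cx + r) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    alpha = np.clip(radius + 0.5 - dist, 0.0, 1.0)[..., None]
    pixels[y0:y1, x0:x1] = (1 - alpha) * pixels[y0:y1, x0:x1] + alpha * np.asarray(
        color
    )


def _ecc_band(canvas: tuple[int, int]) -> tuple[float, float]:
    scale = min(canvas) / REFERENCE_CANVAS
    return ECC_RANGE_PX[0] * scale, ECC_RANGE_PX[1] * scale


def _target_style(
    t: TargetSpec, distractor_color: Sequence[float]
) -> tuple[tuple[float, ...], float]:
    if t.feature_kind == "color":
        return GREEN, 0.0
    if t.feature_kind == "intensity":
        return DIM_RED, 0.0
    return tuple(distractor_color), t.angle_deg


def render_bar_stimulus(spec: StimulusSpec) -> SyntheticScene:
    """Render a control search array; deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas
    side = bar_side_px(spec.bar_level)
    length, thickness = float(side), side / BAR_ASPECT
    rows, cols = spec.grid_shape
    sy, sx = h / rows, w / cols
    if min(sy, sx) < 1.5 * side:
        raise PlacementError(
            f"grid spacing {min(sy, sx):.1f} px < 1.5 bar sides ({1.5 * side:.1f} px); "
            "bars cannot be packed without overlap"
        )
    ecc_lo, ecc_hi = _ecc_band(spec.canvas)
    center = (w / 2.0, h / 2.0)

    # place targets first, inside the eccentricity band, non-overlapping
    positions: list[tuple[float, float]] = []
    kinds: list[str] = []
    for t in spec.targets:
        for _ in range(200):
            ecc = (
                float(t.eccentricity_px)
                if t.eccentricity_px is not None
                else rng.uniform(ecc_lo, ecc_hi)
            )
            phi = (
                math.radians(float(t.polar_angle_deg))
                if t.polar_angle_deg is not None
                else rng.uniform(0.0, 2 * math.pi)
            )
            cx = center[0] + ecc * math.cos(phi)
            cy = center[1] + ecc * math.sin(phi)
            margin = side
            inside = margin <= cx <= w - margin and margin <= cy <= h - margin
            clear = all(
                math.hypot(cx - px, cy - py) > 2 * side for px, py in positions
            )
            if inside and clear:
                break
        else:
            raise PlacementError("could not place targets without overlap")
        positions.append((cx, cy))
        kinds.append(t.feature_kind)

    pixels = np.full((h, w, 3), spec.background, dtype=float)
    for t, (cx, cy) in zip(spec.targets, positions):
        color, angle = _target_style(t, spec.distractor_color)
        _paint_bar(pixels, (cx, cy), length, thickness, angle, color)
        if t.n_dots:
            # dots along the bar's long axis, countable only on fixation
            th = math.radians(angle)
            offsets = np.linspace(-length / 4, length / 4, t.n_dots)
            for off in offsets:
                _paint_dot(
                    pixels,
                    (cx + off * math.cos(th), cy + off * math.sin(th)),
                    radius=max(1.0, thickness / 3.5),
                    color=BLACK,
                )

    jitter = spec.jitter_frac * min(sy, sx)
    for i in range(rows):
        for j in range(cols):
            cy = (i + 0.5) * sy + rng.uniform(-jitter, jitter)
            cx = (j + 0.5) * sx + rng.uniform(-jitter, jitter)
            if any(
                math.hypot(cx - px, cy - py) < 0.7 * min(sy, sx)
                for px, py in positions
            ):
                continue  # the target occupies this cell
            _paint_bar(
                pixels, (cx, cy), length, thickness, 0.0, spec.distractor_color
            )

    np.clip(pixels, 0.0, 1.0, out=pixels)
    image = RasterImage(pixels, image_id=f"bar-l{spec.bar_level}-s{spec.seed}")
    return SyntheticScene(
        image=image,
        target_positions=positions,
        target_kinds=kinds,
        seed=spec.seed,
    )


def render_cat_stimulus(
    angle_deg: float,
    bar_level: int = 10,
    seed: int = 0,
    n_dots: int = 0,
    canvas: tuple[int, int] = (900, 900),
    background: float = 0.5,
) -> SyntheticScene:
    """Render a competitive two-target array.

    A green horizontal color singleton and a red bar at ``angle_deg`` sit on
    opposite ends of a randomly oriented diameter of a circle whose radius
    falls in the eccentricity band; at 0 deg the orientation target
    degenerates into a plain distractor and color is the only deviant.
    """
    if angle_deg not in range(0, 100, 10):
        raise DataValidationError(
            f"CAT angle must be one of 0,10,...,90 deg, got {angle_deg}"
        )
    rng = np.random.default_rng(seed)
    ecc_lo, ecc_hi = _ecc_band(canvas)
    radius = rng.uniform(ecc_lo, ecc_hi)
    phi = rng.uniform(0.0, 360.0)
    targets = (
        TargetSpec("color", eccentricity_px=radius, polar_angle_deg=phi, n_dots=n_dots),
        TargetSpec(
            "orientation",
            angle_deg=float(angle_deg),
            eccentricity_px=radius,
            polar_angle_deg=phi + 180.0,
            n_dots=n_dots,
        ),
    )
    spec = StimulusSpec(
        canvas=canvas,
        background=background,
        bar_level=bar_level,
        targets=targets,
        seed=seed,
    )
    scene = render_bar_stimulus(spec)
    scene.image.image_id = f"cat-a{int(angle_deg)}-s{seed}"
    return scene


# ---------------------------------------------------------------------------
# synthetic observers
# ---------------------------------------------------------------------------

def simulate_observer(
    maps,
    true_weights: WeightVector | Sequence[float],
    cfg: ObserverConfig | None = None,
    image_id: str = "",
) -> list[FixationRecord]:
    """Sample fixations from the planted linear mix of feature maps.

    Fixation pixels are drawn i.i.d. from a probability field proportional
    to ``clip(X @ w, 0)``, mixed with a uniform component of weight
    ``uniform_outlier_fraction``, then perturbed by Gaussian positional
    jitter and clipped to the canvas.  Fully seeded and reproducible.
    """
    cfg = cfg or ObserverConfig()
    X = maps if isinstance(maps, FeatureMatrix) else flatten_features(maps)
    w = (
        true_weights.as_array()
        if isinstance(true_weights, WeightVector)
        else np.asarray(true_weights, dtype=float)
    )
    p = np.clip(X.values @ w, 0.0, None)
    total = p.sum()
    if total <= 0:
        raise DataValidationError("combined map is identically zero")
    p = p / total
    f = cfg.uniform_outlier_fraction
    p = (1 - f) * p + f / p.size
    h, w_img = X.n_rows, X.n_cols
    sd = (
        cfg.position_noise_sd_px
        if cfg.position_noise_sd_px is not None
        else 0.01 * math.hypot(h, w_img)
    )
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects * cfg.fixations_per_subject
    idx = rng.choice(p.size, size=n, p=p)
    rows, cols = np.unravel_index(idx, (h, w_img))
    if sd > 0:
        rows = rows + rng.normal(0.0, sd, size=n)
        cols = cols + rng.normal(0.0, sd, size=n)
    rows = np.clip(np.round(rows), 0, h - 1).astype(int)
    cols = np.clip(np.round(cols), 0, w_img - 1).astype(int)
    records = []
    k = 0
    for s in range(cfg.n_subjects):
        for order in range(1, cfg.fixations_per_subject + 1):
            records.append(
                FixationRecord(
                    image_id=image_id,
                    subject_id=f"s{s:02d}",
                    x=int(cols[k]),
                    y=int(rows[k]),
                    order=order,
                )
            )
            k += 1
    return records


# ---------------------------------------------------------------------------
# dataset bundles
# ---------------------------------------------------------------------------

def _random_texture(shape: tuple[int, int], seed: int) -> RasterImage:
    """Seeded smooth colored noise with an embedded oriented grating patch.

    The grating guarantees genuine orientation-energy structure so the three
    channel maps are not collinear; smoothing scales vary per channel so
    color and intensity structure decouple.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    channels = []
    for _ in range(3):
        noise = rng.standard_normal((h, w))
        channels.append(ndimage.gaussian_filter(noise, sigma=rng.uniform(2.0, 6.0)))
    px = np.stack(channels, axis=-1)
    # oriented grating in a Gaussian window at a random off-center spot
    yy, xx = np.mgrid[0:h, 0:w]
    th = rng.uniform(0.0, math.pi)
    freq = rng.uniform(0.06, 0.15)
    cy, cx = rng.uniform(0.25, 0.75) * h, rng.uniform(0.25, 0.75) * w
    envelope = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * (0.12 * min(h, w)) ** 2))
    grating = np.sin(2 * math.pi * freq * (xx * math.cos(th) + yy * math.sin(th)))
    px += 1.5 * (envelope * grating)[..., None]
    px -= px.min()
    peak = px.max()
    if peak > 0:
        px /= peak
    return RasterImage(px, image_id=f"tex-{seed}")


def make_synthetic_dataset(
    n_images: int,
    true_weights: WeightVector | Sequence[float] = (0.2, 0.1, 0.7),
    observer: ObserverConfig | None = None,
    seed: int = 0,
    image_size: tuple[int, int] = (128, 128),
    bar_fraction: float = 0.25,
    channel_cfg: ChannelConfig | None = None,
    out_dir: str | Path | None = None,
) -> SyntheticDataset:
    """Generate a fully labeled dataset bundle.

    Each scene carries its image, the three channel maps, the exact planted
    mix ``X @ w`` (``scene.mix``), seeded fixations sampled from that mix,
    the binary saccadic map and the smoothed density map.  A fraction of the
    scenes are bar-array stimuli, the rest smooth random textures.  With
    ``out_dir`` the bundle is also written in the standard dataset layout
    (``images/`` + ``fixations.csv`` + ``truth.json``).
    """
    if n_images < 1:
        raise DataValidationError("n_images must be >= 1")
    wv = (
        true_weights
        if isinstance(true_weights, WeightVector)
        else WeightVector.from_array(true_weights)
    )
    observer = observer or ObserverConfig()
    rng = np.random.default_rng(seed)
    n_bars = int(round(bar_fraction * n_images))
    scenes: list[SyntheticScene] = []
    for i in range(n_images):
        for _ in range(10):  # retry until the maps are identifiably independent
            img_seed = int(rng.integers(2**31))
            if i < n_bars:
                level = 2 if min(image_size) < 400 else 10
                grid = (4, 4) if min(image_size) < 400 else (8, 8)
                kind = FEATURE_ORDER[i % 3]
                spec = StimulusSpec(
                    canvas=image_size,
                    bar_level=level,
                    grid_shape=grid,
                    targets=(TargetSpec(kind),),
                    seed=img_seed,
                )
                scene = render_bar_stimulus(spec)
                image = scene.image
                target_positions, target_kinds = (
                    scene.target_positions,
                    scene.target_kinds,
                )
            else:
                image = _random_texture(image_size, img_seed)
                target_positions, target_kinds = [], []
            image.image_id = f"img{i:03d}"
            maps = extract_feature_maps(image, channel_cfg)
            X = flatten_features(maps)
            gram = X.values.T @ X.values
            if np.linalg.cond(gram) < 1e8:
                break
        mix = (X.values @ wv.as_array()).reshape(image.shape)
        obs = replace(observer, seed=int(rng.integers(2**31)))
        fixations = simulate_observer(X, wv, obs, image_id=image.image_id)
        smap = build_saccadic_map(fixations, image.shape)
        dmap = build_density_map(smap)
        scenes.append(
            SyntheticScene(
                image=image,
                target_positions=target_positions,
                target_kinds=target_kinds,
                seed=img_seed,
                true_weights=wv,
                maps=maps,
                mix=mix,
                fixations=fixations,
                saccadic=smap,
                true_density=dmap,
            )
        )
    bundle = SyntheticDataset(scenes=scenes, true_weights=wv, seed=seed)
    if out_dir is not None:
        write_dataset(bundle, out_dir)
    return bundle


def write_dataset(bundle: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write a bundle in the standard on-disk layout the pipeline reads."""
    from .io import save_image, write_fixation_table  # local: avoids cycle

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    records = []
    truth = {
        "true_weights": dict(zip(FEATURE_ORDER, bundle.true_weights.as_array())),
        "seed": bundle.seed,
        "scenes": {},
    }
    for scene in bundle.scenes:
        save_image(scene.image, out / "images" / f"{scene.image_id}.png")
        records.extend(scene.fixations or [])
        truth["scenes"][scene.image_id] = {
            "seed": scene.seed,
            "target_positions": [list(p) for p in scene.target_positions],
            "target_kinds": scene.target_kinds,
        }
    write_fixation_table(records, out / "fixations.csv")
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return out
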