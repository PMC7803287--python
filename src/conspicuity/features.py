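"""Bottom-up conspicuity channels in the style of the classic saliency
architecture of Itti, Koch and Niebur.

Each channel (color opponency, luminance contrast, oriented Gabor energy)
is computed as rectified center--surround differences across a Gaussian
pyramid, passed through a peak-promotion normalization operator, summed
across scales at a common pyramid level, and bilinearly upsampled back to
image resolution.  The resulting maps are the columns of the feature
matrix used downstream for metric scoring and weight estimation.

Conventions
-----------
* Images are ``h x w x 3`` float arrays, RGB, values in [0, 1].
* Maps are ``h x w`` nonnegative float arrays, max-normalized to 1 when
  nonzero, so that histogram bins and regression targets are comparable
  across channels.
* Orientation angles are in degrees, measured from the horizontal; a
  "0 deg" Gabor responds maximally to a horizontal bar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.filters import gabor_kernel
from skimage.transform import resize

from .errors import DimensionError

__all__ = [
    "MIN_IMAGE_SIDE",
    "FEATURE_ORDER",
    "RasterImage",
    "FeatureMap",
    "ChannelConfig",
    "WeightVector",
    "build_gaussian_pyramid",
    "normalize_map",
    "extract_intensity_conspicuity",
    "extract_color_conspicuity",
    "extract_orientation_conspicuity",
    "extract_feature_maps",
    "combine_saliency",
]

#: Smallest image side accepted by the channel extractors (pyramid depth).
MIN_IMAGE_SIDE = 64

#: Canonical channel ordering used for weight vectors and feature matrices.
FEATURE_ORDER = ("color", "intensity", "orientation")

#: Center-surround maps whose dynamic range falls below this are treated as
#: exactly zero, so that flat inputs yield identically zero channels instead
#: of normalized floating-point noise.
_ZERO_EPS = 1e-9


@dataclass
class RasterImage:
    """An RGB scene, natural or synthetic, with values in [0, 1]."""

    pixels: np.ndarray
    pixel_size_deg: float | None = None
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise DimensionError(
                f"expected an h x w x 3 RGB array, got shape {self.pixels.shape}"
            )
        h, w = self.pixels.shape[:2]
        if h < MIN_IMAGE_SIDE or w < MIN_IMAGE_SIDE:
            raise DimensionError(
                f"image {self.image_id!r} is {h}x{w}; channel extraction needs at "
                f"least {MIN_IMAGE_SIDE} px per side for the pyramid"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise DimensionError(
                f"image {self.image_id!r} contains non-finite values"
            )
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise DimensionError(
                f"image {self.image_id!r} has values outside [0, 1]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class FeatureMap:
    """A per-channel conspicuity (or combined saliency) map.

    Values are nonnegative and max-normalized to 1 when the map is nonzero;
    the map has the same height/width as its source image.
    """

    map_kind: str
    values: np.ndarray
    source_image_id: str = ""

    def __post_init__(self) -> None:
        if self.map_kind not in (*FEATURE_ORDER, "saliency"):
            raise ValueError(f"unknown map kind {self.map_kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("feature map must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise DimensionError("feature map contains non-finite values")
        if self.values.min() < 0:
            raise DimensionError("feature map contains negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class WeightVector:
    """Linear combination weights (w_color, w_intensity, w_orientation)."""

    w_color: float
    w_intensity: float
    w_orientation: float
    constrained: bool = False

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.w_color, self.w_intensity, self.w_orientation], dtype=float
        )

    @classmethod
    def from_array(cls, w, constrained: bool = False) -> "WeightVector":
        w = np.asarray(w, dtype=float).ravel()
        if w.size != 3 or not np.all(np.isfinite(w)):
            raise ValueError("weight vector must be 3 finite numbers")
        return cls(float(w[0]), float(w[1]), float(w[2]), constrained=constrained)

    @property
    def dominant_feature(self) -> str:
        return FEATURE_ORDER[int(np.argmax(self.as_array()))]


@dataclass(frozen=True)
class ChannelConfig:
    """Tunable parameters of the channel extractors.

    ``pyramid_depth=None`` adapts the depth to the image:
    ``min(9, floor(log2(min(h, w))) - 1)`` reduction steps, and
    center--surround pairs whose surround level does not exist are skipped.
    """

    pyramid_depth: int | None = None
    center_scales: tuple[int, ...] = (2, 3, 4)
    surround_deltas: tuple[int, ...] = (3, 4)
    across_scale_level: int = 2
    gabor_orientations_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    gabor_wavelength_px: float = 7.0
    gabor_bandwidth: float = 1.0
    normalization_iterations: int = 1
    luminance_threshold_frac: float = 0.02

    def __post_init__(self) -> None:
        angles = self.gabor_orientations_deg
        if len(set(angles)) != len(angles):
            raise ValueError("gabor orientations must be distinct")
        if any(a < 0 or a >= 180 for a in angles):
            raise ValueError("gabor orientations must lie in [0, 180) degrees")
        if not self.center_scales or not self.surround_deltas:
            raise ValueError("center scales and surround deltas must be nonempty")
        if self.normalization_iterations < 0:
            raise ValueError("normalization_iterations must be >= 0")

    def resolved_depth(self, shape: tuple[int, int]) -> int:
        """Number of pyramid reduction steps for an image of this shape."""
        adaptive = min(9, int(math.floor(math.log2(min(shape)))) - 1)
        depth = adaptive if self.pyramid_depth is None else self.pyramid_depth
        min_pair = min(self.center_scales) + min(self.surround_deltas)
        if depth < min_pair:
            raise DimensionError(
                f"pyramid depth {depth} leaves no center-surround pair "
                f"(smallest surround level is {min_pair})"
            )
        return depth


# ---------------------------------------------------------------------------
# pyramid
# ---------------------------------------------------------------------------

def _half_shape(shape: tuple[int, int]) -> tuple[int, int]:
    return (max(1, math.ceil(shape[0] / 2)), max(1, math.ceil(shape[1] / 2)))


def _resample(plane: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resampling on the pixel-center grid (mirror symmetric)."""
    if plane.shape == tuple(shape):
        return plane
    return resize(
        plane, shape, order=1, mode="edge", anti_aliasing=False, preserve_range=True
    )


def build_gaussian_pyramid(plane: np.ndarray, depth: int) -> list[np.ndarray]:
    """Gaussian pyramid: level k is a low-pass, factor-2 decimation of k-1.

    Returns ``depth + 1`` arrays, level 0 being the input itself.  Each
    reduction step blurs with a sigma-1 Gaussian (reflect boundary) and
    resamples bilinearly to ``ceil(n/2)`` on the symmetric pixel-center grid.
    """
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise DimensionError("pyramid input must be a 2-D plane")
    h, w = plane.shape
    max_depth = int(math.floor(math.log2(min(h, w)))) - 1
    if depth > max_depth:
        raise DimensionError(
            f"depth {depth} too large for a {h}x{w} plane (max {max_depth})"
        )
    levels = [plane.copy()]
    for _ in range(depth):
        prev = levels[-1]
        blurred = ndimage.gaussian_filter(prev, sigma=1.0, mode="reflect")
        levels.append(_resample(blurred, _half_shape(prev.shape)))
    return levels


# ---------------------------------------------------------------------------
# normalization operator
# ---------------------------------------------------------------------------

def normalize_map(values: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Peak-promotion normalization.

    The map is scaled to [0, 1] and multiplied by ``(M - mbar)**2`` where
    ``M`` is the (scaled) global maximum, 1, and ``mbar`` the mean of all
    other local maxima above 10% of the peak.  Maps with a single strong
    peak keep their weight; maps with many comparable peaks are suppressed.
    All-zero maps are returned unchanged.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise DimensionError("normalize_map requires finite input")
    if v.size and v.min() < 0:
        raise DimensionError("normalize_map requires nonnegative input")
    for _ in range(max(1, iterations)):
        peak = v.max() if v.size else 0.0
        if peak <= 0:
            return v.copy()
        v = v / peak
        size = max(3, (min(v.shape) // 10) | 1)
        local_max = ndimage.maximum_filter(v, size=size, mode="reflect")
        peaks = v[(v >= local_max - 1e-12) & (v > 0.1)]
        if peaks.size <= 1:
            weight = 1.0
        else:
            mbar = (peaks.sum() - peaks.max()) / (peaks.size - 1)
            weight = (1.0 - mbar) ** 2
        v = v * weight
    return v


# ---------------------------------------------------------------------------
# center-surround machinery
# ---------------------------------------------------------------------------

def _center_surround_pairs(
    n_levels: int, cfg: ChannelConfig
) -> list[tuple[int, int]]:
    pairs = [
        (c, c + d)
        for c in cfg.center_scales
        for d in cfg.surround_deltas
        if c + d < n_levels
    ]
    if not pairs:
        raise DimensionError(
            "no center-surround pair fits the pyramid; image too small"
        )
    return pairs


def _zero_small(m: np.ndarray) -> np.ndarray:
    return m if m.max() > _ZERO_EPS else np.zeros_like(m)


def _feature_maps_from_planes(
    planes: Sequence[list[np.ndarray]], cfg: ChannelConfig
) -> list[np.ndarray]:
    """Rectified across-scale differences |plane_c - plane_s| per pair."""
    maps = []
    n_levels = len(planes[0])
    for c, s in _center_surround_pairs(n_levels, cfg):
        for pyr in planes:
            surround = _resample(pyr[s], pyr[c].shape)
            maps.append((c, _zero_small(np.abs(pyr[c] - surround))))
    return maps


def _across_scale_sum(
    maps: Iterable[tuple[int, np.ndarray]],
    level_shapes: Sequence[tuple[int, int]],
    cfg: ChannelConfig,
) -> np.ndarray:
    target_level = min(cfg.across_scale_level, len(level_shapes) - 1)
    target = level_shapes[target_level]
    total = np.zeros(target)
    for _, m in maps:
        total += _resample(normalize_map(m, cfg.normalization_iterations), target)
    return total


def _finish_channel(
    consp: np.ndarray, shape: tuple[int, int], kind: str, image_id: str
) -> FeatureMap:
    full = np.clip(_resample(consp, shape), 0.0, None)
    peak = full.max()
    full = full / peak if peak > _ZERO_EPS else np.zeros_like(full)
    return FeatureMap(kind, full, image_id)


def _intensity_plane(image: RasterImage) -> np.ndarray:
    return image.pixels.mean(axis=2)


# ---------------------------------------------------------------------------
# channels
# ---------------------------------------------------------------------------

def extract_intensity_conspicuity(
    image: RasterImage, cfg: ChannelConfig | None = None
) -> FeatureMap:
    """Luminance-contrast channel: |I_c - I_s| across the intensity pyramid."""
    cfg = cfg or ChannelConfig()
    depth = cfg.resolved_depth(image.shape)
    pyr = build_gaussian_pyramid(_intensity_plane(image), depth)
    maps = _feature_maps_from_planes([pyr], cfg)
    consp = _across_scale_sum(maps, [lv.shape for lv in pyr], cfg)
    return _finish_channel(consp, image.shape, "intensity", image.image_id)


def _opponency_planes(
    image: RasterImage, cfg: ChannelConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Signed red-green and blue-yellow opponency planes.

    r, g, b are divided by local luminance (where luminance exceeds a small
    fraction of its maximum) so that hue is decoupled from intensity, then
    broadly-tuned color responses R, G, B, Y are formed and opposed.
    """
    return _signed_opponency(image, cfg)


def _signed_opponency(
    image: RasterImage, cfg: ChannelConfig
) -> tuple[np.ndarray, np.ndarray]:
    px = image.pixels
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    lum = _intensity_plane(image)
    thresh = cfg.luminance_threshold_frac * lum.max()
    mask = lum > max(thresh, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        rn = np.where(mask, r / lum, 0.0)
        gn = np.where(mask, g / lum, 0.0)
        bn = np.where(mask, b / lum, 0.0)
    R = np.clip(rn - (gn + bn) / 2, 0.0, None)
    G = np.clip(gn - (rn + bn) / 2, 0.0, None)
    B = np.clip(bn - (rn + gn) / 2, 0.0, None)
    Y = np.clip((rn + gn) / 2 - np.abs(rn - gn) / 2 - bn, 0.0, None)
    return R - G, B - Y


def extract_color_conspicuity(
    image: RasterImage, cfg: ChannelConfig | None = None
) -> FeatureMap:
    """Color-opponency channel from red-green and blue-yellow contrast.

    Each signed opponency plane is split into its rectified ON and OFF
    halves (the two polarities of a double-opponent cell population) before
    center--surround differencing, so each polarity competes in its own map
    under the peak-promotion operator.  A lone green item among many red
    ones then owns a single-peak map that survives normalization, while the
    many-peak opposite-polarity map is suppressed -- the model analogue of
    color pop-out.  The construction is symmetric under swapping the red
    and green planes of the input.
    """
    cfg = cfg or ChannelConfig()
    depth = cfg.resolved_depth(image.shape)
    rg, by = _opponency_planes(image, cfg)
    halves = [
        np.clip(rg, 0.0, None),
        np.clip(-rg, 0.0, None),
        np.clip(by, 0.0, None),
        np.clip(-by, 0.0, None),
    ]
    pyramids = [build_gaussian_pyramid(p, depth) for p in halves]
    maps = _feature_maps_from_planes(pyramids, cfg)
    consp = _across_scale_sum(maps, [lv.shape for lv in pyramids[0]], cfg)
    return _finish_channel(consp, image.shape, "color", image.image_id)


def _gabor_bank(cfg: ChannelConfig) -> dict[float, np.ndarray]:
    """Complex Gabor kernels keyed by the *bar* orientation they prefer.

    ``skimage.filters.gabor_kernel`` modulates along its ``theta`` direction,
    i.e. a theta-0 kernel prefers vertical structure; kernels are therefore
    built at ``bar_angle + 90`` degrees so the bank is labeled by the
    orientation of the bar that maximally excites it.
    """
    freq = 1.0 / cfg.gabor_wavelength_px
    bank = {}
    for angle in cfg.gabor_orientations_deg:
        bank[angle] = gabor_kernel(
            freq,
            theta=np.deg2rad(angle + 90.0),
            bandwidth=cfg.gabor_bandwidth,
        )
    return bank


def _gabor_energy(plane: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Magnitude of the complex Gabor response.

    The plane is padded symmetrically by the kernel half-size before a
    "valid" convolution; pyramid levels smaller than the kernel fall back
    to edge replication (symmetric reflection is undefined there), which
    still preserves constants and mirror symmetry.
    """
    kh, kw = kernel.shape
    pr, pc = kh // 2, kw // 2
    mode = "symmetric" if pr < plane.shape[0] and pc < plane.shape[1] else "edge"
    padded = np.pad(plane, ((pr, pr), (pc, pc)), mode=mode)
    return np.abs(fftconvolve(padded, kernel, mode="valid"))


def extract_orientation_conspicuity(
    image: RasterImage, cfg: ChannelConfig | None = None
) -> FeatureMap:
    """Oriented-energy channel: Gabor energy contrast at four orientations."""
    cfg = cfg or ChannelConfig()
    depth = cfg.resolved_depth(image.shape)
    pyr = build_gaussian_pyramid(_intensity_plane(image), depth)
    pairs = _center_surround_pairs(len(pyr), cfg)
    needed = sorted({lvl for pair in pairs for lvl in pair})
    bank = _gabor_bank(cfg)
    energy = {
        lvl: {a: _gabor_energy(pyr[lvl], k) for a, k in bank.items()}
        for lvl in needed
    }
    level_shapes = [lv.shape for lv in pyr]
    consp = np.zeros(level_shapes[min(cfg.across_scale_level, depth)])
    for angle in cfg.gabor_orientations_deg:
        maps = []
        for c, s in pairs:
            surround = _resample(energy[s][angle], energy[c][angle].shape)
            maps.append((c, _zero_small(np.abs(energy[c][angle] - surround))))
        theta_map = _across_scale_sum(maps, level_shapes, cfg)
        consp = consp + normalize_map(theta_map, cfg.normalization_iterations)
    return _finish_channel(consp, image.shape, "orientation", image.image_id)


_EXTRACTORS = {
    "color": extract_color_conspicuity,
    "intensity": extract_intensity_conspicuity,
    "orientation": extract_orientation_conspicuity,
}


def extract_feature_maps(
    image: RasterImage,
    cfg: ChannelConfig | None = None,
    kinds: Sequence[str] = FEATURE_ORDER,
) -> dict[str, FeatureMap]:
    """All requested channel maps of an image, keyed by kind."""
    return {kind: _EXTRACTORS[kind](image, cfg) for kind in kinds}


# ---------------------------------------------------------------------------
# combination
# ---------------------------------------------------------------------------

def _maps_in_order(
    maps: Mapping[str, FeatureMap] | Sequence[FeatureMap],
) -> list[FeatureMap]:
    if isinstance(maps, Mapping):
        ordered = [maps[k] for k in FEATURE_ORDER]
    else:
        ordered = list(maps)
        if len(ordered) == 3 and all(isinstance(m, FeatureMap) for m in ordered):
            kinds = [m.map_kind for m in ordered]
            if sorted(kinds) == sorted(FEATURE_ORDER) and kinds != list(FEATURE_ORDER):
                ordered = [ordered[kinds.index(k)] for k in FEATURE_ORDER]
    if len(ordered) != 3:
        raise DimensionError("expected exactly three feature maps")
    shapes = {m.shape for m in ordered}
    if len(shapes) != 1:
        raise DimensionError(f"feature maps disagree in shape: {shapes}")
    return ordered


def combine_saliency(
    maps: Mapping[str, FeatureMap] | Sequence[FeatureMap],
    weights: WeightVector | Sequence[float],
    rescale: bool = True,
) -> FeatureMap:
    """Weighted linear combination S = w_c*C + w_i*I + w_o*O.

    Negative pixels (possible with signed least-squares weights) are clipped
    to zero; by default the result is max-normalized to 1 when nonzero.
    """
    ordered = _maps_in_order(maps)
    if isinstance(weights, WeightVector):
        w = weights.as_array()
    else:
        w = np.asarray(weights, dtype=float).ravel()
    if w.size != 3 or not np.all(np.isfinite(w)):
        raise DimensionError("weights must be 3 finite numbers")
    s = sum(wk * m.values for wk, m in zip(w, ordered))
    s = np.clip(s, 0.0, None)
    if rescale and s.max() > 0:
        s = s / s.max()
    return FeatureMap("saliency", s, ordered[0].source_image_id)
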