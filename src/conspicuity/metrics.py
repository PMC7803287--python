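"""Similarity scores between maps and their per-image summaries.

Three scores compare a feature map with the human density map (or with
another feature map):

* ``correlation2d`` -- the normalized inner product
  sum(a*b) / sqrt(sum(a^2) * sum(b^2)).  Deliberately *not* Pearson
  correlation: there is no mean subtraction, so nonnegative maps score in
  [0, 1] and a map correlates perfectly with any positive rescaling of
  itself.
* ``mutual_information`` -- MI(A, B) = H(A) + H(B) - H(A, B) in bits, with
  entropies taken from (joint) intensity histograms of the maps rescaled
  to [0, 1].
* ``auc_fixation`` -- the area under the ROC curve of saliency as a
  classifier of fixated vs. non-fixated pixels, in its rank (Mann-Whitney)
  form with ties counted 1/2.

``winner_tally`` and ``significance_label`` aggregate per-image scores the
way the per-dataset report tables do.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .density import SaccadicMap
from .errors import DataValidationError, DimensionError, UndefinedMetricError
from .features import FeatureMap

__all__ = [
    "EntropyValue",
    "WinnerTally",
    "correlation2d",
    "histogram_entropy",
    "mutual_information",
    "auc_fixation",
    "winner_tally",
    "significance_label",
]


def _values(obj) -> np.ndarray:
    if isinstance(obj, FeatureMap):
        return obj.values
    if hasattr(obj, "values") and isinstance(getattr(obj, "values"), np.ndarray):
        return np.asarray(obj.values, dtype=float)
    return np.asarray(obj, dtype=float)


def _check_pair(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise DimensionError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DataValidationError("metric operands must be finite")


@dataclass(frozen=True)
class EntropyValue:
    """Shannon entropy of a map's intensity histogram, in bits."""

    bits: float
    n_bins: int

    def __float__(self) -> float:
        return self.bits


def correlation2d(a, b) -> float:
    """2-D correlation without mean subtraction (see module docstring)."""
    A, B = _values(a), _values(b)
    _check_pair(A, B)
    denom = float(np.sqrt((A * A).sum() * (B * B).sum()))
    if denom == 0:
        raise UndefinedMetricError(
            "correlation undefined: an operand is identically zero"
        )
    return float((A * B).sum() / denom)


def _rescaled_unit(v: np.ndarray) -> np.ndarray:
    peak = v.max()
    return v / peak if peak > 0 else v


def histogram_entropy(a, n_bins: int = 256) -> EntropyValue:
    """Entropy of the intensity histogram after rescaling the map to [0, 1]."""
    if n_bins < 2:
        raise DataValidationError("need at least 2 histogram bins")
    v = _values(a)
    if not np.all(np.isfinite(v)):
        raise DataValidationError("entropy input must be finite")
    v = _rescaled_unit(v - v.min() if v.min() < 0 else v)
    hist, _ = np.histogram(v, bins=n_bins, range=(0.0, 1.0))
    p = hist[hist > 0] / hist.sum()
    bits = float(-(p * np.log2(p)).sum())
    return EntropyValue(bits=bits, n_bins=n_bins)


def _joint_histogram(A: np.ndarray, B: np.ndarray, n_bins: int) -> np.ndarray:
    va = _rescaled_unit(A).ravel()
    vb = _rescaled_unit(B).ravel()
    joint, _, _ = np.histogram2d(
        va, vb, bins=n_bins, range=[[0.0, 1.0], [0.0, 1.0]]
    )
    return joint / joint.sum()


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information(a, b, n_bins: int = 32) -> float:
    """MI(A, B) = H(A) + H(B) - H(A, B) in bits, from the joint histogram.

    Marginals are taken from the same joint histogram, so the estimate is
    symmetric and nonnegative up to floating-point rounding.
    """
    A, B = _values(a), _values(b)
    _check_pair(A, B)
    if n_bins < 2:
        raise DataValidationError("need at least 2 histogram bins")
    pxy = _joint_histogram(A, B, n_bins)
    hx = _entropy_bits(pxy.sum(axis=1))
    hy = _entropy_bits(pxy.sum(axis=0))
    hxy = _entropy_bits(pxy.ravel())
    return hx + hy - hxy


def _positive_mask(positives, shape: tuple[int, int]) -> np.ndarray:
    if isinstance(positives, SaccadicMap):
        mask = positives.values.astype(bool)
    else:
        arr = np.asarray(positives)
        if arr.ndim == 2 and arr.shape == shape:
            mask = arr.astype(bool)
        else:
            mask = np.zeros(shape, dtype=bool)
            for rc in positives:
                row, col = int(rc[0]), int(rc[1])
                if not (0 <= row < shape[0] and 0 <= col < shape[1]):
                    raise DataValidationError(f"positive pixel {rc} out of bounds")
                mask[row, col] = True
    if mask.shape != shape:
        raise DimensionError("positives mask shape mismatch")
    return mask


def auc_fixation(saliency, positives) -> float:
    """Fixation ROC area in rank form.

    Probability that a uniformly drawn positive (fixated) pixel has strictly
    higher saliency than a uniformly drawn negative pixel, ties counted 1/2.
    Equals the trapezoidal area under the threshold-sweep ROC curve.
    """
    sal = _values(saliency)
    if not np.all(np.isfinite(sal)):
        raise DataValidationError("saliency must be finite")
    mask = _positive_mask(positives, sal.shape)
    n_pos = int(mask.sum())
    n_neg = mask.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            "AUC needs at least one positive and one negative pixel"
        )
    ranks = stats.rankdata(sal.ravel())
    pos_rank_sum = ranks[mask.ravel()].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_many(flat_saliency: np.ndarray, flat_mask: np.ndarray) -> np.ndarray:
    """Vectorized rank AUC for a (n_pixels, k) column stack of saliency maps.

    Shares the Mann-Whitney formulation of :func:`auc_fixation`; used by the
    genetic optimizer to score whole populations in one pass.
    """
    n_pos = int(flat_mask.sum())
    n_neg = flat_mask.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            "AUC needs at least one positive and one negative pixel"
        )
    # average rank of value v is (#less + #less-or-equal + 1) / 2, so the
    # positive rank sum follows from two binary searches per column
    srt = np.sort(flat_saliency, axis=0)
    pos = flat_saliency[flat_mask]
    out = np.empty(flat_saliency.shape[1])
    for k in range(flat_saliency.shape[1]):
        lt = np.searchsorted(srt[:, k], pos[:, k], side="left")
        le = np.searchsorted(srt[:, k], pos[:, k], side="right")
        rank_sum = (lt + le + 1).sum() / 2.0
        out[k] = (rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return out


@dataclass
class WinnerTally:
    """Per-feature counts of images on which that feature's score was maximal.

    Ties are split fractionally among the tied features, so counts may be
    non-integer but always sum to the number of images.
    """

    metric_kind: str
    counts: dict[str, float]
    percentages: dict[str, float]
    n_images: int


def winner_tally(
    per_image_scores: pd.DataFrame | Iterable[tuple],
    metric_kind: str = "",
    features: Sequence[str] | None = None,
) -> WinnerTally:
    """Tally which feature attains the per-image maximum score.

    ``per_image_scores`` is a table of (image, feature, value); every image
    must carry exactly one score per feature.  The expected feature set
    defaults to the three channels whenever the observed labels are drawn
    from them, so a wholly absent channel is still reported as missing.
    """
    if isinstance(per_image_scores, pd.DataFrame):
        df = per_image_scores.iloc[:, :3].copy()
        df.columns = ["image", "feature", "value"]
    else:
        df = pd.DataFrame(per_image_scores, columns=["image", "feature", "value"])
    observed = set(df["feature"].unique())
    if features is None:
        from .features import FEATURE_ORDER

        features = (
            list(FEATURE_ORDER) if observed <= set(FEATURE_ORDER) else sorted(observed)
        )
    features = sorted(features)
    counts = {f: 0.0 for f in features}
    n_images = df["image"].nunique()
    for image, group in df.groupby("image", sort=True):
        if sorted(group["feature"]) != list(features):
            raise DataValidationError(
                f"image {image!r} is missing scores for some features"
            )
        vals = group.set_index("feature")["value"]
        top = vals.max()
        tied = [f for f in features if np.isclose(vals[f], top, rtol=0, atol=1e-12)]
        for f in tied:
            counts[f] += 1.0 / len(tied)
    percentages = {f: 100.0 * c / n_images for f, c in counts.items()}
    return WinnerTally(metric_kind, counts, percentages, n_images)


def significance_label(
    paired_a: Sequence[float], paired_b: Sequence[float]
) -> tuple[str, float]:
    """Paired two-sided t-test across images, mapped to NS / S / HS.

    p >= 0.05 -> "NS"; 1e-5 <= p < 0.05 -> "S"; p < 1e-5 -> "HS".
    Identical inputs (zero variance of the differences) are reported as NS
    with p = 1.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise DimensionError("paired score vectors differ in length")
    if a.size < 5:
        raise DataValidationError("need at least 5 paired scores")
    diffs = a - b
    if np.allclose(diffs, diffs[0]) and np.isclose(diffs[0], 0):
        p = 1.0
    else:
        _, p = stats.ttest_rel(a, b)
        p = 1.0 if np.isnan(p) else float(p)
    if p >= 0.05:
        label = "NS"
    elif p >= 1e-5:
        label = "S"
    else:
        label = "HS"
    return label, p
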