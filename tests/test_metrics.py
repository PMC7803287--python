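"""Similarity metrics against brute-force reference implementations."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import conspicuity as cp
from conspicuity.errors import (
    DataValidationError,
    DimensionError,
    UndefinedMetricError,
)

# ---------------------------------------------------------------------------
# brute-force oracles (kept deliberately naive and independent)
# ---------------------------------------------------------------------------


def corr_oracle(A, B):
    num = den_a = den_b = 0.0
    for i in range(A.shape[0]):
        for j in range(A.shape[1]):
            num += A[i, j] * B[i, j]
            den_a += A[i, j] ** 2
            den_b += B[i, j] ** 2
    return num / np.sqrt(den_a * den_b)


def entropy_oracle(A, n_bins):
    v = A / A.max() if A.max() > 0 else A
    counts = [0] * n_bins
    for x in v.ravel():
        k = min(int(x * n_bins), n_bins - 1)
        counts[k] += 1
    total = sum(counts)
    return -sum(c / total * np.log2(c / total) for c in counts if c)


def mi_oracle(A, B, n_bins):
    va = (A / A.max() if A.max() > 0 else A).ravel()
    vb = (B / B.max() if B.max() > 0 else B).ravel()
    joint = np.zeros((n_bins, n_bins))
    for x, y in zip(va, vb):
        i = min(int(x * n_bins), n_bins - 1)
        j = min(int(y * n_bins), n_bins - 1)
        joint[i, j] += 1
    joint /= joint.sum()

    def h(p):
        p = p[p > 0]
        return -(p * np.log2(p)).sum()

    return h(joint.sum(1)) + h(joint.sum(0)) - h(joint.ravel())


def auc_pairs_oracle(sal, mask):
    pos = sal[mask]
    neg = sal[~mask]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def auc_sweep_oracle(sal, mask):
    """Trapezoidal area under the threshold-sweep ROC curve."""
    thresholds = np.unique(sal)[::-1]
    n_pos, n_neg = mask.sum(), (~mask).sum()
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        sel = sal >= t
        tpr.append((sel & mask).sum() / n_pos)
        fpr.append((sel & ~mask).sum() / n_neg)
    return float(np.trapezoid(tpr, fpr))


# ---------------------------------------------------------------------------


class TestCorrelation2d:
    def test_self_correlation_is_one(self, rng):
        A = rng.uniform(0, 1, (16, 16))
        assert np.isclose(cp.correlation2d(A, A), 1.0)

    def test_disjoint_support_scores_zero(self):
        A = np.array([[1.0, 0.0], [0.0, 0.0]])
        B = np.array([[0.0, 0.0], [0.0, 1.0]])
        assert cp.correlation2d(A, B) == 0.0

    def test_scale_invariance(self, rng):
        A = rng.uniform(0, 1, (16, 16))
        assert np.isclose(cp.correlation2d(A, 3.0 * A), 1.0)

    def test_zero_operand_rejected(self, rng):
        with pytest.raises(UndefinedMetricError):
            cp.correlation2d(np.zeros((4, 4)), rng.uniform(0, 1, (4, 4)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            cp.correlation2d(np.ones((4, 4)), np.ones((4, 5)))

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(20):
            A, B = rng.uniform(0, 1, (2, 16, 16))
            assert abs(cp.correlation2d(A, B) - corr_oracle(A, B)) < 1e-10


class TestHistogramEntropy:
    def test_constant_map_has_zero_entropy(self):
        assert cp.histogram_entropy(np.full((8, 8), 0.4)).bits == 0.0

    def test_uniform_histogram_attains_log2_bins(self):
        vals = (np.arange(256) + 0.5) / 256.0
        ent = cp.histogram_entropy(vals.reshape(16, 16), n_bins=256)
        assert np.isclose(ent.bits, 8.0)

    def test_two_equal_levels_give_one_bit(self):
        vals = np.array([[0.0, 1.0]] * 8)
        assert np.isclose(cp.histogram_entropy(vals, n_bins=2).bits, 1.0)

    def test_bounded_by_log2_bins(self, rng):
        for bins in (8, 32):
            ent = cp.histogram_entropy(rng.uniform(0, 1, (32, 32)), n_bins=bins)
            assert 0.0 <= ent.bits <= np.log2(bins)

    def test_matches_counting_oracle(self, rng):
        for _ in range(10):
            A = rng.uniform(0, 1, (16, 16))
            mine = cp.histogram_entropy(A, n_bins=16).bits
            assert abs(mine - entropy_oracle(A, 16)) < 1e-10


class TestMutualInformation:
    def test_self_information_equals_entropy(self, rng):
        A = rng.uniform(0, 1, (16, 16))
        assert np.isclose(
            cp.mutual_information(A, A, 16), cp.histogram_entropy(A, 16).bits
        )

    def test_symmetry(self, rng):
        for _ in range(10):
            A, B = rng.uniform(0, 1, (2, 16, 16))
            assert np.isclose(
                cp.mutual_information(A, B, 8), cp.mutual_information(B, A, 8)
            )

    def test_independent_noise_carries_little_information(self):
        a = np.random.default_rng(11).uniform(0, 1, (256, 256))
        b = np.random.default_rng(22).uniform(0, 1, (256, 256))
        assert cp.mutual_information(a, b, 32) < 0.02

    def test_bounded_by_marginal_entropies(self, rng):
        for _ in range(10):
            A, B = rng.uniform(0, 1, (2, 16, 16))
            mi = cp.mutual_information(A, B, 8)
            assert mi <= min(
                cp.histogram_entropy(A, 8).bits, cp.histogram_entropy(B, 8).bits
            ) + 1e-9
            assert mi >= -1e-12

    def test_matches_joint_histogram_oracle(self, rng):
        for _ in range(10):
            A, B = rng.uniform(0, 1, (2, 16, 16))
            assert abs(cp.mutual_information(A, B, 8) - mi_oracle(A, B, 8)) < 1e-10

    def test_agrees_with_sklearn_contingency_mi(self, rng):
        from sklearn.metrics import mutual_info_score

        A, B = rng.uniform(0, 1, (2, 32, 32))
        bins = 8
        la = np.minimum((A / A.max() * bins).astype(int), bins - 1).ravel()
        lb = np.minimum((B / B.max() * bins).astype(int), bins - 1).ravel()
        ref = mutual_info_score(la, lb) / np.log(2)
        assert np.isclose(cp.mutual_information(A, B, bins), ref, atol=1e-10)


class TestAucFixation:
    def test_complete_separation_scores_one(self):
        sal = np.array([[0.9, 0.1], [0.2, 0.8]])
        assert cp.auc_fixation(sal, {(0, 0), (1, 1)}) == 1.0

    def test_constant_saliency_is_chance(self):
        sal = np.full((8, 8), 0.3)
        mask = np.zeros((8, 8), bool)
        mask[2, 2] = True
        assert cp.auc_fixation(sal, mask) == 0.5

    def test_tie_with_one_negative_pair(self):
        sal = np.array([[0.5, 0.5, 0.1]])
        mask = np.array([[True, False, False]])
        assert cp.auc_fixation(sal, mask) == 0.75

    def test_degenerate_positive_sets_rejected(self, rng):
        sal = rng.uniform(0, 1, (4, 4))
        with pytest.raises(UndefinedMetricError):
            cp.auc_fixation(sal, np.zeros((4, 4), bool))
        with pytest.raises(UndefinedMetricError):
            cp.auc_fixation(sal, np.ones((4, 4), bool))

    def test_matches_pair_enumeration_and_threshold_sweep(self, rng):
        for _ in range(20):
            sal = rng.choice(np.linspace(0, 1, 13), size=(16, 16))
            mask = rng.uniform(size=(16, 16)) < 0.2
            if not mask.any() or mask.all():
                continue
            mine = cp.auc_fixation(sal, mask)
            assert abs(mine - auc_pairs_oracle(sal, mask)) < 1e-10
            assert abs(mine - auc_sweep_oracle(sal, mask)) < 1e-10

    def test_agrees_with_sklearn_roc_auc(self, rng):
        from sklearn.metrics import roc_auc_score

        sal = rng.uniform(0, 1, (32, 32))
        mask = rng.uniform(size=(32, 32)) < 0.1
        ref = roc_auc_score(mask.ravel(), sal.ravel())
        assert np.isclose(cp.auc_fixation(sal, mask), ref, atol=1e-12)


@given(
    arrays(float, (8, 8), elements=st.floats(0.01, 1.0)),
    st.floats(1.001, 50.0),
)
def test_correlation_scale_invariance_property(A, scale):
    assert np.isclose(cp.correlation2d(A, scale * A), 1.0, atol=1e-9)


@given(arrays(float, (10, 10), elements=st.floats(0.0, 1.0)), st.integers(2, 16))
def test_entropy_within_bounds_property(A, bins):
    ent = cp.histogram_entropy(A, n_bins=bins)
    assert -1e-12 <= ent.bits <= np.log2(bins) + 1e-12


class TestWinnerTally:
    @staticmethod
    def _table(values_by_image):
        rows = []
        for img, vals in values_by_image.items():
            for feat, v in zip(cp.FEATURE_ORDER, vals):
                rows.append((img, feat, v))
        return rows

    def test_counts_straight_majority(self):
        vals = {f"i{k}": (0.1, 0.2, 0.9) for k in range(8)}
        vals.update({"j0": (0.9, 0.1, 0.2), "j1": (0.1, 0.9, 0.2)})
        tally = cp.winner_tally(self._table(vals), "auc")
        assert tally.percentages["orientation"] == 80.0
        assert sum(tally.counts.values()) == 10

    def test_exact_tie_splits_fractionally(self):
        tally = cp.winner_tally(self._table({"i": (0.5, 0.5, 0.5)}))
        assert all(np.isclose(c, 1 / 3) for c in tally.counts.values())
        assert np.isclose(sum(tally.percentages.values()), 100.0)

    def test_single_image_winner_gets_everything(self):
        tally = cp.winner_tally(self._table({"i": (0.9, 0.1, 0.2)}))
        assert tally.percentages == {"color": 100.0, "intensity": 0.0, "orientation": 0.0}

    def test_missing_feature_score_names_the_image(self):
        rows = [("imgX", "color", 0.5), ("imgX", "intensity", 0.4)]
        with pytest.raises(DataValidationError, match="imgX"):
            cp.winner_tally(rows)


class TestSignificanceLabel:
    def test_identical_vectors_are_not_significant(self):
        a = np.linspace(0, 1, 20)
        label, p = cp.significance_label(a, a.copy())
        assert label == "NS" and p == 1.0

    def test_large_consistent_shift_is_highly_significant(self, rng):
        a = rng.uniform(0, 1, 100)
        b = a + 10 + rng.normal(0, 1e-3, 100)
        label, p = cp.significance_label(a, b)
        assert label == "HS" and p < 1e-5

    def test_threshold_bands(self, rng):
        # engineered moderate effect: p in the S band
        a = rng.normal(0, 1, 30)
        b = a + 0.6 + rng.normal(0, 1, 30) * 0.9
        label, p = cp.significance_label(a, b)
        if 1e-5 <= p < 0.05:
            assert label == "S"
        elif p >= 0.05:
            assert label == "NS"
        else:
            assert label == "HS"

    def test_short_vectors_rejected(self):
        with pytest.raises(DataValidationError):
            cp.significance_label([1, 2], [3, 4])
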