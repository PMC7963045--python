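import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jsom import (
    Dataset,
    DegenerateInputError,
    SharedFeatureSpec,
    binarize_dataset,
    binary_match,
    build_matching,
    pearson_match,
    stepminer_threshold,
)


def brute_stepminer(values):
    """Independent O(L^2) two-segment step fit on sorted values."""
    v = np.sort(np.asarray(values, float))
    L = len(v)
    best = None
    for s in range(1, L):
        left, right = v[:s], v[s:]
        sse = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if best is None or sse < best[0] - 1e-12:
            best = (sse, s, 0.5 * (left.mean() + right.mean()))
    return best[2], best[1]


class TestPearsonMatch:
    def test_self_match_has_delta_one(self, rng):
        A = rng.normal(size=(8, 6))
        res = pearson_match(A, A)
        assert np.array_equal(res.match_1to2, np.arange(8))
        np.testing.assert_allclose(res.delta1, 1.0, atol=1e-12)

    def test_perfect_positive_and_clamped_negative(self):
        A = np.array([[1.0, 2.0, 3.0]])
        B = np.array([[2.0, 4.0, 6.0], [3.0, 2.0, 1.0]])
        res = pearson_match(A, B)
        assert res.match_1to2[0] == 0
        assert res.delta1[0] == pytest.approx(1.0)
        # the anticorrelated candidate would carry weight 0
        res_neg = pearson_match(np.array([[3.0, 2.0, 1.0]]), B[:1],
                                allow_negative_delta=True)
        assert res_neg.delta1[0] == pytest.approx(-1.0)
        res_clamped = pearson_match(np.array([[3.0, 2.0, 1.0]]), B[:1])
        assert res_clamped.delta1[0] == 0.0

    def test_constant_row_gets_zero_delta_and_warning(self):
        A = np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        B = np.array([[1.0, 2.0, 3.0], [0.0, 1.0, 5.0]])
        with pytest.warns(UserWarning, match="constant"):
            res = pearson_match(A, B)
        assert res.delta1[0] == 0.0 and res.match_1to2[0] == 0
        assert res.delta1[1] == pytest.approx(1.0)

    def test_few_features_warns(self):
        with pytest.warns(UserWarning, match="shared feature"):
            pearson_match(np.array([[1.0, 2.0]]), np.array([[1.0, 3.0]]))

    @given(st.floats(0.1, 10), st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_positive_affine_rescaling(self, a, b):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(5, 6))
        B = rng.normal(size=(7, 6))
        base = pearson_match(A, B)
        A2 = A.copy()
        A2[2] = a * A2[2] + b
        res = pearson_match(A2, B)
        assert np.array_equal(base.match_1to2, res.match_1to2)
        np.testing.assert_allclose(base.delta1, res.delta1, atol=1e-10)

    def test_deltas_in_unit_interval(self, rng):
        A, B = rng.normal(size=(30, 5)), rng.normal(size=(40, 5))
        res = pearson_match(A, B)
        for d in (res.delta1, res.delta2):
            assert ((d >= 0) & (d <= 1 + 1e-12)).all()


class TestStepminer:
    def test_clean_step(self):
        thr, s = stepminer_threshold([1, 1, 1, 5, 5, 5])
        assert thr == pytest.approx(3.0) and s == 3

    def test_matches_brute_force_on_asymmetric_input(self):
        assert stepminer_threshold([0, 0, 1, 10]) == pytest.approx(
            brute_stepminer([0, 0, 1, 10])
        )

    def test_constant_input_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            stepminer_threshold([2, 2, 2, 2])

    def test_brute_force_oracle_equivalence(self, rng):
        for _ in range(60):
            L = rng.integers(2, 200)
            v = rng.normal(size=L)
            if np.ptp(v) == 0:
                continue
            thr, s = stepminer_threshold(v)
            bthr, bs = brute_stepminer(v)
            assert s == bs and thr == pytest.approx(bthr, abs=1e-10)

    def test_order_independence(self, rng):
        v = rng.normal(size=50)
        assert stepminer_threshold(v) == stepminer_threshold(v[::-1])


class TestBinarize:
    def test_simple_column(self):
        view = binarize_dataset(np.array([[1.0], [1.0], [5.0], [5.0]]))
        assert view.thresholds[0] == pytest.approx(3.0)
        assert view.bits[:, 0].tolist() == [0, 0, 1, 1]

    def test_monotone_column_splits_low_high(self):
        col = np.arange(10.0)[:, None]
        view = binarize_dataset(col)
        bits = view.bits[:, 0]
        assert (np.diff(bits) >= 0).all() and bits[0] == 0 and bits[-1] == 1

    def test_constant_column_dropped_with_warning(self):
        X = np.array([[1.0, 7.0], [1.0, 7.0], [5.0, 7.0]])
        with pytest.warns(UserWarning, match="constant"):
            view = binarize_dataset(X)
        assert view.bits.shape[1] == 1
        assert view.kept.tolist() == [0]
        assert view.thresholds.tolist() == [pytest.approx(3.0)]


class TestBinaryMatch:
    def test_identical_rows_full_agreement(self):
        A = binarize_dataset(np.array([[0.0, 9.0], [9.0, 0.0], [9.0, 9.0]]))
        res = binary_match(A, A)
        np.testing.assert_allclose(res.delta1, 1.0)
        assert np.array_equal(res.match_1to2, np.arange(3))

    def test_partial_agreement_counted(self):
        from jsom import BinaryView

        A = BinaryView(np.array([[1, 0, 1, 0]]), np.zeros(4))
        B = BinaryView(np.array([[1, 0, 0, 0], [0, 1, 0, 1]]), np.zeros(4))
        res = binary_match(A, B)
        assert res.match_1to2[0] == 0 and res.delta1[0] == pytest.approx(0.75)

    def test_complement_has_zero_delta(self):
        from jsom import BinaryView

        A = BinaryView(np.array([[1, 0, 1]]), np.zeros(3))
        B = BinaryView(np.array([[0, 1, 0]]), np.zeros(3))
        assert binary_match(A, B).delta1[0] == 0.0

    def test_similarity_symmetric_for_mutual_best_pairs(self, rng):
        bits1 = rng.integers(0, 2, size=(15, 9))
        bits2 = rng.integers(0, 2, size=(12, 9))
        from jsom import BinaryView

        res = binary_match(BinaryView(bits1, np.zeros(9)), BinaryView(bits2, np.zeros(9)))
        for i, j in enumerate(res.match_1to2):
            if res.match_2to1[j] == i:
                assert res.delta1[i] == pytest.approx(res.delta2[j])

    def test_column_mismatch_rejected(self):
        from jsom import BinaryView

        with pytest.raises(ValueError):
            binary_match(BinaryView(np.zeros((2, 3), int), np.zeros(3)),
                         BinaryView(np.zeros((2, 4), int), np.zeros(4)))


class TestBuildMatching:
    def _pair(self, rng, n1=12, n2=15, p=10):
        X1, X2 = rng.normal(size=(n1, p)), rng.normal(size=(n2, p))
        mk = lambda X, tag: Dataset(X, [f"f{i}" for i in range(p)],
                                    [f"{tag}{i}" for i in range(X.shape[0])])
        return mk(X1, "a"), mk(X2, "b")

    def test_correlation_on_shared_columns_only(self, rng):
        d1, d2 = self._pair(rng)
        spec = SharedFeatureSpec(idx1=[0, 2, 4, 6], idx2=[1, 3, 5, 7])
        res = build_matching(d1, d2, spec, mode="correlation")
        expected = pearson_match(d1.values[:, [0, 2, 4, 6]], d2.values[:, [1, 3, 5, 7]])
        assert np.array_equal(res.match_1to2, expected.match_1to2)
        np.testing.assert_allclose(res.delta1, expected.delta1)

    def test_self_match_correlation(self, rng):
        d1, _ = self._pair(rng)
        spec = SharedFeatureSpec(idx1=list(range(10)), idx2=list(range(10)))
        res = build_matching(d1, d1, spec)
        assert np.array_equal(res.match_1to2, np.arange(d1.n_cells))

    def test_binary_mode_equals_composition(self, rng):
        d1, d2 = self._pair(rng)
        idx = list(range(7))  # cytometry-style overlap: 7 shared markers
        spec = SharedFeatureSpec(idx1=idx, idx2=idx)
        res = build_matching(d1, d2, spec, mode="binary")
        direct = binary_match(binarize_dataset(d1.values[:, idx]),
                              binarize_dataset(d2.values[:, idx]))
        assert np.array_equal(res.match_1to2, direct.match_1to2)
        np.testing.assert_allclose(res.delta1, direct.delta1)
        assert res.mode == "binary"

    def test_binary_mode_drops_paired_constant_column(self, rng):
        d1, d2 = self._pair(rng, p=4)
        d1.values[:, 2] = 3.0  # constant in d1 only
        spec = SharedFeatureSpec(idx1=[0, 1, 2, 3], idx2=[0, 1, 2, 3])
        with pytest.warns(UserWarning, match="dropping"):
            res = build_matching(d1, d2, spec, mode="binary")
        cols = [0, 1, 3]
        direct = binary_match(binarize_dataset(d1.values[:, cols]),
                              binarize_dataset(d2.values[:, cols]))
        assert np.array_equal(res.match_1to2, direct.match_1to2)

    def test_unknown_mode_rejected(self, rng):
        d1, d2 = self._pair(rng)
        spec = SharedFeatureSpec(idx1=[0], idx2=[0])
        with pytest.raises(ValueError, match="mode"):
            build_matching(d1, d2, spec, mode="euclidean")
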