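from collections import Counter

import numpy as np
import pytest

from jsom import (
    MapGrid,
    SharedFeatureSpec,
    alignment_rmse,
    average_kl_divergence,
    label_transfer_accuracy,
    matching_score,
    node_purity_score,
)


def brute_mode(labels):
    """Most frequent label; ties -> lexicographically smallest."""
    counts = Counter(labels)
    best = max(counts.values())
    return sorted(l for l, c in counts.items() if c == best)[0]


def brute_purity(nodes1, labels1, nodes2, labels2, n_nodes):
    hits = 0
    for nodes, labels in ((nodes1, labels1), (nodes2, labels2)):
        for j in range(n_nodes):
            sub = [l for nd, l in zip(nodes, labels) if nd == j]
            if sub:
                hits += sum(l == brute_mode(sub) for l in sub)
    return hits / (len(nodes1) + len(nodes2))


def brute_matching(nodes1, labels1, nodes2, labels2, n_nodes):
    hits = 0
    for own_nodes, own_labels, other_nodes, other_labels in (
        (nodes1, labels1, nodes2, labels2),
        (nodes2, labels2, nodes1, labels1),
    ):
        for j in range(n_nodes):
            other = [l for nd, l in zip(other_nodes, other_labels) if nd == j]
            if not other:
                continue
            mode = brute_mode(other)
            hits += sum(l == mode for nd, l in zip(own_nodes, own_labels) if nd == j)
    return hits / (len(nodes1) + len(nodes2))


def random_instance(rng):
    n_nodes = int(rng.integers(2, 10))
    n1, n2 = int(rng.integers(1, 101)), int(rng.integers(1, 101))
    labels = ["A", "B", "C"]
    return (
        rng.integers(0, n_nodes, n1),
        rng.choice(labels, n1),
        rng.integers(0, n_nodes, n2),
        rng.choice(labels, n2),
        n_nodes,
    )


class TestPurityAndMatching:
    def test_single_label_is_perfect(self):
        nodes = np.array([0, 1, 2, 1])
        labels = np.array(["T"] * 4)
        assert node_purity_score(nodes, labels, nodes, labels, 4) == 1.0
        assert matching_score(nodes, labels, nodes, labels, 4) == 1.0

    def test_worked_two_node_example(self):
        # node 0: Labels1=[A,A,B], Labels2=[A,A]; node 1: Labels1=[B], Labels2=[B,B]
        nodes1 = np.array([0, 0, 0, 1])
        labels1 = np.array(["A", "A", "B", "B"])
        nodes2 = np.array([0, 0, 1, 1])
        labels2 = np.array(["A", "A", "B", "B"])
        assert node_purity_score(nodes1, labels1, nodes2, labels2, 2) == pytest.approx(0.875)
        assert matching_score(nodes1, labels1, nodes2, labels2, 2) == pytest.approx(0.875)

    def test_maximally_mixed_nodes_give_half(self):
        nodes = np.array([0, 0, 1, 1])
        labels = np.array(["A", "B", "A", "B"])
        assert node_purity_score(nodes, labels, nodes, labels, 2) == pytest.approx(0.5)

    def test_discordant_modes_give_zero_cross_matches(self):
        nodes = np.array([0, 0, 1, 1])
        labels1 = np.array(["A", "A", "B", "B"])
        labels2 = np.array(["B", "B", "A", "A"])
        assert matching_score(nodes, labels1, nodes, labels2, 2) == 0.0
        # while each dataset alone is perfectly pure
        assert node_purity_score(nodes, labels1, nodes, labels2, 2) == 1.0

    def test_one_sided_nodes_count_in_denominator(self):
        # dataset2 never occupies node 1, so its dataset1 cells can't match
        nodes1 = np.array([0, 1, 1])
        labels1 = np.array(["A", "A", "A"])
        nodes2 = np.array([0])
        labels2 = np.array(["A"])
        assert matching_score(nodes1, labels1, nodes2, labels2, 2) == pytest.approx(2 / 4)

    def test_relabeling_invariance(self, rng):
        nodes1, labels1, nodes2, labels2, n_nodes = random_instance(rng)
        bijection = {"A": "zeta", "B": "alpha", "C": "mid"}
        r1 = np.array([bijection[l] for l in labels1])
        r2 = np.array([bijection[l] for l in labels2])
        assert node_purity_score(nodes1, labels1, nodes2, labels2, n_nodes) == \
            pytest.approx(node_purity_score(nodes1, r1, nodes2, r2, n_nodes))

    def test_brute_force_oracle_equivalence(self, rng):
        for _ in range(50):
            inst = random_instance(rng)
            assert node_purity_score(*inst) == pytest.approx(brute_purity(*inst), abs=1e-12)
            assert matching_score(*inst) == pytest.approx(brute_matching(*inst), abs=1e-12)

    def test_unlabeled_cells_excluded_with_warning(self):
        nodes = np.array([0, 0, 1])
        labels = np.array(["A", "", "B"], dtype=object)
        clean = np.array(["A", "B"])
        with pytest.warns(UserWarning, match="unlabeled"):
            got = node_purity_score(nodes, labels, np.array([0, 1]), clean, 2)
        assert got == node_purity_score(np.array([0, 1]), clean, np.array([0, 1]), clean, 2)


class TestAlignmentRmse:
    def _maps(self, V1, V2):
        return MapGrid(m=1, n=V1.shape[0], V1=V1, V2=V2)

    def test_identical_blocks_zero(self, rng):
        V = rng.normal(size=(4, 3))
        spec = SharedFeatureSpec(idx1=[0, 1, 2], idx2=[0, 1, 2])
        assert alignment_rmse(self._maps(V, V.copy()), spec) == 0.0

    def test_constant_offset(self, rng):
        V = rng.normal(size=(4, 3))
        spec = SharedFeatureSpec(idx1=[0, 1], idx2=[0, 1])
        assert alignment_rmse(self._maps(V, V + 0.7), spec) == pytest.approx(0.7)

    def test_hand_computed(self):
        V1 = np.array([[1.0], [0.0]])
        V2 = np.array([[0.0], [3.0]])  # diffs 1 and -3
        spec = SharedFeatureSpec(idx1=[0], idx2=[0])
        assert alignment_rmse(self._maps(V1, V2), spec) == pytest.approx(np.sqrt(5))

    def test_out_of_range_spec(self, rng):
        V = rng.normal(size=(4, 2))
        with pytest.raises(ValueError):
            alignment_rmse(self._maps(V, V), SharedFeatureSpec(idx1=[5], idx2=[0]))


class TestAverageKl:
    def test_perfectly_mixed_is_zero(self):
        groups = np.array([0, 0, 1, 1])
        batch = np.array(["x", "y", "x", "y"])
        assert average_kl_divergence(groups, batch) == pytest.approx(0.0)

    def test_pure_groups_give_ln2(self):
        groups = np.array([0, 0, 1, 1])
        batch = np.array(["x", "x", "y", "y"])
        assert average_kl_divergence(groups, batch) == pytest.approx(np.log(2))

    def test_merging_identical_groups_invariant(self, rng):
        batch = rng.choice(["x", "y"], size=40)
        # two groups with identical local batch distributions
        batch[:20] = batch[20:40]
        groups = np.repeat([0, 1], 20)
        merged = np.zeros(40, dtype=int)
        assert average_kl_divergence(groups, batch) == pytest.approx(
            average_kl_divergence(merged, batch))

    def test_brute_force_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 100))
            groups = rng.integers(0, 5, size=n)
            batch = rng.choice(["p", "q", "r"], size=n)
            if len(set(batch)) < 2:
                continue
            # independent recomputation
            bs = sorted(set(batch))
            g = np.array([np.mean(batch == b) for b in bs])
            kls = []
            for grp in sorted(set(groups)):
                local = batch[groups == grp]
                kl = 0.0
                for b, gb in zip(bs, g):
                    pb = np.mean(local == b)
                    if pb > 0:
                        kl += pb * np.log(pb / gb)
                kls.append(kl)
            assert average_kl_divergence(groups, batch) == pytest.approx(
                np.mean(kls), abs=1e-12)

    def test_single_batch_rejected(self):
        with pytest.raises(ValueError):
            average_kl_divergence(np.array([0, 1]), np.array(["x", "x"]))


class TestLabelTransferAccuracy:
    def test_counting(self):
        truth = np.array(list("AAAABBBB"))
        pred = truth.copy()
        assert label_transfer_accuracy(pred, truth) == 1.0
        pred[0] = "B"
        assert label_transfer_accuracy(pred, truth) == pytest.approx(0.875)
        assert label_transfer_accuracy(np.array(["Z"] * 8), truth) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            label_transfer_accuracy(np.array(["A"]), np.array(["A", "B"]))
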