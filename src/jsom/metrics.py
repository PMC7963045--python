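"""Evaluation metrics: node purity, matching score, alignment RMSE,
average-KL batch mixing, and label-transfer accuracy.

Purity measures clustering quality per dataset (how label-homogeneous each
node is); the matching score measures alignment across datasets (whether a
cell's label agrees with the *other* dataset's majority at the same node).
Both divide by the total number of cells across both datasets.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import MapGrid, SharedFeatureSpec


def _node_modes(nodes: np.ndarray, labels: np.ndarray, n_nodes: int) -> np.ndarray:
    """Majority label per node (object array; None where unoccupied).

    Ties go to the lexicographically smallest label, matching the mode-map
    convention, so purity and matching stay deterministic.
    """
    modes = np.full(n_nodes, None, dtype=object)
    order = np.argsort(nodes, kind="stable")
    sorted_nodes = nodes[order]
    boundaries = np.flatnonzero(np.diff(sorted_nodes)) + 1
    for chunk in np.split(order, boundaries):
        node = nodes[chunk[0]]
        labs, counts = np.unique(labels[chunk].astype(str), return_counts=True)
        modes[node] = labs[np.argmax(counts)]  # np.unique sorts: ties -> smallest
    return modes


def _check_labels(nodes: np.ndarray, labels: np.ndarray, name: str):
    nodes = np.asarray(nodes, dtype=int)
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError(f"no labels provided for {name}")
    if nodes.shape != labels.shape:
        raise ValueError(f"{name}: nodes and labels must have equal length")
    mask = np.array([l is not None and str(l) != "" for l in labels.tolist()])
    if not mask.all():
        warnings.warn(
            f"{name}: excluding {int((~mask).sum())} unlabeled cell(s) from scoring",
            stacklevel=3,
        )
    return nodes[mask], labels[mask].astype(str)


def node_purity_score(
    nodes1: np.ndarray,
    labels1: np.ndarray,
    nodes2: np.ndarray,
    labels2: np.ndarray,
    n_nodes: int,
) -> float:
    """Fraction of cells whose label equals their node's own-dataset mode."""
    nodes1, labels1 = _check_labels(nodes1, labels1, "dataset1")
    nodes2, labels2 = _check_labels(nodes2, labels2, "dataset2")
    modes1 = _node_modes(nodes1, labels1, n_nodes)
    modes2 = _node_modes(nodes2, labels2, n_nodes)
    hits = int(np.sum(labels1 == modes1[nodes1].astype(str)))
    hits += int(np.sum(labels2 == modes2[nodes2].astype(str)))
    return hits / (nodes1.size + nodes2.size)


def matching_score(
    nodes1: np.ndarray,
    labels1: np.ndarray,
    nodes2: np.ndarray,
    labels2: np.ndarray,
    n_nodes: int,
) -> float:
    """Fraction of cells whose label equals the OTHER dataset's node mode.

    Cells on nodes the other dataset never occupies count as unmatched:
    they stay in the denominator but cannot contribute hits.
    """
    nodes1, labels1 = _check_labels(nodes1, labels1, "dataset1")
    nodes2, labels2 = _check_labels(nodes2, labels2, "dataset2")
    modes1 = _node_modes(nodes1, labels1, n_nodes)
    modes2 = _node_modes(nodes2, labels2, n_nodes)
    cross1 = modes2[nodes1]  # dataset1 cells vs dataset2's modes
    cross2 = modes1[nodes2]
    hits = sum(l == m for l, m in zip(labels1, cross1) if m is not None)
    hits += sum(l == m for l, m in zip(labels2, cross2) if m is not None)
    return hits / (nodes1.size + nodes2.size)


def alignment_rmse(maps: MapGrid, spec: SharedFeatureSpec) -> float:
    """RMSE between the two maps' codebooks over shared-feature pairs.

    Small values mean node ``j`` encodes the same shared-feature profile in
    both maps, i.e. the grids are quantitatively aligned.
    """
    if len(spec) == 0:
        raise ValueError("shared feature spec is empty")
    if max(spec.idx1) >= maps.V1.shape[1] or max(spec.idx2) >= maps.V2.shape[1]:
        raise ValueError("spec indices out of range for the trained codebooks")
    diff = maps.V1[:, spec.idx1] - maps.V2[:, spec.idx2]
    return float(np.sqrt(np.mean(diff**2)))


def average_kl_divergence(groups: np.ndarray, batch: np.ndarray) -> float:
    """Mean KL divergence (nats) of local batch distributions from global.

    ``groups`` assigns each cell to a node or cluster; for each non-empty
    group the batch-label distribution is compared with the global one.
    0 means perfectly mixed batches; larger values mean batch separation.
    """
    groups = np.asarray(groups)
    batch = np.asarray(batch).astype(str)
    if groups.shape != batch.shape:
        raise ValueError("groups and batch must have equal length")
    batches = np.unique(batch)
    if batches.size < 2:
        raise ValueError("need at least two batches")
    g = np.array([(batch == b).mean() for b in batches])
    kls = []
    for grp in np.unique(groups):
        local = batch[groups == grp]
        p = np.array([(local == b).mean() for b in batches])
        nz = p > 0
        kls.append(float(np.sum(p[nz] * np.log(p[nz] / g[nz]))))
    return float(np.mean(kls))


def label_transfer_accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of cells whose predicted label equals the true label."""
    predicted = np.asarray(predicted).astype(str)
    truth = np.asarray(truth).astype(str)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    return float(np.mean(predicted == truth))
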