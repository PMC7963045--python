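"""Post-training assignment, mode maps, node clustering and label transfer.

After training, every cell of each full dataset (not just the downsampled
training subset) is assigned to its nearest node. Nodes can then be merged
into superposition clusters by Ward clustering of the concatenated
codebooks ``[V1 | V2]``, and node-wise majority labels support mode maps
and reference-to-query label transfer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .core import Assignment, Dataset, MapGrid, NodeClustering, grid_distance_matrix

#: marker used in mode maps for nodes with no assigned cell
EMPTY = "__EMPTY__"


@dataclass
class ModeMap:
    """Per-node majority label plus the full node x label count table."""

    majority_label: list[str]
    counts: pd.DataFrame  # index: node, columns: labels


def _bmu_all(X: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Vectorised nearest-codebook assignment for every row of X."""
    if X.shape[1] != V.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match codebook {V.shape[1]}"
        )
    out = np.empty(X.shape[0], dtype=int)
    for start in range(0, X.shape[0], 4096):
        block = X[start : start + 4096]
        d2 = (
            (block**2).sum(axis=1)[:, None]
            - 2 * block @ V.T
            + (V**2).sum(axis=1)[None, :]
        )
        out[start : start + 4096] = np.argmin(d2, axis=1)
    return out


def assign_to_nodes(d1: Dataset, d2: Dataset, maps: MapGrid) -> Assignment:
    """Assign every cell of each dataset to its nearest node of its own map."""
    return Assignment(
        nodes1=_bmu_all(d1.values, maps.V1),
        nodes2=_bmu_all(d2.values, maps.V2),
    )


def mode_map(nodes: np.ndarray, labels: np.ndarray, n_nodes: int) -> ModeMap:
    """Majority label per node; ties go to the lexicographically smallest
    label and unoccupied nodes are marked EMPTY."""
    nodes = np.asarray(nodes, dtype=int)
    labels = np.asarray(labels)
    if nodes.shape != labels.shape:
        raise ValueError("nodes and labels must have the same length")
    uniq = sorted(str(l) for l in set(labels.tolist()))
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(n_nodes, name="node"), columns=uniq, dtype=int
    )
    for node, lab in zip(nodes, labels.astype(str)):
        counts.loc[node, lab] += 1
    majority = []
    for j in range(n_nodes):
        row = counts.loc[j]
        if row.sum() == 0:
            majority.append(EMPTY)
        else:
            # idxmax on the sorted columns returns the first (lexicographically
            # smallest) label among tied maxima
            majority.append(str(row.idxmax()))
    return ModeMap(majority_label=majority, counts=counts)


def superpose_cluster(maps: MapGrid, K: int | None = None) -> NodeClustering:
    """Ward clustering (Euclidean) of the concatenated codebooks [V1 | V2].

    The tree is cut at ``K`` clusters (default ``max(m, n)``) and cluster
    ids are relabeled 0..K-1 by the first node index at which each appears.
    """
    if K is None:
        K = max(maps.m, maps.n)
    n_nodes = maps.n_nodes
    if not 1 <= K <= n_nodes:
        raise ValueError(f"K must be in [1, {n_nodes}]")
    concat = np.hstack([maps.V1, maps.V2])
    if K == n_nodes:
        raw = np.arange(n_nodes)
    else:
        Z = linkage(concat, method="ward", metric="euclidean")
        raw = fcluster(Z, t=K, criterion="maxclust")
    # relabel by first occurrence for a deterministic, order-stable labeling
    relabel: dict[int, int] = {}
    out = np.empty(n_nodes, dtype=int)
    for j, c in enumerate(raw):
        if c not in relabel:
            relabel[c] = len(relabel)
        out[j] = relabel[c]
    return NodeClustering(cluster_of_node=out, K=len(relabel))


def composition_table(
    assignment: Assignment,
    clustering: NodeClustering,
    labels1: np.ndarray | None = None,
    labels2: np.ndarray | None = None,
) -> dict[str, pd.DataFrame]:
    """Percent of each label's cells landing in each superposition cluster.

    Returns one ``cluster x label`` table per labeled dataset; each label
    column sums to 100.
    """
    out: dict[str, pd.DataFrame] = {}
    for name, nodes, labels in (
        ("dataset1", assignment.nodes1, labels1),
        ("dataset2", assignment.nodes2, labels2),
    ):
        if labels is None:
            continue
        labels = np.asarray(labels).astype(str)
        if labels.shape[0] != nodes.shape[0]:
            raise ValueError(f"labels for {name} do not match its assignment")
        cluster_of_cell = clustering.cluster_of_node[nodes]
        tab = pd.crosstab(
            pd.Series(cluster_of_cell, name="cluster"),
            pd.Series(labels, name="label"),
        )
        tab = tab.reindex(index=range(clustering.K), fill_value=0)
        out[name] = 100.0 * tab / tab.sum(axis=0)
    if not out:
        raise ValueError("labels are required for at least one dataset")
    return out


def transfer_labels(
    ref_nodes: np.ndarray,
    ref_labels: np.ndarray,
    query_nodes: np.ndarray,
    n_nodes: int,
    m: int,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Predict query-cell labels from the reference's node-wise majorities.

    A query cell on a node the reference never occupied receives the label
    of the nearest (grid-distance) non-empty node, ties broken by the
    lowest node index, and is flagged as imputed.

    Returns ``(predicted_labels, imputed_flags)``.
    """
    ref_nodes = np.asarray(ref_nodes, dtype=int)
    if ref_nodes.size == 0:
        raise ValueError("reference assignment is empty")
    if m * n != n_nodes:
        raise ValueError("n_nodes must equal m * n")
    mm = mode_map(ref_nodes, np.asarray(ref_labels), n_nodes)
    majority = np.array(mm.majority_label, dtype=object)
    non_empty = np.flatnonzero(majority != EMPTY)
    if non_empty.size == 0:
        raise ValueError("every reference node is empty")
    grid_dist = grid_distance_matrix(m, n)
    node_label = majority.copy()
    imputed_node = np.zeros(n_nodes, dtype=bool)
    for j in np.flatnonzero(majority == EMPTY):
        # argmin over non-empty nodes; first minimum = lowest index
        nearest = non_empty[np.argmin(grid_dist[j, non_empty])]
        node_label[j] = majority[nearest]
        imputed_node[j] = True
    query_nodes = np.asarray(query_nodes, dtype=int)
    return node_label[query_nodes].astype(str), imputed_node[query_nodes]
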