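"""Shared domain types, grid geometry and best-matching-unit search.

The two coupled maps are rectangular ``m x n`` grids of nodes laid out in
row-major order: node ``j`` sits at grid coordinate ``(j // n, j % n)``.
Each node carries one codebook vector per dataset (``V1`` and ``V2``),
living in the two datasets' respective feature spaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


class DegenerateInputError(ValueError):
    """Raised when an input is too degenerate for the operation (e.g. a
    constant feature offered to a step-function binarizer)."""


@dataclass
class Dataset:
    """One modality's cell-by-feature matrix with names and optional metadata.

    Parameters
    ----------
    values
        Dense ``(n_cells, n_features)`` float array; no missing values.
    feature_names, cell_ids
        Unique names for columns and rows.
    labels, batch
        Optional per-cell categorical annotations.
    """

    values: np.ndarray
    feature_names: list[str]
    cell_ids: list[str]
    labels: Optional[np.ndarray] = None
    batch: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cell-by-feature matrix")
        if np.isnan(self.values).any():
            raise ValueError("values must not contain missing entries")
        n_cells, n_features = self.values.shape
        self.feature_names = [str(f) for f in self.feature_names]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.feature_names) != n_features:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {n_features} columns"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n_cells} rows")
        if len(set(self.feature_names)) != n_features:
            raise ValueError("feature names must be unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell ids must be unique")
        for attr in ("labels", "batch"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v)
                if v.shape != (n_cells,):
                    raise ValueError(f"{attr} must have one entry per cell")
                setattr(self, attr, v)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, idx: Sequence[int]) -> "Dataset":
        """Return a new Dataset restricted to the given cell rows."""
        idx = np.asarray(idx, dtype=int)
        return Dataset(
            values=self.values[idx],
            feature_names=list(self.feature_names),
            cell_ids=[self.cell_ids[i] for i in idx],
            labels=None if self.labels is None else self.labels[idx],
            batch=None if self.batch is None else self.batch[idx],
        )

    def subset_features(self, idx: Sequence[int]) -> "Dataset":
        """Return a new Dataset restricted to the given feature columns."""
        idx = np.asarray(idx, dtype=int)
        return Dataset(
            values=self.values[:, idx],
            feature_names=[self.feature_names[i] for i in idx],
            cell_ids=list(self.cell_ids),
            labels=self.labels,
            batch=self.batch,
        )


@dataclass
class SharedFeatureSpec:
    """Which columns of dataset1 correspond to which columns of dataset2.

    Position ``k`` of ``idx1`` pairs with position ``k`` of ``idx2``.
    """

    idx1: list[int]
    idx2: list[int]

    def __post_init__(self) -> None:
        self.idx1 = [int(i) for i in self.idx1]
        self.idx2 = [int(i) for i in self.idx2]
        if len(self.idx1) != len(self.idx2):
            raise ValueError("idx1 and idx2 must have the same length")
        if len(self.idx1) < 1:
            raise ValueError("at least one shared feature is required")

    def __len__(self) -> int:
        return len(self.idx1)

    def validate(self, d1: Dataset, d2: Dataset) -> None:
        if any(i < 0 or i >= d1.n_features for i in self.idx1):
            raise ValueError("idx1 contains out-of-range column indices")
        if any(i < 0 or i >= d2.n_features for i in self.idx2):
            raise ValueError("idx2 contains out-of-range column indices")

    @classmethod
    def from_names(
        cls, names1: Sequence[str], names2: Sequence[str], d1: Dataset, d2: Dataset
    ) -> "SharedFeatureSpec":
        """Resolve paired feature-name lists against the two datasets."""
        idx1 = [d1.feature_names.index(str(f)) for f in names1]
        idx2 = [d2.feature_names.index(str(f)) for f in names2]
        return cls(idx1=idx1, idx2=idx2)


@dataclass
class MatchingResult:
    """Per-cell cross-dataset best matches and matching weights delta.

    ``match_1to2[i]`` is the row of dataset2 most related to row ``i`` of
    dataset1; ``delta1[i]`` in [0, 1] is the strength of that match and
    scales the learning rate during joint updates.
    """

    match_1to2: np.ndarray
    match_2to1: np.ndarray
    delta1: np.ndarray
    delta2: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.match_1to2 = np.asarray(self.match_1to2, dtype=int)
        self.match_2to1 = np.asarray(self.match_2to1, dtype=int)
        self.delta1 = np.asarray(self.delta1, dtype=float)
        self.delta2 = np.asarray(self.delta2, dtype=float)
        if self.mode not in ("correlation", "binary"):
            raise ValueError(f"unknown matching mode {self.mode!r}")
        if self.match_1to2.shape != self.delta1.shape:
            raise ValueError("match_1to2 and delta1 must be the same length")
        if self.match_2to1.shape != self.delta2.shape:
            raise ValueError("match_2to1 and delta2 must be the same length")


@dataclass
class MapGrid:
    """The two coupled node grids with their codebook vector sets."""

    m: int
    n: int
    V1: np.ndarray
    V2: np.ndarray
    coords: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.V1 = np.asarray(self.V1, dtype=float)
        self.V2 = np.asarray(self.V2, dtype=float)
        n_nodes = self.m * self.n
        if self.V1.shape[0] != n_nodes or self.V2.shape[0] != n_nodes:
            raise ValueError("V1/V2 must have one row per grid node")
        self.coords = np.asarray(grid_coordinates(self.m, self.n), dtype=int)

    @property
    def n_nodes(self) -> int:
        return self.m * self.n


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    ``epsilon0`` defaults to ``ceil(2 * (max(m, n) - 1) / 3)`` — 6 for the
    default 10x10 grid — so the initial neighborhood spans roughly two
    thirds of the grid and shrinks to a single node by the final
    iterations.
    """

    m: int = 10
    n: int = 10
    epochs: int = 3
    alpha0: float = 0.9
    alpha_final: float = 0.01
    epsilon0: Optional[float] = None
    downsample_target: int = 10_000
    downsample_enabled: bool = True
    seed: int = 0
    allow_negative_delta: bool = False
    delta_in_independent: bool = True
    joint_updates: bool = True
    sampling: str = "permutation"  # or "iid"

    def __post_init__(self) -> None:
        if self.m < 2 or self.n < 2:
            raise ValueError("grid dimensions must be at least 2")
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")
        if not (0 < self.alpha_final < self.alpha0 <= 1):
            raise ValueError("need 0 < alpha_final < alpha0 <= 1")
        if self.epsilon0 is None:
            self.epsilon0 = default_epsilon0(self.m, self.n)
        if self.epsilon0 < 0:
            raise ValueError("epsilon0 must be non-negative")
        if self.sampling not in ("permutation", "iid"):
            raise ValueError("sampling must be 'permutation' or 'iid'")


def default_epsilon0(m: int, n: int) -> int:
    """Default initial neighborhood radius: ``ceil(2 * (max(m, n) - 1) / 3)``."""
    return math.ceil(2 * (max(m, n) - 1) / 3)


@dataclass
class Assignment:
    """Per-cell node index for each dataset after training."""

    nodes1: np.ndarray
    nodes2: np.ndarray

    def __post_init__(self) -> None:
        self.nodes1 = np.asarray(self.nodes1, dtype=int)
        self.nodes2 = np.asarray(self.nodes2, dtype=int)


@dataclass
class NodeClustering:
    """Cluster label per node from Ward clustering of concatenated codebooks."""

    cluster_of_node: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.cluster_of_node = np.asarray(self.cluster_of_node, dtype=int)
        present = np.unique(self.cluster_of_node)
        if len(present) != self.K or present.min() < 0 or present.max() >= self.K:
            raise ValueError("cluster labels must be exactly 0..K-1, all non-empty")


def grid_coordinates(m: int, n: int) -> list[tuple[int, int]]:
    """Row-major (row, col) coordinates of the ``m*n`` grid nodes."""
    if m < 1 or n < 1:
        raise ValueError("grid dimensions must be positive")
    return [(j // n, j % n) for j in range(m * n)]


def grid_distance_matrix(m: int, n: int) -> np.ndarray:
    """Pairwise Euclidean distances between node coordinates, (m*n, m*n)."""
    coords = np.asarray(grid_coordinates(m, n), dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def grid_neighborhood(center: int, epsilon: float, m: int, n: int) -> set[int]:
    """All nodes within Euclidean grid distance ``epsilon`` of ``center``.

    Always contains ``center`` itself (distance 0).
    """
    n_nodes = m * n
    if not 0 <= center < n_nodes:
        raise ValueError(f"center {center} out of range for a {m}x{n} grid")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    coords = np.asarray(grid_coordinates(m, n), dtype=float)
    d = np.sqrt(((coords - coords[center]) ** 2).sum(axis=1))
    return set(np.flatnonzero(d <= epsilon).tolist())


def find_bmu(x: np.ndarray, V: np.ndarray) -> int:
    """Index of the codebook row nearest to ``x`` (Euclidean).

    Ties are broken by the lowest node index so runs are reproducible.
    """
    x = np.asarray(x, dtype=float)
    V = np.asarray(V, dtype=float)
    if x.ndim != 1 or V.ndim != 2 or x.shape[0] != V.shape[1]:
        raise ValueError(
            f"dimension mismatch: x has {x.shape}, codebook has {V.shape}"
        )
    diff = V - x
    # argmin returns the first (lowest-index) minimiser, which is the tie rule
    return int(np.argmin((diff * diff).sum(axis=1)))
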