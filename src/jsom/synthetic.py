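"""Synthetic paired datasets with known cluster structure.

Emulates two single-cell datasets measuring the same underlying cell
populations through partially different technologies: both observe a set
of *shared* features (the same biological coordinates, but dataset2 sees
them through a per-feature affine distortion emulating cross-platform
scale/offset differences), and each additionally observes its own
*private* features the other lacks. Cluster identities are recorded so
alignment, scoring and label transfer can be validated without any
external downloads.

Values are continuous Gaussians: they stand in for data *after* the usual
variance-stabilising preprocessing, not for raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .core import Dataset, SharedFeatureSpec


@dataclass
class SimSpec:
    """Parameters of the paired-dataset generator.

    ``cluster_sep`` is the minimum distance between cluster centers in
    shared space, in units of ``noise_sd``; at 6 the clusters are well
    separated, near 2 they start to overlap. ``shared_distortion`` is the
    standard deviation of the per-feature affine perturbation
    ``a * x + b`` (a ~ 1 + N(0, s), b ~ N(0, s)) applied to dataset2's
    shared coordinates.
    """

    k_clusters: int = 5
    cells_per_cluster1: Union[int, list[int]] = 200
    cells_per_cluster2: Union[int, list[int]] = 200
    p_shared: int = 8
    p_private1: int = 4
    p_private2: int = 4
    cluster_sep: float = 6.0
    noise_sd: float = 1.0
    shared_distortion: float = 0.05
    missing_cluster_in_d2: Optional[int] = None
    seed: int = 0

    sizes1: list[int] = field(init=False)
    sizes2: list[int] = field(init=False)

    def __post_init__(self) -> None:
        if self.k_clusters < 2:
            raise ValueError("need at least two clusters")
        if self.cluster_sep <= 0 or self.noise_sd <= 0:
            raise ValueError("cluster_sep and noise_sd must be positive")

        def expand(c) -> list[int]:
            sizes = [c] * self.k_clusters if isinstance(c, int) else list(c)
            if len(sizes) != self.k_clusters or any(s < 1 for s in sizes):
                raise ValueError("need one positive cell count per cluster")
            return sizes

        self.sizes1 = expand(self.cells_per_cluster1)
        self.sizes2 = expand(self.cells_per_cluster2)
        if self.missing_cluster_in_d2 is not None and not (
            0 <= self.missing_cluster_in_d2 < self.k_clusters
        ):
            raise ValueError("missing_cluster_in_d2 out of range")


def _draw_centers(
    rng: np.random.Generator, k: int, p: int, min_sep: float, max_tries: int = 200
) -> np.ndarray:
    """Rejection-sample k centers with pairwise separation >= min_sep."""
    scale = max(min_sep, 1.0)
    for _ in range(max_tries):
        centers = rng.normal(0.0, scale, size=(k, p))
        d = np.sqrt(((centers[:, None] - centers[None]) ** 2).sum(-1))
        if (d[np.triu_indices(k, 1)] >= min_sep).all():
            return centers
    raise RuntimeError(
        "could not place well-separated cluster centers; lower k_clusters "
        "or cluster_sep"
    )


def generate_paired(
    spec: SimSpec,
) -> tuple[Dataset, Dataset, np.ndarray, np.ndarray]:
    """Draw the two paired datasets.

    Returns ``(dataset1, dataset2, labels1, labels2)``; the labels are the
    true cluster names ``C0..C{k-1}`` and are also attached to each
    Dataset. The shared features occupy the first ``p_shared`` columns of
    both datasets, so ``shared_spec(spec)`` describes the correspondence.
    """
    rng = np.random.default_rng(spec.seed)
    k, p = spec.k_clusters, spec.p_shared
    shared_centers = _draw_centers(rng, k, p, spec.cluster_sep * spec.noise_sd)
    priv1_centers = rng.normal(0.0, spec.cluster_sep * spec.noise_sd / 2, (k, spec.p_private1))
    priv2_centers = rng.normal(0.0, spec.cluster_sep * spec.noise_sd / 2, (k, spec.p_private2))
    # cross-technology distortion of dataset2's view of the shared features
    a = 1.0 + rng.normal(0.0, spec.shared_distortion, p)
    b = rng.normal(0.0, spec.shared_distortion, p)

    def build(
        sizes: list[int],
        priv_centers: np.ndarray,
        distort: bool,
        skip: Optional[int],
        tag: str,
    ) -> tuple[np.ndarray, np.ndarray]:
        rows, labs = [], []
        for c in range(k):
            if skip is not None and c == skip:
                continue
            n_c = sizes[c]
            shared = shared_centers[c] + rng.normal(0, spec.noise_sd, (n_c, p))
            if distort:
                shared = a * shared + b
            private = priv_centers[c] + rng.normal(
                0, spec.noise_sd, (n_c, priv_centers.shape[1])
            )
            rows.append(np.hstack([shared, private]))
            labs.extend([f"C{c}"] * n_c)
        return np.vstack(rows), np.array(labs)

    X1, labels1 = build(spec.sizes1, priv1_centers, False, None, "d1")
    X2, labels2 = build(
        spec.sizes2, priv2_centers, True, spec.missing_cluster_in_d2, "d2"
    )

    def to_dataset(X, labels, which: int, p_priv: int) -> Dataset:
        features = [f"S{j}" for j in range(p)] + [
            f"P{which}_{j}" for j in range(p_priv)
        ]
        cells = [f"d{which}_cell{i}" for i in range(X.shape[0])]
        return Dataset(
            values=X,
            feature_names=features,
            cell_ids=cells,
            labels=labels,
            batch=np.array([f"batch{which}"] * X.shape[0]),
        )

    d1 = to_dataset(X1, labels1, 1, spec.p_private1)
    d2 = to_dataset(X2, labels2, 2, spec.p_private2)
    return d1, d2, labels1, labels2


def shared_spec(spec: SimSpec) -> SharedFeatureSpec:
    """Shared-feature correspondence for datasets from ``generate_paired``."""
    idx = list(range(spec.p_shared))
    return SharedFeatureSpec(idx1=idx, idx2=idx)
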