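"""Joint training of the two coupled self-organizing maps.

Each iteration draws one cell from each dataset and performs two kinds of
update:

* **independent** — the drawn cell pulls its own map's best-matching unit
  (BMU) and the nodes within the current neighborhood radius toward it,
  scaled by the learning rate and the cell's matching weight delta;
* **joint** — the cell's matched partner from the *other* dataset pulls the
  *other* map at the very same node set, again scaled by delta.

The joint step is what couples the two maps: wherever dataset1 places a
population, its matched dataset2 cells drag the second map's codebooks to
the same grid region, so related clusters end up on overlapping nodes.

The learning rate ``alpha`` decays linearly from ``alpha0`` to
``alpha_final`` and the neighborhood radius ``epsilon`` decays linearly
from ``epsilon0`` to 0 over the full run; once ``epsilon`` drops below 1
only the BMU itself is updated.
"""

from __future__ import annotations

import numpy as np

from .core import Dataset, MapGrid, MatchingResult, TrainConfig, grid_distance_matrix


def initialize_maps(cfg: TrainConfig, d1: Dataset, d2: Dataset) -> MapGrid:
    """Seeded random initialization of both codebook sets.

    Every component is drawn uniformly within its feature's observed
    [min, max] range, so initial codebooks start inside the data cloud.
    """
    if d1.n_cells == 0 or d2.n_cells == 0:
        raise ValueError("datasets must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    n_nodes = cfg.m * cfg.n
    maps = []
    for d in (d1, d2):
        lo = d.values.min(axis=0)
        hi = d.values.max(axis=0)
        maps.append(lo + (hi - lo) * rng.random((n_nodes, d.n_features)))
    return MapGrid(m=cfg.m, n=cfg.n, V1=maps[0], V2=maps[1])


def schedule(cfg: TrainConfig, t: int, T: int) -> tuple[float, float]:
    """Learning rate and neighborhood radius at iteration ``t`` of ``T``.

    Both ramps are affine in ``t / (T - 1)``: alpha from ``alpha0`` down to
    ``alpha_final``, epsilon from ``epsilon0`` down to 0.
    """
    if T < 2:
        return cfg.alpha0, float(cfg.epsilon0)
    if not 0 <= t < T:
        raise ValueError(f"iteration {t} outside [0, {T})")
    frac = t / (T - 1)
    alpha_t = cfg.alpha0 + (cfg.alpha_final - cfg.alpha0) * frac
    epsilon_t = cfg.epsilon0 * (1.0 - frac)
    return max(alpha_t, cfg.alpha_final), max(epsilon_t, 0.0)


def apply_update(
    V: np.ndarray,
    nodes: np.ndarray,
    x: np.ndarray,
    delta: float,
    alpha: float,
) -> np.ndarray:
    """In-place codebook update ``V_j <- V_j + delta * alpha * (x - V_j)``
    for every node ``j`` in ``nodes``; returns ``V``.

    Since ``delta * alpha`` is in [0, 1] each update is a convex step
    toward ``x``, so codebooks can never leave the data's bounding box.
    Computed as ``(1 - delta*alpha) * V_j + delta*alpha * x``, which is the
    same formula arranged so that a full step (``delta*alpha == 1``) lands
    exactly on ``x``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] != V.shape[1]:
        raise ValueError("datapoint dimension does not match the codebook")
    eta = delta * alpha
    V[nodes] = (1.0 - eta) * V[nodes] + eta * x
    return V


def _draw_order(n: int, T: int, rng: np.random.Generator, sampling: str) -> np.ndarray:
    """Sequence of T row indices: cycled fresh permutations, or i.i.d."""
    if sampling == "iid":
        return rng.integers(0, n, size=T)
    reps = -(-T // n)  # ceil
    chunks = [rng.permutation(n) for _ in range(reps)]
    return np.concatenate(chunks)[:T]


def _bmu_fast(x: np.ndarray, V: np.ndarray) -> int:
    # hot loop: squared distances, plain row-wise reduction (codebook rows
    # that have converged to near-equality must compare reproducibly)
    diff = V - x
    return int(np.argmin((diff * diff).sum(axis=1)))


def train_jsom(
    d1: Dataset,
    d2: Dataset,
    match: MatchingResult,
    cfg: TrainConfig,
    maps: MapGrid | None = None,
    order1: np.ndarray | None = None,
    order2: np.ndarray | None = None,
) -> MapGrid:
    """Run the full alternating independent/joint training loop.

    ``match`` must have been computed on exactly the rows of ``d1``/``d2``
    passed here (downsample first, then match, then train). The total
    iteration count is ``epochs * max(n1, n2)``; the smaller dataset's
    permutation is simply recycled.

    ``maps``, ``order1`` and ``order2`` override the seeded initialization
    and draw sequences; they exist for reproducibility studies and for
    testing against reference implementations.
    """
    n1, n2 = d1.n_cells, d2.n_cells
    if match.match_1to2.shape[0] != n1 or match.match_2to1.shape[0] != n2:
        raise ValueError(
            "matching length does not match the training rows; compute the "
            "matching on the same (possibly downsampled) rows used to train"
        )
    if maps is None:
        maps = initialize_maps(cfg, d1, d2)
    V1 = maps.V1.copy()
    V2 = maps.V2.copy()
    T = cfg.epochs * max(n1, n2)

    seq = np.random.SeedSequence(cfg.seed).spawn(3)
    if order1 is None:
        order1 = _draw_order(n1, T, np.random.default_rng(seq[1]), cfg.sampling)
    if order2 is None:
        order2 = _draw_order(n2, T, np.random.default_rng(seq[2]), cfg.sampling)

    X1, X2 = d1.values, d2.values
    grid_dist = grid_distance_matrix(cfg.m, cfg.n)
    delta1 = match.delta1 if cfg.delta_in_independent else np.ones(n1)
    delta2 = match.delta2 if cfg.delta_in_independent else np.ones(n2)

    for t in range(T):
        alpha_t, eps_t = schedule(cfg, t, T)
        i1, i2 = order1[t], order2[t]
        x1, x2 = X1[i1], X2[i2]

        b1 = _bmu_fast(x1, V1)
        nodes1 = np.flatnonzero(grid_dist[b1] <= eps_t)
        eta = delta1[i1] * alpha_t
        V1[nodes1] = (1.0 - eta) * V1[nodes1] + eta * x1

        b2 = _bmu_fast(x2, V2)
        nodes2 = np.flatnonzero(grid_dist[b2] <= eps_t)
        eta = delta2[i2] * alpha_t
        V2[nodes2] = (1.0 - eta) * V2[nodes2] + eta * x2

        if cfg.joint_updates:
            # matched partner updates the OTHER map at the SAME node set
            eta = match.delta1[i1] * alpha_t
            V2[nodes1] = (1.0 - eta) * V2[nodes1] + eta * X2[match.match_1to2[i1]]
            eta = match.delta2[i2] * alpha_t
            V1[nodes2] = (1.0 - eta) * V1[nodes2] + eta * X1[match.match_2to1[i2]]

    return MapGrid(m=cfg.m, n=cfg.n, V1=V1, V2=V2)


def quantization_error(values: np.ndarray, V: np.ndarray) -> float:
    """Mean Euclidean distance of datapoints to their best-matching unit."""
    X = np.asarray(values, dtype=float)
    # blocked to bound the n_cells x n_nodes distance matrix
    total = 0.0
    for start in range(0, X.shape[0], 4096):
        block = X[start : start + 4096]
        d2 = (
            (block**2).sum(axis=1)[:, None]
            - 2 * block @ V.T
            + (V**2).sum(axis=1)[None, :]
        )
        total += np.sqrt(np.maximum(d2, 0.0)).min(axis=1).sum()
    return float(total / X.shape[0])
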