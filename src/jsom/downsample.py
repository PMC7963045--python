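"""Density-dependent downsampling to the training cap.

Keeping every cell of a 100k-cell dataset would swamp the maps with the
abundant populations, so datasets above the cap are subsampled with a
keep-probability inversely proportional to local density (the SPADE-style
scheme): abundant populations are thinned hard while rare ones are kept
nearly intact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors


@dataclass
class DensityProfile:
    """Per-cell neighbor counts within a fixed kernel radius."""

    local_density: np.ndarray
    kernel_radius: float

    def __post_init__(self) -> None:
        self.local_density = np.asarray(self.local_density, dtype=int)
        if (self.local_density < 1).any():
            raise ValueError("each cell counts itself: density >= 1")


def local_density(values: np.ndarray, radius_multiplier: float = 5.0) -> DensityProfile:
    """Count, for every cell, the cells within the kernel radius (inclusive,
    counting itself).

    The radius is ``radius_multiplier`` times the median nearest-neighbor
    distance, so "local" scales with the data's own granularity.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least two cells to define local density")
    if radius_multiplier <= 0:
        raise ValueError("radius_multiplier must be positive")
    nn = NearestNeighbors(n_neighbors=2).fit(X)
    dist, _ = nn.kneighbors(X)
    median_nn = float(np.median(dist[:, 1]))
    if median_nn == 0:
        warnings.warn(
            "median nearest-neighbor distance is 0 (many duplicate cells); "
            "densities count exact duplicates only",
            stacklevel=2,
        )
    radius = radius_multiplier * median_nn
    counts = np.array(
        [len(ind) for ind in nn.radius_neighbors(X, radius=radius, return_distance=False)]
    )
    return DensityProfile(local_density=counts, kernel_radius=radius)


def _target_density(densities: np.ndarray, target_size: int) -> float:
    """Largest TD with sum(min(1, TD / d_i)) <= target_size, by bisection."""
    lo, hi = 0.0, float(densities.max())
    if np.sum(np.minimum(1.0, hi / densities)) <= target_size:
        return hi
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if np.sum(np.minimum(1.0, mid / densities)) <= target_size:
            lo = mid
        else:
            hi = mid
    return lo


def density_downsample(
    values: np.ndarray,
    target_size: int,
    outlier_percentile: float = 1.0,
    seed: int = 0,
    radius_multiplier: float = 5.0,
) -> np.ndarray:
    """Return the kept cell indices after density-dependent downsampling.

    Cells below the ``outlier_percentile`` of local density are discarded as
    outliers; the rest are kept with probability ``min(1, TD / density)``
    where the target density TD is the largest value for which the expected
    kept count stays within ``target_size``.
    """
    X = np.asarray(values, dtype=float)
    n = X.shape[0]
    if target_size < 1:
        raise ValueError("target_size must be at least 1")
    if not 0 <= outlier_percentile < 50:
        raise ValueError("outlier_percentile must be in [0, 50)")
    if n <= target_size:
        return np.arange(n)
    profile = local_density(X, radius_multiplier=radius_multiplier)
    dens = profile.local_density.astype(float)
    candidates = np.arange(n)
    if outlier_percentile > 0:
        cutoff = np.percentile(dens, outlier_percentile)
        keep_mask = dens >= cutoff  # strictly-below cells are outliers
        candidates = candidates[keep_mask]
        dens = dens[keep_mask]
    td = _target_density(dens, target_size)
    rng = np.random.default_rng(seed)
    p_keep = np.minimum(1.0, td / dens)
    kept = candidates[rng.random(candidates.size) < p_keep]
    return kept


def uniform_downsample(n_cells: int, target_size: int, seed: int = 0) -> np.ndarray:
    """Plain uniform random subsample to the cap (sorted indices)."""
    if n_cells <= target_size:
        return np.arange(n_cells)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_cells, size=target_size, replace=False))
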