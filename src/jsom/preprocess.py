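"""Preprocessing: variance-stabilising transforms, cell QC filters,
highly-variable-gene selection and PCA reduction.

Cytometry inputs get an inverse-hyperbolic-sine transform (cofactor 150
for flow, 5 for mass cytometry, following common practice); scRNA-seq
counts get log(1 + x). High-dimensional inputs should be reduced to a few
tens of PCA components before map training.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .core import Dataset


def arcsinh_transform(d: Dataset, cofactor: float = 150.0) -> Dataset:
    """Return a Dataset with every value x replaced by asinh(x / cofactor)."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return Dataset(
        values=np.arcsinh(d.values / cofactor),
        feature_names=list(d.feature_names),
        cell_ids=list(d.cell_ids),
        labels=d.labels,
        batch=d.batch,
    )


def log1p_transform(d: Dataset) -> Dataset:
    """Return a Dataset with every value x replaced by ln(1 + x)."""
    if (d.values < 0).any():
        raise ValueError("log1p requires non-negative values")
    return Dataset(
        values=np.log1p(d.values),
        feature_names=list(d.feature_names),
        cell_ids=list(d.cell_ids),
        labels=d.labels,
        batch=d.batch,
    )


def filter_cells(
    d: Dataset,
    mito_prefix: str = "MT-",
    min_genes: int = 200,
    max_genes: int = 2500,
    max_mito_frac: float = 0.05,
) -> Dataset:
    """Quality-control filter on raw counts.

    Keeps cells whose number of detected features (count > 0) lies in
    ``[min_genes, max_genes]`` inclusive and whose fraction of counts in
    mitochondrial features (name starts with ``mito_prefix``) is at most
    ``max_mito_frac``. Boundaries are kept: only strictly "over" /
    "less than" / "greater than" cells are excluded. Cells with zero total
    counts are excluded with a warning (their mitochondrial fraction is
    undefined).
    """
    X = d.values
    detected = (X > 0).sum(axis=1)
    total = X.sum(axis=1)
    mito_cols = [i for i, f in enumerate(d.feature_names) if f.startswith(mito_prefix)]
    mito = X[:, mito_cols].sum(axis=1) if mito_cols else np.zeros(d.n_cells)
    zero_total = total == 0
    if zero_total.any():
        warnings.warn(
            f"excluding {int(zero_total.sum())} cell(s) with zero total counts",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(zero_total, np.inf, mito / np.where(zero_total, 1, total))
    keep = (
        (detected >= min_genes)
        & (detected <= max_genes)
        & (mito_frac <= max_mito_frac)
        & ~zero_total
    )
    return d.subset_cells(np.flatnonzero(keep))


def select_hvg(d: Dataset, n_top: int) -> list[int]:
    """Indices of the ``n_top`` features with the largest variance-to-mean
    dispersion (population variance / mean; mean-zero features score 0).

    Ties are broken by the lowest feature index.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > d.n_features:
        raise ValueError("n_top exceeds the number of features")
    mean = d.values.mean(axis=0)
    var = d.values.var(axis=0)  # population variance (ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(mean > 0, var / np.where(mean > 0, mean, 1), 0.0)
    # stable sort on negated dispersion keeps the lowest index first on ties
    order = np.argsort(-dispersion, kind="stable")
    return sorted(order[:n_top].tolist())


def pca_reduce(d: Dataset, n_components: int, scale: bool = False) -> Dataset:
    """Project onto the top principal components.

    Features are centered (and unit-scaled when ``scale`` is set) before the
    decomposition; the returned Dataset has features PC1..PCk and the same
    cells, labels and batches.
    """
    if n_components > min(d.n_cells, d.n_features):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_cells, n_features)"
        )
    X = d.values
    if scale:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return Dataset(
        values=scores,
        feature_names=[f"PC{k + 1}" for k in range(n_components)],
        cell_ids=list(d.cell_ids),
        labels=d.labels,
        batch=d.batch,
    )


def standard_scrna_pipeline(
    d: Dataset,
    mito_prefix: str = "MT-",
    n_hvg: int = 2000,
    n_components: int = 20,
) -> Dataset:
    """Convenience chain: QC filter -> log1p -> HVG -> PCA."""
    d = filter_cells(d, mito_prefix=mito_prefix)
    d = log1p_transform(d)
    hvg: Sequence[int] = select_hvg(d, min(n_hvg, d.n_features))
    d = d.subset_features(hvg)
    return pca_reduce(d, n_components)
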