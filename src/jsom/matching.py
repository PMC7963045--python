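"""Datapoint-to-datapoint matching across the two datasets.

The matching is computed on the shared-feature submatrices only. In
``correlation`` mode each cell is matched to the cell of the other dataset
with the highest Pearson correlation across shared features; the matching
weight ``delta`` is that correlation (clamped to [0, 1] by default). In
``binary`` mode the shared features are first binarized with a two-step
(StepMiner-style) fit and cells are matched by the fraction of features on
which the binary calls agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Dataset, DegenerateInputError, MatchingResult, SharedFeatureSpec

#: rows per block when forming the nA x nB score matrix, to bound memory
_BLOCK_ROWS = 2048


@dataclass
class BinaryView:
    """Binarized shared-feature matrix with the per-feature thresholds.

    ``kept`` records which input columns survived binarization (constant
    columns cannot be thresholded and are dropped), so callers can drop
    the paired columns in the other dataset too.
    """

    bits: np.ndarray
    thresholds: np.ndarray
    kept: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.kept is None:
            self.kept = np.arange(self.bits.shape[1])
        self.kept = np.asarray(self.kept, dtype=int)
        if self.bits.ndim != 2 or self.thresholds.shape != (self.bits.shape[1],):
            raise ValueError("need one threshold per binarized column")
        if self.kept.shape != (self.bits.shape[1],):
            raise ValueError("kept must list one input column per bits column")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be 0/1")


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and unit-scale each row; flag constant (zero-variance) rows."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    Z = X - mu
    norm = np.sqrt((Z**2).sum(axis=1, keepdims=True))
    constant = norm[:, 0] == 0
    norm[constant] = 1.0
    return Z / norm, constant


def _argmax_match(
    ZA: np.ndarray, ZB: np.ndarray, clamp: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Row-blocked argmax of the correlation score matrix ZA @ ZB.T."""
    nA = ZA.shape[0]
    match = np.empty(nA, dtype=int)
    delta = np.empty(nA, dtype=float)
    for start in range(0, nA, _BLOCK_ROWS):
        block = ZA[start : start + _BLOCK_ROWS] @ ZB.T
        idx = np.argmax(block, axis=1)  # first maximiser = lowest index
        match[start : start + _BLOCK_ROWS] = idx
        best = block[np.arange(block.shape[0]), idx]
        delta[start : start + _BLOCK_ROWS] = np.maximum(best, 0) if clamp else best
    return match, delta


def pearson_match(
    sharedA: np.ndarray,
    sharedB: np.ndarray,
    allow_negative_delta: bool = False,
) -> MatchingResult:
    """Mutual best-correlation matching between two shared-feature matrices.

    A constant row has no defined correlation; it is matched to index 0
    with weight 0 and a warning.
    """
    sharedA = np.asarray(sharedA, dtype=float)
    sharedB = np.asarray(sharedB, dtype=float)
    if sharedA.ndim != 2 or sharedB.ndim != 2 or sharedA.shape[1] != sharedB.shape[1]:
        raise ValueError("shared matrices must have the same number of columns")
    p = sharedA.shape[1]
    if p < 3:
        warnings.warn(
            f"only {p} shared feature(s); correlations on < 3 points are unstable",
            stacklevel=2,
        )
    ZA, constA = _standardize_rows(sharedA)
    ZB, constB = _standardize_rows(sharedB)
    clamp = not allow_negative_delta
    match12, delta1 = _argmax_match(ZA, ZB, clamp)
    match21, delta2 = _argmax_match(ZB, ZA, clamp)
    for const, match, delta, name in (
        (constA, match12, delta1, "dataset1"),
        (constB, match21, delta2, "dataset2"),
    ):
        if const.any():
            warnings.warn(
                f"{int(const.sum())} constant row(s) in {name}: "
                "correlation undefined, matching weight set to 0",
                stacklevel=2,
            )
            match[const] = 0
            delta[const] = 0.0
    return MatchingResult(
        match_1to2=match12,
        match_2to1=match21,
        delta1=delta1,
        delta2=delta2,
        mode="correlation",
    )


def stepminer_threshold(values: np.ndarray) -> tuple[float, int]:
    """Fit a rising two-segment step to the sorted values.

    Over every split ``s`` in ``[1, len - 1]`` the two segments are fitted
    by their means and the split minimising total squared error is chosen
    (ties broken by the smallest ``s``). The threshold is the midpoint of
    the two segment means.

    Uses prefix sums, O(len) after sorting.
    """
    v = np.sort(np.asarray(values, dtype=float))
    L = v.size
    if L < 2:
        raise ValueError("need at least two values to fit a step")
    if v[0] == v[-1]:
        raise DegenerateInputError("all values identical: no step exists")
    csum = np.concatenate(([0.0], np.cumsum(v)))
    csq = np.concatenate(([0.0], np.cumsum(v**2)))
    s = np.arange(1, L)
    left_n, right_n = s, L - s
    left_sum, right_sum = csum[s], csum[L] - csum[s]
    # SSE of a segment fitted by its mean: sum(x^2) - (sum x)^2 / n
    sse = (
        csq[s]
        - left_sum**2 / left_n
        + (csq[L] - csq[s])
        - right_sum**2 / right_n
    )
    best = int(np.argmin(sse))  # first minimum = smallest split
    split = int(s[best])
    threshold = 0.5 * (left_sum[best] / left_n[best] + right_sum[best] / right_n[best])
    return float(threshold), split


def binarize_dataset(shared: np.ndarray) -> BinaryView:
    """Binarize every column at its StepMiner threshold (value > threshold).

    Constant columns cannot be thresholded and are dropped with a warning;
    ``kept`` records the surviving input column indices so the caller can
    drop the paired columns in the other dataset too.
    """
    shared = np.asarray(shared, dtype=float)
    n_cols = shared.shape[1]
    thresholds = []
    keep = []
    for k in range(n_cols):
        try:
            thr, _ = stepminer_threshold(shared[:, k])
            thresholds.append(thr)
            keep.append(k)
        except DegenerateInputError:
            warnings.warn(
                f"shared column {k} is constant and was dropped from binarization",
                stacklevel=2,
            )
    if not keep:
        raise DegenerateInputError("every shared column is constant")
    thresholds = np.array(thresholds)
    bits = (shared[:, keep] > thresholds).astype(np.int8)
    return BinaryView(bits=bits, thresholds=thresholds, kept=np.array(keep))


def binary_match(binA: BinaryView, binB: BinaryView) -> MatchingResult:
    """Match cells by the fraction of binarized features that agree.

    ``delta`` is the number of co-occurring (both positive or both
    negative) features divided by the number of features.
    """
    if binA.bits.shape[1] != binB.bits.shape[1]:
        raise ValueError("binary views must have the same number of columns")
    p = binA.bits.shape[1]
    # agreement count = p - Hamming distance; signed +/-1 trick keeps it a
    # single blocked matrix product
    SA = (2 * binA.bits - 1).astype(float)
    SB = (2 * binB.bits - 1).astype(float)

    def one_direction(S1: np.ndarray, S2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n1 = S1.shape[0]
        match = np.empty(n1, dtype=int)
        delta = np.empty(n1, dtype=float)
        for start in range(0, n1, _BLOCK_ROWS):
            agree = (S1[start : start + _BLOCK_ROWS] @ S2.T + p) / 2
            idx = np.argmax(agree, axis=1)
            match[start : start + _BLOCK_ROWS] = idx
            delta[start : start + _BLOCK_ROWS] = agree[np.arange(len(idx)), idx] / p
        return match, delta

    match12, delta1 = one_direction(SA, SB)
    match21, delta2 = one_direction(SB, SA)
    return MatchingResult(
        match_1to2=match12,
        match_2to1=match21,
        delta1=delta1,
        delta2=delta2,
        mode="binary",
    )


def build_matching(
    d1: Dataset,
    d2: Dataset,
    spec: SharedFeatureSpec,
    mode: str = "correlation",
    allow_negative_delta: bool = False,
) -> MatchingResult:
    """Extract the shared-feature submatrices and dispatch to the matcher."""
    spec.validate(d1, d2)
    sharedA = d1.values[:, spec.idx1]
    sharedB = d2.values[:, spec.idx2]
    if mode == "correlation":
        return pearson_match(sharedA, sharedB, allow_negative_delta)
    if mode == "binary":
        # a column constant in either dataset must be dropped from BOTH to
        # keep positional correspondence
        const = np.array(
            [
                sharedA[:, k].min() == sharedA[:, k].max()
                or sharedB[:, k].min() == sharedB[:, k].max()
                for k in range(len(spec))
            ]
        )
        if const.any():
            warnings.warn(
                f"dropping {int(const.sum())} shared column(s) constant in at "
                "least one dataset",
                stacklevel=2,
            )
            sharedA = sharedA[:, ~const]
            sharedB = sharedB[:, ~const]
            if sharedA.shape[1] == 0:
                raise DegenerateInputError("no usable shared columns remain")
        return binary_match(binarize_dataset(sharedA), binarize_dataset(sharedB))
    raise ValueError(f"unknown matching mode {mode!r}")
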