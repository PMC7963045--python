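"""Readers and writers: dense CSV/TSV matrices, MatrixMarket triplets with
feature/barcode companions, and the trained-map container.

Matrices are oriented cells x features on disk (header row = feature
names, first column = cell ids); a ``transpose`` flag flips files stored
the other way. Trained maps are saved as a single JSON document — Python's
JSON float round-trip is exact, so save/load is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
from scipy.io import mmread

from .core import Dataset, MapGrid

MAPS_FORMAT_MAJOR = 1


def read_matrix(
    path: str | Path,
    fmt: Optional[str] = None,
    transpose: bool = False,
    label_column: Optional[str] = None,
    batch_column: Optional[str] = None,
    features_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> Dataset:
    """Read a cell-by-feature matrix into a Dataset.

    ``fmt`` is inferred from the suffix when omitted. For ``mtx`` the
    companion ``features_path`` / ``barcodes_path`` name files are
    required (one name per line; MTX rows are features, columns cells, as
    written by common single-cell pipelines).
    """
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx", ".txt": "tsv"}.get(
            path.suffix.lower()
        )
        if fmt is None:
            raise ValueError(f"cannot infer format from {path.name!r}")
    if fmt == "mtx":
        if features_path is None or barcodes_path is None:
            raise ValueError("mtx input needs features and barcodes companion files")
        mat = np.asarray(mmread(str(path)).todense(), dtype=float)
        features = Path(features_path).read_text().split()
        barcodes = Path(barcodes_path).read_text().split()
        values = mat.T  # rows are features in MTX convention
        if transpose:
            values = values.T
            features, barcodes = barcodes, features
        return Dataset(values=values, feature_names=features, cell_ids=barcodes)

    sep = "," if fmt == "csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    labels = batch = None
    if label_column is not None and label_column in df.columns:
        labels = df.pop(label_column).to_numpy()
    if batch_column is not None and batch_column in df.columns:
        batch = df.pop(batch_column).to_numpy()
    if transpose:
        df = df.T
    bad = df.columns[~df.dtypes.map(lambda t: np.issubdtype(t, np.number))]
    if len(bad):
        raise ValueError(f"non-numeric column(s) in {path.name}: {list(bad)}")
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()[:5]
        raise ValueError(f"missing/ragged values in {path.name} at rows {rows}")
    return Dataset(
        values=df.to_numpy(dtype=float),
        feature_names=[str(c) for c in df.columns],
        cell_ids=[str(i) for i in df.index],
        labels=labels,
        batch=batch,
    )


def write_matrix(d: Dataset, path: str | Path, fmt: str = "csv") -> None:
    """Write a Dataset as dense CSV/TSV (6 significant digits)."""
    df = pd.DataFrame(d.values, index=d.cell_ids, columns=d.feature_names)
    if d.labels is not None:
        df["label"] = d.labels
    if d.batch is not None:
        df["batch"] = d.batch
    df.to_csv(path, sep="," if fmt == "csv" else "\t", float_format="%.6g")


def save_maps(maps: MapGrid, path: str | Path, config: dict[str, Any] | None = None) -> None:
    """Serialise a trained MapGrid (plus provenance) losslessly to JSON."""
    from . import __version__

    doc = {
        "format_major": MAPS_FORMAT_MAJOR,
        "package_version": __version__,
        "m": maps.m,
        "n": maps.n,
        "V1": maps.V1.tolist(),
        "V2": maps.V2.tolist(),
        "config": config or {},
    }
    Path(path).write_text(json.dumps(doc))


def load_maps(path: str | Path) -> tuple[MapGrid, dict[str, Any]]:
    """Load a MapGrid saved by :func:`save_maps`; returns (maps, config)."""
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot load map container {path}: {exc}") from exc
    if not isinstance(doc, dict) or "format_major" not in doc:
        raise ValueError(f"{path} is not a map container")
    if doc["format_major"] > MAPS_FORMAT_MAJOR:
        raise ValueError(
            f"map container {path} uses format {doc['format_major']}, newer "
            f"than this package supports ({MAPS_FORMAT_MAJOR})"
        )
    V1 = np.asarray(doc["V1"], dtype=float)
    V2 = np.asarray(doc["V2"], dtype=float)
    m, n = int(doc["m"]), int(doc["n"])
    if V1.ndim != 2 or V2.ndim != 2 or V1.shape[0] != m * n or V2.shape[0] != m * n:
        raise ValueError(f"map container {path} has inconsistent dimensions")
    return MapGrid(m=m, n=n, V1=V1, V2=V2), doc.get("config", {})
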