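"""End-to-end convenience wrapper: downsample -> match -> train -> assign.

The stages are all available individually; this wrapper only enforces the
correct order (the matching must be computed on the same rows used for
training, i.e. after downsampling) and gathers the products.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import Assignment, Dataset, MapGrid, MatchingResult, SharedFeatureSpec, TrainConfig
from .downsample import density_downsample, uniform_downsample
from .matching import build_matching
from .postprocess import NodeClustering, assign_to_nodes, superpose_cluster
from .train import train_jsom


@dataclass
class JSOMResult:
    """Everything the aligned-map workflow produces."""

    maps: MapGrid
    matching: MatchingResult
    assignment: Assignment  # on the FULL datasets
    clustering: NodeClustering
    train_idx1: np.ndarray  # rows of each dataset used for training
    train_idx2: np.ndarray


def run_jsom(
    d1: Dataset,
    d2: Dataset,
    spec: SharedFeatureSpec,
    cfg: Optional[TrainConfig] = None,
    mode: str = "correlation",
    density_downsampling: bool = True,
    n_clusters: Optional[int] = None,
) -> JSOMResult:
    """Run the full alignment workflow and return all products.

    Datasets larger than ``cfg.downsample_target`` are downsampled before
    matching and training (density-dependent by default, plain uniform
    when ``density_downsampling`` is off); the final assignment is always
    computed on the full datasets.
    """
    if cfg is None:
        cfg = TrainConfig()
    spec.validate(d1, d2)

    idxs = []
    for which, d in enumerate((d1, d2)):
        if cfg.downsample_enabled and d.n_cells > cfg.downsample_target:
            if density_downsampling:
                idx = density_downsample(
                    d.values, cfg.downsample_target, seed=cfg.seed + which
                )
            else:
                idx = uniform_downsample(
                    d.n_cells, cfg.downsample_target, seed=cfg.seed + which
                )
        else:
            idx = np.arange(d.n_cells)
        idxs.append(idx)
    t1 = d1.subset_cells(idxs[0])
    t2 = d2.subset_cells(idxs[1])

    matching = build_matching(
        t1, t2, spec, mode=mode, allow_negative_delta=cfg.allow_negative_delta
    )
    maps = train_jsom(t1, t2, matching, cfg)
    assignment = assign_to_nodes(d1, d2, maps)
    clustering = superpose_cluster(maps, K=n_clusters)
    return JSOMResult(
        maps=maps,
        matching=matching,
        assignment=assignment,
        clustering=clustering,
        train_idx1=idxs[0],
        train_idx2=idxs[1],
    )
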