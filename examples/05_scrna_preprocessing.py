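"""Standard scRNA-seq preprocessing ahead of map training.

Simulated raw counts go through the usual chain: QC filtering (detected
genes in [200, 2500], mitochondrial fraction <= 5%), log1p, selection of
highly variable genes by variance-to-mean dispersion, and PCA down to a
few tens of components — the representation the maps are trained on.
"""

import numpy as np

from jsom import Dataset, filter_cells, log1p_transform, pca_reduce, select_hvg

rng = np.random.default_rng(8)
n_cells, n_genes = 400, 3000
rates = rng.gamma(0.3, 1.0, size=n_genes)          # skewed per-gene expression
counts = rng.poisson(rates, size=(n_cells, n_genes)).astype(float)
counts[:5, :2600] += 1          # doublet-like cells detecting > 2500 genes
counts[5:9, :10] += 50          # cells with runaway mitochondrial fraction
genes = [f"MT-{i}" if i < 10 else f"G{i}" for i in range(n_genes)]
raw = Dataset(counts, genes, [f"cell{i}" for i in range(n_cells)])

qc = filter_cells(raw, mito_prefix="MT-", min_genes=200, max_genes=2500,
                  max_mito_frac=0.05)
print(f"QC filter: {raw.n_cells} -> {qc.n_cells} cells")

logged = log1p_transform(qc)
hvg = select_hvg(logged, n_top=500)
reduced = pca_reduce(logged.subset_features(hvg), n_components=20)
print(f"selected {len(hvg)} highly variable genes; "
      f"reduced to {reduced.n_features} PCs ({reduced.feature_names[:3]} ...)")
var = reduced.values.var(axis=0)
print(f"PC variance is non-increasing: PC1 {var[0]:.2f} >= PC20 {var[-1]:.2f}")
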