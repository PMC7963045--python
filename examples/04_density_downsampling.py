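"""Density-dependent downsampling protects rare populations.

A 9:1 mixture is capped to 2000 training cells; because keep-probability
is inversely proportional to local density, the kept cells are far more
balanced than the input.
"""

import numpy as np

from jsom import density_downsample, uniform_downsample

rng = np.random.default_rng(0)
X = np.vstack([rng.normal(0, 1, size=(9000, 4)),    # abundant population
               rng.normal(30, 1, size=(1000, 4))])  # rare population

kept = density_downsample(X, 2000, seed=0)
n_big, n_small = int((kept < 9000).sum()), int((kept >= 9000).sum())
print(f"density-dependent: kept {n_big} abundant / {n_small} rare "
      f"(ratio {n_big / n_small:.2f}:1, input was 9:1)")

kept_u = uniform_downsample(10_000, 2000, seed=0)
nb, ns = int((kept_u < 9000).sum()), int((kept_u >= 9000).sum())
print(f"plain uniform     : kept {nb} abundant / {ns} rare "
      f"(ratio {nb / ns:.2f}:1 — the rare population stays rare)")
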