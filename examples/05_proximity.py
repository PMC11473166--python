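"""Nearest-neighbor proximity of a macrophage class to regenerating fibers.

Plants one cell class 10x denser within 20 um of fiber positions (the
growth-factor-expressing-macrophage pattern) and a competing class uniform,
then tests enrichment of the <20 um proximity fraction with a relabeling
permutation null.
"""

import numpy as np
from scipy.spatial import cKDTree

import rizmap as rz

rng = np.random.default_rng(1)
fibers = rng.uniform(0, 1000, (50, 2))          # eMyHC+ fiber centroids (um)

proposals = rng.uniform(0, 1000, (1200, 2))
d, _ = cKDTree(fibers).query(proposals)
keep = rng.uniform(size=1200) < np.where(d <= 20.0, 1.0, 0.1)
enriched = proposals[keep][:150]                 # GPNMB+ -like class
competing = rng.uniform(0, 1000, (150, 2))       # GPNMB- -like class

res = rz.proximity_fraction(enriched, fibers, competing,
                            d_max_um=20.0, n_perm=999, seed=1)
base = rz.proximity_fraction(competing, fibers, d_max_um=20.0)

print(f"fraction of enriched class within 20 um of a fiber: {res.fraction:.3f}")
print(f"fraction of competing class within 20 um:          {base.fraction:.3f}")
print(f"one-sided enrichment p (relabeling null, n={res.null.size}): {res.p_value:.4g}")

# Under no association both fractions would match the ~6% of the field
# lying within 20 um of a fiber; the planted class is strongly enriched.
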