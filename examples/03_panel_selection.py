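"""Max-min panel selection from a pairwise discriminability matrix.

Every unordered pair of populations is scored by how well an unsupervised
two-component Gaussian mixture separates the pooled pair (0.5 = chance,
1.0 = perfect).  A panel's worst pair limits its usefulness, so the search
maximizes the minimum within-subset pairwise accuracy over random draws;
on this small instance the exhaustive optimum verifies the search.
"""

import numpy as np

from fpbarcode import features, panel, simulate, tags

# 10 populations, some deliberately similar
panel10 = [
    tags.TagSpec(*t)
    for t in [(1, 0, 0), (2, 0, 0), (8, 0, 0), (0, 1, 0), (0, 8, 0),
              (0, 0, 8), (1, 1, 0), (2, 2, 0), (4, 0, 4), (0, 4, 4)]
]
cfg = simulate.GeneratorConfig(n_cells_per_population=300, seed=2)
table = simulate.simulate_intensity_table(panel10, cfg)
table = features.normalize_global_median(table)
feats = features.add_spherical_features(table)
feats = feats[feats["valid"]]

matrix = panel.pairwise_matrix(feats, seed=3)
off = matrix.values[~np.eye(len(matrix.labels), dtype=bool)]
print(f"pairwise accuracies: min {np.nanmin(off):.3f}, median {np.nanmedian(off):.3f}")

for k in (4, 6, 8):
    found = panel.maxmin_random_search(matrix, k, n_draws=50_000, seed=4)
    exact = panel.maxmin_exhaustive(matrix, k)
    print(f"k={k}: max-min accuracy {found.min_accuracy:.3f} "
          f"(exhaustive {exact.min_accuracy:.3f}) panel={found.subset}")
# The max-min floor falls as k grows: more populations force harder pairs
# into every panel.
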