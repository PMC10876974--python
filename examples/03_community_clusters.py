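"""Bray-Curtis / PCoA / k-means community typing.

Generates 18 samples drawn from three composition archetypes (think three
microbiome community states), computes Bray-Curtis dissimilarities on the
compositional vectors, ordinates them by PCoA, and scans k = 2..6 k-means
solutions for the best silhouette.  The scan should recover k = 3.
"""

import numpy as np
import pandas as pd

from longmeta.community import bray_curtis_matrix, cluster_membership, pcoa, scan_kmeans

rng = np.random.default_rng(0)
rows, n_species = [], 9
for g in range(3):
    arch = np.full(n_species, 0.01)
    arch[3 * g : 3 * g + 3] = rng.uniform(0.25, 0.4, 3)
    arch /= arch.sum()
    for _ in range(6):
        noise = rng.dirichlet(np.full(n_species, 80.0))
        vec = 0.85 * arch + 0.15 * noise
        rows.append(vec / vec.sum())
table = pd.DataFrame(rows, index=[f"s{i}" for i in range(18)])

dm = bray_curtis_matrix(table)
ordination = pcoa(dm)
print(
    "PCoA axis 1+2 explain "
    f"{ordination.proportion_explained[:2].sum():.0%} of positive inertia"
)

clusters = scan_kmeans(ordination, seed=0, restarts=50)
print("\nsilhouette by k:")
for k, s in sorted(clusters.silhouette_by_k.items()):
    marker = "  <- chosen" if k == clusters.k else ""
    print(f"  k={k}: {s:.3f}{marker}")

# Follow-up membership: is a new sample inside a baseline cluster space?
membership = cluster_membership(
    ordination,
    {s: c for s, c in clusters.labels.items() if s != "s17"},
    ["s17"],
)
print(
    f"\nsample s17 lies {'inside' if membership.loc['s17', 'inside'] else 'outside'} "
    f"cluster {membership.loc['s17', 'cluster']}'s baseline hull"
)
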