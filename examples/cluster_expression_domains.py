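"""Cluster synthetic expression profiles into anatomical domains.

Generates 200 noisy profiles from the five domain archetypes, normalizes them
with the standard pipeline (smoothing spline spar = 0.4, landmark alignment,
left/right folding, max normalization), selects the cluster count by
silhouette, and labels each cluster with its expression domain.
"""

from sklearn.metrics import adjusted_rand_score

import gemmatlas as g
from gemmatlas.normalize import normalize_matrix

matrix, truth = g.make_profile_set(n_per_archetype=40, noise_sd=0.1, seed=1)
folded = normalize_matrix(matrix)
print(f"profile matrix: {matrix.shape[0]} reporters x {matrix.shape[1]} grid points")

k = g.select_k(folded.to_numpy(), (2, 8))
print(f"silhouette-selected number of clusters: k = {k}")

clustering = g.assign_domains(g.cluster_profiles(folded, g.ClusterConfig(k=k)))
frame = clustering.to_frame()
print(frame.groupby(["cluster", "domain"]).size().rename("reporters"))
print(f"ARI vs planted archetypes: "
      f"{adjusted_rand_score(truth, clustering.labels):.3f}")
print("each cluster's mode position (folded axis, notch at 0.2, center at 0.5):")
for cid, mode in sorted(clustering.mode_positions.items()):
    print(f"  cluster {cid}: mode {mode:.3f} -> {clustering.domain_labels[cid]}")
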