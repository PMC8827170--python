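"""GMPR normalization, Faith's PD, and generalized UniFrac distances.

Counts are first normalized with GMPR size factors (robust to the zero
inflation of amplicon data), alpha diversity is Faith's phylogenetic
diversity, and beta diversity is the generalized UniFrac distance at
alpha = 0.5.
"""

import dyadome as dy

study = dy.simulate_study(dy.SimulationConfig(
    group_sizes=(5, 5, 4), n_seasons=2, n_asvs=120,
    samples_per_individual_season=2, seed=2,
))

normalized, factors = dy.gmpr_normalize(study.counts)
print(f"GMPR size factors: median {factors.median():.3f}, "
      f"range {factors.min():.3f}-{factors.max():.3f}")
# A factor of 2 means the sample was sequenced about twice as deeply as a
# typical sample; dividing by it makes abundances comparable.

alpha = dy.alpha_diversity_table(study.counts, study.tree)
print(alpha.head())
print(f"mean Faith's PD: {alpha['faith_pd'].mean():.2f} (tree branch-length units)")

d = dy.pairwise_distance_matrix(normalized, study.tree, alpha=0.5)
print(f"GUniFrac matrix: {d.shape[0]} x {d.shape[1]}, "
      f"mean off-diagonal distance {d.condensed_form().mean():.3f}")
# Distances lie in [0, 1]: 0 = identical communities on the tree,
# 1 = phylogenetically disjoint communities.
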