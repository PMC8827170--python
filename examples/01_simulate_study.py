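"""Generate a synthetic gut-microbiome study and look at its pieces.

The generator emulates a longitudinal field study: seven social groups
of 2-12 individuals (41 in total), four field seasons, about 3.9 faecal
samples per individual per season, with group-, individual-, kinship-
and season-level effects on log relative abundances.
"""

import warnings

import dyadome as dy

warnings.simplefilter("ignore")  # the generator may warn about its PD fallback

config = dy.SimulationConfig(seed=1)
study = dy.simulate_study(config)

counts = study.counts
meta = study.metadata
print(f"ASV table: {counts.shape[0]} ASVs x {counts.shape[1]} samples")
print(f"reads per sample: mean {counts.sum().mean():.0f}, "
      f"range {counts.sum().min()}-{counts.sum().max()}")
print(f"individuals: {len(meta.individuals)} in groups "
      f"{meta.individuals_per_group().to_dict()}")
print(f"seasons: {meta.seasons}")

kin = study.relatedness.to_numpy()
n_kin = int((kin > 0).sum() / 2)
print(f"maternal-kin dyads (RC > 0): {n_kin}")
# Each kin dyad carries RC 0.25, 0.375 or 0.5; the generator makes related
# individuals' compositions more similar through a shared covariance term.
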