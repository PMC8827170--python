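"""One-call pipeline: simulate -> normalize -> diversity -> group tests ->
indicators -> dyad tables -> mixed models, with a reproducibility manifest.

The same entry point accepts file inputs (counts TSV, newick tree,
metadata TSVs) through an `inputs:` section in the config.
"""

import json
import warnings

from dyadome.pipeline import run_pipeline

warnings.simplefilter("ignore")

config = {
    "seed": 6,
    "simulate": {
        "group_sizes": [5, 5, 4],
        "n_seasons": 2,
        "n_asvs": 100,
        "samples_per_individual_season": 2,
    },
    "gunifrac_alpha": 0.5,
    "group_test": {"n_perm": 999, "per_season": True},
    "indicators": {"category": "group_id", "n_perm": 199},
    "models": ["LMM_I", "LMM_III"],
}

manifest = run_pipeline(config, output_dir="scratch/example_run")
print(json.dumps(manifest.results, indent=2, sort_keys=True))
print()
print("stage seeds:", manifest.stage_seeds)
print(f"{len(manifest.outputs)} output files written with checksums; "
      "rerunning the same config reproduces them byte-identically.")
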