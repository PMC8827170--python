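"""End-to-end orchestration: one config file drives
normalize -> diversity -> per-season group tests -> habitat Mantel ->
indicator analysis -> dyad tables -> mixed models, writing every stage's
output plus a run manifest with checksums.

Randomized stages draw their seeds from one master seed through a
counter scheme (:class:`numpy.random.SeedSequence` spawn keys), so each
stage is reproducible on its own and a rerun with the same config and
inputs produces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import diversity, dyadic, indicators, io, normalization, permutation, simulate
from .core import DyadomeError, ValidationError

logger = logging.getLogger("dyadome")

__all__ = ["RunManifest", "run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "seed": 1,
    "output_dir": "dyadome_out",
    "simulate": {},  # SimulationConfig overrides; or use "inputs" with paths
    "gunifrac_alpha": 0.5,
    "group_test": {"n_perm": 1000, "per_season": True},
    "indicators": {"category": "group_id", "n_perm": 999, "depth": None},
    "models": ["LMM_I", "LMM_III"],
    "bootstrap": 0,
}


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    master_seed: int
    stage_seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256
    warnings: list = field(default_factory=list)
    results: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "master_seed": self.master_seed,
                "stage_seeds": self.stage_seeds,
                "outputs": self.outputs,
                "warnings": self.warnings,
                "results": self.results,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    key = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    seq = np.random.SeedSequence(entropy=master, spawn_key=(key,))
    return int(seq.generate_state(1)[0] % (2**31))


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(config or {})
    merged = {**DEFAULT_CONFIG, **user}
    for key in ("group_test", "indicators"):
        merged[key] = {**DEFAULT_CONFIG[key], **(user.get(key) or {})}
    return merged


def run_pipeline(config, output_dir=None) -> RunManifest:
    """Run the full analysis described by ``config`` (path or mapping).

    Inputs come either from the synthetic generator (``simulate`` section)
    or from files (``inputs`` section with ``counts``, ``tree``,
    ``samples``, ``individuals``, ``relatedness`` and optionally
    ``dyads`` paths). Pre-flight validation aborts before any output is
    written when an input is missing or fatally inconsistent.
    """
    cfg = _load_config(config)
    out_dir = Path(output_dir or cfg["output_dir"])
    master_seed = int(cfg["seed"])
    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(config_hash=config_hash, master_seed=master_seed)

    # ---- inputs (pre-flight before creating outputs) ----
    group_covariates = None
    if "inputs" in cfg and cfg["inputs"]:
        paths = {k: Path(v) for k, v in cfg["inputs"].items()}
        missing = [str(p) for p in paths.values() if not p.exists()]
        if missing:
            raise ValidationError(f"input files not found: {missing}")
        tree = io.read_tree(paths["tree"])
        meta = io.read_metadata(
            paths["samples"], paths["individuals"], paths.get("dyads")
        )
        counts = io.read_count_table(paths["counts"], metadata=meta)
        relatedness = (
            io.read_relatedness(paths["relatedness"])
            if "relatedness" in paths
            else None
        )
    else:
        sim_seed = _stage_seed(master_seed, "simulate")
        manifest.stage_seeds["simulate"] = sim_seed
        sim_cfg = simulate.SimulationConfig(**{**cfg["simulate"], "seed": sim_seed})
        study = simulate.simulate_study(sim_cfg)
        counts, tree, meta = study.counts, study.tree, study.metadata
        relatedness = study.relatedness
        group_covariates = study.group_covariates

    report = io.validate_study(counts, tree, meta)
    for sev, code, msg in report.entries:
        manifest.warnings.append(f"[{sev}] {code}: {msg}")
    if not report.ok:
        raise ValidationError(f"fatal validation entries:\n{report}")

    out_dir.mkdir(parents=True, exist_ok=True)

    def write(name, writer, *args):
        path = out_dir / name
        writer(*args, path)
        manifest.outputs[name] = _sha256(path)
        return path

    write("counts.tsv", io.write_count_table, counts)
    write("tree.nwk", io.write_tree, tree)
    io.write_metadata(
        meta, out_dir / "samples.tsv", out_dir / "individuals.tsv",
        out_dir / "dyads.tsv" if meta.dyads is not None else None,
    )
    for name in ("samples.tsv", "individuals.tsv", "dyads.tsv"):
        p = out_dir / name
        if p.exists():
            manifest.outputs[name] = _sha256(p)
    if relatedness is not None:
        write("relatedness.tsv", io.write_relatedness, relatedness)

    # ---- normalization + diversity ----
    normalized, factors = normalization.gmpr_normalize(counts)
    factors.to_csv(out_dir / "gmpr_size_factors.tsv", sep="\t")
    manifest.outputs["gmpr_size_factors.tsv"] = _sha256(out_dir / "gmpr_size_factors.tsv")

    alpha = diversity.alpha_diversity_table(counts, tree)
    alpha.to_csv(out_dir / "alpha_diversity.tsv", sep="\t")
    manifest.outputs["alpha_diversity.tsv"] = _sha256(out_dir / "alpha_diversity.tsv")

    galpha = float(cfg["gunifrac_alpha"])
    dmat = diversity.pairwise_distance_matrix(normalized, tree, alpha=galpha)
    write("gunifrac_distances.tsv", io.write_distance_matrix, dmat)

    # ---- per-season restricted group tests ----
    gt_cfg = cfg["group_test"]
    gt_seed = _stage_seed(master_seed, "group_test")
    manifest.stage_seeds["group_test"] = gt_seed
    if gt_cfg.get("per_season", True):
        season_results = permutation.per_season_group_tests(
            dmat, meta, n_perm=int(gt_cfg["n_perm"]), seed=gt_seed
        )
    else:
        season_results = {
            "all": permutation.restricted_group_test(
                dmat, meta, n_perm=int(gt_cfg["n_perm"]), seed=gt_seed
            )
        }
    manifest.results["group_tests"] = {
        season: {
            "statistic": r.observed_stat,
            "mean_within": r.mean_within,
            "mean_between": r.mean_between,
            "p_value": r.p_value,
            "mode": r.mode,
            "n_perm": r.n_perm,
        }
        for season, r in season_results.items()
    }

    # ---- habitat Mantel (group level), when covariates are available ----
    if group_covariates and "habitat_dissimilarity" in group_covariates:
        mantel_seed = _stage_seed(master_seed, "mantel")
        manifest.stage_seeds["mantel"] = mantel_seed
        gdyads = dyadic.build_dyad_table(dmat, meta, level="group")
        manifest.results["habitat_mantel"] = {}
        habitat = group_covariates["habitat_dissimilarity"]
        import skbio

        for season in meta.seasons:
            sub = gdyads[gdyads["season"] == season]
            groups = sorted(set(sub["unit_a"]) | set(sub["unit_b"]))
            if len(groups) < 3:
                continue
            m = np.zeros((len(groups), len(groups)))
            gi = {g: i for i, g in enumerate(groups)}
            for _, row in sub.iterrows():
                i, j = gi[row["unit_a"]], gi[row["unit_b"]]
                m[i, j] = m[j, i] = row["response"]
            d_micro = skbio.DistanceMatrix(m, ids=groups)
            d_hab = habitat.filter(groups)
            res = permutation.mantel_pearson(
                d_micro, d_hab, n_perm=int(gt_cfg["n_perm"]), seed=mantel_seed
            )
            manifest.results["habitat_mantel"][season] = {
                "r": res.observed_stat,
                "p_value": res.p_value,
                "mode": res.mode,
            }

    # ---- indicator analysis ----
    ind_cfg = cfg["indicators"]
    ind_seed = _stage_seed(master_seed, "indicators")
    manifest.stage_seeds["indicators"] = ind_seed
    depth = ind_cfg.get("depth") or int(counts.sum(axis=0).min())
    rarefied = normalization.rarefy(counts, depth, seed=ind_seed)
    category_col = ind_cfg.get("category", "group_id")
    labels = meta.samples.loc[rarefied.columns, category_col]
    ind_result = indicators.indicator_analysis(
        rarefied, labels, n_perm=int(ind_cfg["n_perm"]), seed=ind_seed
    )
    ind_result.table.to_csv(out_dir / "indicator_statistics.tsv", sep="\t")
    indicators.association_edges(ind_result).to_csv(
        out_dir / "association_edges.tsv", sep="\t", index=False
    )
    for name in ("indicator_statistics.tsv", "association_edges.tsv"):
        manifest.outputs[name] = _sha256(out_dir / name)
    manifest.results["indicators"] = {
        "fraction_associated": ind_result.fraction_associated,
        "n_associated": int(len(ind_result.associations)),
        "rarefaction_depth": int(depth),
    }

    # ---- dyad tables + mixed models ----
    tables = {
        "dyad_within_group_with_self": dyadic.build_dyad_table(
            dmat, meta, relatedness, level="individual", scope="within-group",
            include_self_dyads=True,
        ),
        "dyad_within_group": dyadic.build_dyad_table(
            dmat, meta, relatedness, level="individual", scope="within-group"
        ),
        "dyad_all": dyadic.build_dyad_table(
            dmat, meta, relatedness, level="individual", scope="all"
        ),
        "group_dyad": dyadic.build_dyad_table(
            dmat, meta, level="group", group_covariates=group_covariates
        ),
        "alpha": dyadic.build_alpha_table(alpha, meta),
    }
    tables["dyad_within_group_with_self"].to_csv(
        out_dir / "dyad_table.tsv", sep="\t", index=False
    )
    manifest.outputs["dyad_table.tsv"] = _sha256(out_dir / "dyad_table.tsv")

    specs = {s.name: s for s in dyadic.preset_models()}
    lmm_results = {}
    for name in cfg.get("models", []):
        if name not in specs:
            raise DyadomeError(f"unknown model {name!r}")
        spec = specs[name]
        table_key = spec.table
        if table_key.startswith("alpha"):
            table = tables["alpha"]
        elif table_key in tables:
            table = tables[table_key]
        else:  # variants (adults-only etc.) fall back to the base table
            table = tables["dyad_within_group"]
        lmm_seed = _stage_seed(master_seed, f"lmm:{name}")
        manifest.stage_seeds[f"lmm:{name}"] = lmm_seed
        try:
            res = dyadic.run_model(
                table, spec, n_boot=int(cfg.get("bootstrap", 0)), seed=lmm_seed,
                drop_aliased=True,
            )
        except (DyadomeError, ValidationError) as exc:
            manifest.warnings.append(f"model {name} skipped: {exc}")
            continue
        lmm_results[name] = {
            "chi2": res["chi2"],
            "df": res["df"],
            "p_value": res["p_value"],
            "r2_marginal": res["r2_marginal"],
            "r2_conditional": res["r2_conditional"],
            "converged": res["full"].converged,
            "structure_note": res["full"].structure_note,
        }
    manifest.results["models"] = lmm_results

    results_path = out_dir / "results.json"
    results_path.write_text(json.dumps(manifest.results, indent=2, sort_keys=True))
    manifest.outputs["results.json"] = _sha256(results_path)
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
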