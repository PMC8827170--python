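"""Synthetic study generator.

Generates complete studies — counts, tree, metadata, maternal
relatedness, group-level covariates — with controllable group, individual,
kinship, and season effect sizes, so every pipeline stage can be exercised
without field data.

Generative model
----------------
For sample ``s`` of individual ``i`` in group ``g`` at season ``t``, the
expected log relative abundance of ASV ``a`` is

    lambda = base_a + G[g, a] + I[i, a] + S[t, a] + eps[s, a]

with ``G ~ N(0, sigma_group^2)`` i.i.d. per (group, ASV),
``S ~ N(0, sigma_season^2)`` per (season, ASV), per-draw noise
``eps ~ N(0, sigma_sample^2)``, and the individual effects
``(I[1, a], ..., I[n, a])`` jointly multivariate normal with covariance
``sigma_individual^2 * Id + sigma_kin^2 * RC`` — so maternally related
individuals (higher RC) receive more similar effects, the direction the
dyadic models test. Counts are drawn multinomially from
``softmax(lambda)`` at a log-normal library size, which yields the
compositional, zero-inflated tables typical of amplicon data
(Dirichlet-multinomial-like overdispersion via ``sigma_sample``).

The defaults mirror the study design the pipeline targets: seven groups
of sizes (10, 7, 3, 6, 5, 5, 5) = 41 individuals, four field seasons, on
average 3.9 samples per individual per season, and library sizes of order
1e4-2e5 reads.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import skbio

from .core import DEFAULT_SEASON_ORDER, StudyMetadata
from .diversity import bray_curtis_matrix

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "generate_tree",
    "generate_metadata",
    "generate_counts",
    "generate_group_covariates",
    "simulate_study",
]

_DEFAULT_GROUP_SIZES = (10, 7, 3, 6, 5, 5, 5)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    All sigmas are standard deviations of log-abundance effects and must
    be non-negative; ``kin_density`` is the fraction of within-group
    dyads assigned RC > 0. A fixed ``seed`` makes every generated
    artifact byte-identical across runs.
    """

    group_sizes: tuple = _DEFAULT_GROUP_SIZES
    n_seasons: int = 4
    samples_per_individual_season: float = 3.9
    n_asvs: int = 300
    depth_log_mean: float = math.log(4.0e4)
    depth_log_sd: float = 0.4
    sigma_group: float = 1.0
    sigma_individual: float = 1.0
    sigma_kin: float = 1.0
    sigma_season: float = 0.5
    sigma_sample: float = 0.5
    base_log_abundance_sd: float = 2.0
    kin_density: float = 0.1
    seed: int = 0

    def __post_init__(self):
        self.group_sizes = tuple(int(s) for s in self.group_sizes)
        if any(s < 1 for s in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if self.n_seasons < 1:
            raise ValueError("need at least one season")
        if self.n_asvs < 2:
            raise ValueError("need at least two ASVs")
        for name in (
            "sigma_group",
            "sigma_individual",
            "sigma_kin",
            "sigma_season",
            "sigma_sample",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.kin_density <= 1.0):
            raise ValueError("kin_density must be in [0, 1]")

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    @property
    def n_individuals(self) -> int:
        return sum(self.group_sizes)

    @property
    def season_ids(self) -> tuple:
        if self.n_seasons == len(DEFAULT_SEASON_ORDER):
            return DEFAULT_SEASON_ORDER
        return tuple(f"season-{t + 1}" for t in range(self.n_seasons))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticStudy:
    """A generated study: all pipeline inputs plus the generating truth."""

    counts: pd.DataFrame
    tree: skbio.TreeNode
    metadata: StudyMetadata
    relatedness: pd.DataFrame
    true_effects: dict
    group_covariates: dict = field(default_factory=dict)
    config: SimulationConfig | None = None


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_tree(n_asvs: int, seed=None) -> skbio.TreeNode:
    """Random rooted binary tree over ``n_asvs`` tips.

    Built by random pairwise joins (coalescent-style topology); every
    branch length is an independent Exponential(rate 1) draw, so all
    lengths are positive. Tip ids are ``ASV0001`` ... in input order.
    """
    if n_asvs < 2:
        raise ValueError("need at least two ASVs for a tree")
    rng = _rng(seed)
    nodes = []
    for i in range(n_asvs):
        tip = skbio.TreeNode(name=f"ASV{i + 1:04d}")
        tip.length = float(rng.exponential(1.0))
        nodes.append(tip)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = int(i), int(j)
        a, b = nodes[i], nodes[j]
        parent = skbio.TreeNode(children=[a, b])
        parent.length = float(rng.exponential(1.0))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return root


def generate_metadata(config: SimulationConfig, seed=None):
    """Individuals, groups, seasons, samples, covariates, relatedness.

    Individuals are partitioned into groups of the configured sizes; each
    individual contributes a Poisson-perturbed number of samples per
    season (minimum 1). Ages, sexes, age classes, male ranks (exactly one
    dominant male per group — deterministically the oldest male),
    reproductive states, fGCM levels, and dyadic affiliation/residence
    covariates are assigned. RC values are placed on a random subset of
    within-group dyads at density ``kin_density`` (and on between-group
    dyads at a quarter of that density, so cross-group kin exist).

    Returns ``(StudyMetadata, relatedness DataFrame)``.
    """
    rng = _rng(seed if seed is not None else config.seed)
    group_ids = [f"G{i + 1}" for i in range(config.n_groups)]
    individual_ids, ind_group = [], {}
    counter = 0
    for gid, size in zip(group_ids, config.group_sizes):
        for _ in range(size):
            counter += 1
            iid = f"I{counter:03d}"
            individual_ids.append(iid)
            ind_group[iid] = gid

    # ages in years; age classes: infant < 1, juvenile 1-4, adult > 4
    ages = rng.uniform(0.3, 18.0, size=len(individual_ids))
    # make sure every group has at least one adult male (rank assignment)
    sexes = rng.choice(["female", "male"], size=len(individual_ids))
    frame = pd.DataFrame(
        {
            "group_id": [ind_group[i] for i in individual_ids],
            "sex": sexes,
            "age": np.round(ages, 2),
        },
        index=pd.Index(individual_ids, name="individual_id"),
    )
    for gid in group_ids:
        members = frame.index[frame["group_id"] == gid]
        adult_males = frame.loc[members].query("sex == 'male' and age > 4")
        if adult_males.empty:
            # promote the oldest member to an adult male so each group has
            # a dominant male, mirroring the study system
            oldest = frame.loc[members, "age"].idxmax()
            frame.loc[oldest, "sex"] = "male"
            frame.loc[oldest, "age"] = max(frame.loc[oldest, "age"], 5.0)

    def age_class(a):
        return "infant" if a < 1 else ("juvenile" if a <= 4 else "adult")

    frame["age_class"] = [age_class(a) for a in frame["age"]]

    rank = []
    for iid in frame.index:
        row = frame.loc[iid]
        if row["age_class"] != "adult":
            rank.append(np.nan)
        elif row["sex"] == "female":
            rank.append("adult-female")
        else:
            rank.append("subordinate-male")
    frame["rank_category"] = rank
    for gid in group_ids:
        males = frame.query("group_id == @gid and rank_category == 'subordinate-male'")
        dominant = males["age"].idxmax()  # oldest adult male is dominant
        frame.loc[dominant, "rank_category"] = "dominant-male"

    repro = []
    for iid in frame.index:
        row = frame.loc[iid]
        if row["sex"] == "female" and row["age_class"] == "adult":
            repro.append(rng.choice(["reproducing", "not-reproducing"]))
        else:
            repro.append(np.nan)
    frame["reproductive_state"] = repro
    frame["fgcm"] = np.round(rng.lognormal(mean=4.0, sigma=0.5, size=len(frame)), 2)
    frame["leaf_intake"] = np.round(rng.uniform(0.2, 0.8, size=len(frame)), 3)

    # samples: Poisson-perturbed count per individual per season, min 1
    seasons = config.season_ids
    sample_rows = []
    counter = 0
    for iid in frame.index:
        for season in seasons:
            n = max(1, int(rng.poisson(config.samples_per_individual_season)))
            for _ in range(n):
                counter += 1
                sample_rows.append(
                    {
                        "sample_id": f"S{counter:05d}",
                        "individual_id": iid,
                        "group_id": ind_group[iid],
                        "season_id": season,
                    }
                )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")

    # dyadic covariates for within-group dyads
    dyad_rows = []
    for gid in group_ids:
        members = list(frame.index[frame["group_id"] == gid])
        for a_idx in range(len(members)):
            for b_idx in range(a_idx + 1, len(members)):
                a, b = sorted((members[a_idx], members[b_idx]))
                dyad_rows.append(
                    {
                        "individual_a": a,
                        "individual_b": b,
                        "affiliation_minutes": round(float(rng.exponential(2.0)), 3),
                        "residence_years": round(
                            float(
                                min(
                                    rng.uniform(0.2, 14.2),
                                    frame.loc[a, "age"],
                                    frame.loc[b, "age"],
                                )
                            ),
                            2,
                        ),
                    }
                )
    dyads = pd.DataFrame(dyad_rows)

    # maternal relatedness
    n_ind = len(individual_ids)
    rc = np.zeros((n_ind, n_ind))
    idx_of = {iid: k for k, iid in enumerate(individual_ids)}
    rc_choices = np.array([0.5, 0.25, 0.375])
    rc_probs = np.array([0.5, 0.3, 0.2])
    for gid in group_ids:
        members = [i for i in individual_ids if ind_group[i] == gid]
        for a_idx in range(len(members)):
            for b_idx in range(a_idx + 1, len(members)):
                if rng.random() < config.kin_density:
                    value = rng.choice(rc_choices, p=rc_probs)
                    ia, ib = idx_of[members[a_idx]], idx_of[members[b_idx]]
                    rc[ia, ib] = rc[ib, ia] = value
    between_density = config.kin_density / 4.0
    for a_idx in range(n_ind):
        for b_idx in range(a_idx + 1, n_ind):
            ia, ib = individual_ids[a_idx], individual_ids[b_idx]
            if ind_group[ia] != ind_group[ib] and rng.random() < between_density:
                value = rng.choice(rc_choices, p=rc_probs)
                rc[a_idx, b_idx] = rc[b_idx, a_idx] = value
    relatedness = pd.DataFrame(rc, index=individual_ids, columns=individual_ids)

    season_order = seasons if config.n_seasons != len(DEFAULT_SEASON_ORDER) else DEFAULT_SEASON_ORDER
    meta = StudyMetadata(
        samples=samples, individuals=frame, dyads=dyads, season_order=tuple(season_order)
    )
    return meta, relatedness


def _effect_cholesky(relatedness: np.ndarray, sigma_individual, sigma_kin):
    """Cholesky factor of sigma_i^2 * Id + sigma_k^2 * RC, with a
    nearest-positive-definite fallback (eigenvalue clipping) when the raw
    matrix is not PD."""
    n = relatedness.shape[0]
    cov = sigma_individual**2 * np.eye(n) + sigma_kin**2 * relatedness
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        warnings.warn(
            "individual-effect covariance not positive definite; "
            "clipping eigenvalues to the nearest PD matrix",
            RuntimeWarning,
            stacklevel=2,
        )
        values, vectors = np.linalg.eigh(cov)
        values = np.clip(values, 1e-10, None)
        return vectors @ np.diag(np.sqrt(values))


def generate_counts(
    metadata: StudyMetadata,
    tree: skbio.TreeNode,
    relatedness: pd.DataFrame,
    config: SimulationConfig,
    seed=None,
    return_effects: bool = False,
):
    """Multinomial ASV counts under the additive log-abundance model.

    With ``return_effects`` the per-level true effect matrices used in
    generation are returned alongside the counts.
    """
    rng = _rng(seed if seed is not None else config.seed)
    tip_ids = [t.name for t in tree.tips()]
    n_asvs = len(tip_ids)
    individuals = list(metadata.individuals.index)
    groups = metadata.group_ids
    seasons = list(config.season_ids)
    g_idx = {g: k for k, g in enumerate(groups)}
    i_idx = {i: k for k, i in enumerate(individuals)}
    t_idx = {t: k for k, t in enumerate(seasons)}

    base = rng.normal(0.0, config.base_log_abundance_sd, size=n_asvs)
    g_eff = rng.normal(0.0, config.sigma_group, size=(len(groups), n_asvs))
    s_eff = rng.normal(0.0, config.sigma_season, size=(len(seasons), n_asvs))
    rc = relatedness.loc[individuals, individuals].to_numpy(dtype=float).copy()
    np.fill_diagonal(rc, 0.0)
    if config.sigma_kin > 0 or config.sigma_individual > 0:
        chol = _effect_cholesky(rc, config.sigma_individual, config.sigma_kin)
        i_eff = chol @ rng.standard_normal((len(individuals), n_asvs))
    else:
        i_eff = np.zeros((len(individuals), n_asvs))

    columns = {}
    for sid, row in metadata.samples.iterrows():
        lam = (
            base
            + g_eff[g_idx[row["group_id"]]]
            + i_eff[i_idx[row["individual_id"]]]
            + s_eff[t_idx[row["season_id"]]]
        )
        if config.sigma_sample > 0:
            lam = lam + rng.normal(0.0, config.sigma_sample, size=n_asvs)
        lam = lam - lam.max()
        p = np.exp(lam)
        p /= p.sum()
        depth = int(round(rng.lognormal(config.depth_log_mean, config.depth_log_sd)))
        depth = max(depth, 1)
        columns[sid] = rng.multinomial(depth, p)
    counts = pd.DataFrame(columns, index=pd.Index(tip_ids, name="asv_id"))
    if not return_effects:
        return counts
    effects = {
        "base": pd.Series(base, index=tip_ids),
        "group": pd.DataFrame(g_eff, index=groups, columns=tip_ids),
        "individual": pd.DataFrame(i_eff, index=individuals, columns=tip_ids),
        "season": pd.DataFrame(s_eff, index=seasons, columns=tip_ids),
    }
    return counts, effects


def generate_group_covariates(config: SimulationConfig, seed=None) -> dict:
    """Group-level environmental covariates.

    * ``habitat_profiles``: group x tree-species abundance counts (one
      forest inventory per home range),
    * ``habitat_dissimilarity``: Bray-Curtis over habitat profiles,
    * ``home_range_overlap``: symmetric overlap fractions per season,
    * ``diet_profiles``: group x plant-family relative abundances per
      season (Dirichlet draws around a season-specific base diet),
    * ``diet_dissimilarity``: Bray-Curtis over diet profiles per season.
    """
    rng = _rng(seed if seed is not None else config.seed)
    groups = [f"G{i + 1}" for i in range(config.n_groups)]
    n_species = 40
    habitat = pd.DataFrame(
        rng.negative_binomial(2, 0.05, size=(len(groups), n_species)),
        index=groups,
        columns=[f"tree{j + 1:02d}" for j in range(n_species)],
    )
    habitat_diss = bray_curtis_matrix(habitat)

    overlap, diet, diet_diss = {}, {}, {}
    n_families = 20
    for season in config.season_ids:
        m = rng.uniform(0.0, 0.6, size=(len(groups), len(groups)))
        m = (m + m.T) / 2.0
        np.fill_diagonal(m, 1.0)
        overlap[season] = pd.DataFrame(m, index=groups, columns=groups)
        base_diet = rng.dirichlet(np.full(n_families, 0.6))
        profiles = rng.dirichlet(base_diet * 50 + 0.1, size=len(groups))
        diet[season] = pd.DataFrame(
            profiles,
            index=groups,
            columns=[f"plantfam{j + 1:02d}" for j in range(n_families)],
        )
        diet_diss[season] = bray_curtis_matrix(diet[season])
    return {
        "habitat_profiles": habitat,
        "habitat_dissimilarity": habitat_diss,
        "home_range_overlap": overlap,
        "diet_profiles": diet,
        "diet_dissimilarity": diet_diss,
    }


def simulate_study(config: SimulationConfig | None = None, **overrides) -> SyntheticStudy:
    """Generate a complete synthetic study from one master seed.

    Stage seeds (tree, metadata, counts, covariates) are spawned from
    ``config.seed`` with :class:`numpy.random.SeedSequence`, so each
    artifact is reproducible independently of the others.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    children = np.random.SeedSequence(config.seed).spawn(4)
    rngs = [np.random.default_rng(c) for c in children]
    tree = generate_tree(config.n_asvs, seed=rngs[0])
    metadata, relatedness = generate_metadata(config, seed=rngs[1])
    counts, effects = generate_counts(
        metadata, tree, relatedness, config, seed=rngs[2], return_effects=True
    )
    covariates = generate_group_covariates(config, seed=rngs[3])
    return SyntheticStudy(
        counts=counts,
        tree=tree,
        metadata=metadata,
        relatedness=relatedness,
        true_effects=effects,
        group_covariates=covariates,
        config=config,
    )
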