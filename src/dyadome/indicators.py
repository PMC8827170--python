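"""Group-equalized indicator taxon analysis.

For each ASV and each candidate category (social group, age class, rank,
reproductive state) the association statistic is the group-equalized
point-biserial correlation r.g: the Pearson correlation between the ASV's
abundance and the 0/1 category membership computed after reweighting
samples so every category contributes equal total weight (weight
N / (K * n_k) for a sample of category k among K categories of sizes
n_k). With equal category sizes this reduces to the classic point-biserial
correlation; with unequal sizes it stops large categories from dominating.

Each ASV is assigned its best (argmax r.g) single category; significance
comes from a permutation null that relabels samples and recomputes the
max statistic. Associations with positive r.g below the significance
cut-off are reported, together with the summary fraction of ASVs uniquely
associated with one category. Input counts should be rarefied to a common
depth so abundance is comparable across samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import UndefinedValueError, ValidationError

logger = logging.getLogger("dyadome")

__all__ = [
    "point_biserial_rg",
    "indicator_analysis",
    "association_edges",
]


def _equalizing_weights(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample weights giving each category equal total weight N/K."""
    cats, inverse = np.unique(labels, return_inverse=True)
    counts = np.bincount(inverse)
    n, k = len(labels), len(cats)
    weights = (n / k) / counts[inverse]
    return weights, cats, inverse


def point_biserial_rg(abundance, membership, labels) -> float:
    """Group-equalized point-biserial correlation for one ASV/category.

    ``abundance`` is the per-sample abundance vector, ``membership`` the
    0/1 indicator of the target category, and ``labels`` the full
    category label vector (used to derive the equalizing weights).
    """
    a = np.asarray(abundance, dtype=float)
    x = np.asarray(membership, dtype=float)
    labels = np.asarray(labels)
    if not (len(a) == len(x) == len(labels)):
        raise ValidationError("abundance, membership, labels differ in length")
    if len(np.unique(labels)) < 2:
        raise ValidationError("need at least two categories")
    w, _, _ = _equalizing_weights(labels)
    sw = w.sum()
    am = (w * a).sum() / sw
    xm = (w * x).sum() / sw
    va = (w * (a - am) ** 2).sum() / sw
    vx = (w * (x - xm) ** 2).sum() / sw
    if va == 0:
        raise UndefinedValueError("abundance has zero variance")
    if vx == 0:
        raise UndefinedValueError("membership has zero variance")
    cov = (w * (a - am) * (x - xm)).sum() / sw
    return float(cov / np.sqrt(va * vx))


def _rg_matrix(abundances: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """r.g for every (ASV, category) pair; rows with zero abundance
    variance get NaN.

    ``abundances`` is (n_asvs, n_samples). Weighted moments are computed
    in closed form; under equalizing weights every category's weighted
    membership mean is 1/K exactly.
    """
    w, cats, inverse = _equalizing_weights(labels)
    k = len(cats)
    sw = w.sum()
    aw = abundances @ w / sw
    va = (abundances**2) @ w / sw - aw**2
    va = np.maximum(va, 0.0)
    # weighted cross-moment with each category indicator
    x_ind = np.zeros((len(labels), k))
    x_ind[np.arange(len(labels)), inverse] = 1.0
    cross = (abundances * w) @ x_ind / sw  # (n_asvs, k)
    xm = 1.0 / k
    vx = xm - xm**2
    cov = cross - np.outer(aw, np.full(k, xm))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.sqrt(np.outer(va, np.full(k, vx)))
    r[va == 0, :] = np.nan
    return r


def indicator_analysis(
    counts: pd.DataFrame,
    categories,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    min_category_size: int = 2,
) -> "IndicatorResult":
    """Best-category indicator analysis over all ASVs with permutation p.

    ``counts`` is a rarefied ASV x sample table; ``categories`` maps each
    sample (by column order or a pandas Series indexed by sample id) to a
    category label. For each ASV the observed statistic is the maximum
    r.g over categories; ``n_perm`` random relabellings (plus the
    observed data) give p = (1 + #{permuted max >= observed}) /
    (n_perm + 1). Associations with p < ``alpha`` and r.g > 0 are
    reported. Constant-abundance ASVs are skipped with a log entry;
    categories with fewer than ``min_category_size`` samples are excluded
    with a warning.
    """
    if isinstance(categories, pd.Series):
        labels = categories.loc[list(counts.columns)].to_numpy()
    else:
        labels = np.asarray(categories)
    if len(labels) != counts.shape[1]:
        raise ValidationError("one category label per sample required")
    keep = np.ones(len(labels), dtype=bool)
    cats, cat_counts = np.unique(labels, return_counts=True)
    for cat, cnt in zip(cats, cat_counts):
        if cnt < min_category_size:
            logger.warning(
                "indicator analysis: excluding category %r with %d sample(s)", cat, cnt
            )
            keep &= labels != cat
    labels = labels[keep]
    table = counts.loc[:, keep]
    if len(np.unique(labels)) < 2:
        raise ValidationError("need at least two categories with enough samples")

    abundances = table.to_numpy(dtype=float)
    n_asvs = abundances.shape[0]
    r_obs = _rg_matrix(abundances, labels)
    constant = np.isnan(r_obs).all(axis=1)
    if constant.any():
        logger.info(
            "indicator analysis: skipping %d constant-abundance ASV(s)",
            int(constant.sum()),
        )
    best_idx = np.full(n_asvs, -1)
    best_stat = np.full(n_asvs, np.nan)
    ok = ~constant
    if ok.any():
        best_idx[ok] = np.nanargmax(r_obs[ok], axis=1)
        best_stat[ok] = np.nanmax(r_obs[ok], axis=1)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_asvs)
    for _ in range(n_perm):
        perm_labels = labels[rng.permutation(len(labels))]
        r_perm = _rg_matrix(abundances, perm_labels)
        perm_max = np.nanmax(np.where(np.isnan(r_perm), -np.inf, r_perm), axis=1)
        exceed += perm_max >= best_stat - 1e-12
    p = (1.0 + exceed) / (n_perm + 1.0)
    p[constant] = np.nan

    rel = abundances / abundances.sum(axis=0, keepdims=True)
    mean_rel = rel.mean(axis=1)

    cat_values = np.unique(labels)
    finite = np.isfinite(p)
    fdr = np.full(n_asvs, np.nan)
    if finite.any():
        fdr[finite] = multipletests(p[finite], method="fdr_bh")[1]
    result_table = pd.DataFrame(
        {
            "asv_id": table.index,
            "category": [
                cat_values[i] if i >= 0 else None for i in best_idx
            ],
            "r_g": best_stat,
            "p_value": p,
            "p_fdr": fdr,
            "mean_relative_abundance": mean_rel,
        }
    ).set_index("asv_id")
    significant = result_table[
        (result_table["p_value"] < alpha) & (result_table["r_g"] > 0)
    ].copy()
    return IndicatorResult(
        table=result_table,
        associations=significant,
        alpha=alpha,
        n_perm=n_perm,
        fraction_associated=len(significant) / n_asvs,
    )


class IndicatorResult:
    """All-ASV statistics plus the significant positive associations.

    ``fraction_associated`` is the summary "% of all taxa uniquely
    associated with one category" (as a fraction).
    """

    def __init__(self, table, associations, alpha, n_perm, fraction_associated):
        self.table = table
        self.associations = associations
        self.alpha = alpha
        self.n_perm = n_perm
        self.fraction_associated = fraction_associated

    def __repr__(self):
        return (
            f"IndicatorResult({len(self.associations)}/{len(self.table)} ASVs "
            f"associated at p<{self.alpha}; fraction="
            f"{self.fraction_associated:.4f})"
        )


def association_edges(result) -> pd.DataFrame:
    """Category -> ASV edge list for network tools.

    Accepts an :class:`IndicatorResult` or its ``associations`` frame;
    returns a table with columns (category, asv, weight, p_value,
    mean_relative_abundance), weights equal to r.g.
    """
    assoc = result.associations if isinstance(result, IndicatorResult) else result
    edges = pd.DataFrame(
        {
            "category": assoc["category"].to_numpy() if len(assoc) else [],
            "asv": assoc.index.to_numpy() if len(assoc) else [],
            "weight": assoc["r_g"].to_numpy() if len(assoc) else [],
            "p_value": assoc["p_value"].to_numpy() if len(assoc) else [],
            "mean_relative_abundance": (
                assoc["mean_relative_abundance"].to_numpy() if len(assoc) else []
            ),
        }
    )
    return edges
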