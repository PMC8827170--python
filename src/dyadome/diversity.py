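"""Phylogenetic alpha and beta diversity: Faith's PD, generalized UniFrac,
and Bray-Curtis dissimilarity.

The central object is the *branch profile*: for every edge ``i`` of the
rooted tree, its length ``b_i`` and, per sample ``A``, the proportion
``p_i^A`` of the sample's total abundance carried by tips below the edge.
The generalized UniFrac distance between samples ``A`` and ``B`` is then

    d_alpha(A, B) = sum_i b_i (p_i^A + p_i^B)^alpha |p_i^A - p_i^B| / (p_i^A + p_i^B)
                    -----------------------------------------------------------------
                    sum_i b_i (p_i^A + p_i^B)^alpha

summing only over edges with ``p_i^A + p_i^B > 0``. ``alpha`` interpolates
between abundance-insensitive (alpha -> 0) and fully weighted (alpha = 1)
variants; ``alpha = 0.5`` is the common compromise and the default here.
Faith's PD is the total branch length of the subtree spanning a sample's
observed tips (by default including the path to the root).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio

from .core import UndefinedValueError, ValidationError

__all__ = [
    "BranchMatrix",
    "BranchProfile",
    "branch_matrix",
    "branch_profiles",
    "faith_pd",
    "alpha_diversity_table",
    "gunifrac",
    "pairwise_distance_matrix",
    "bray_curtis",
    "bray_curtis_matrix",
]


@dataclass
class BranchMatrix:
    """Edge decomposition of a rooted tree.

    ``lengths[e]`` is the branch length of edge ``e`` (the edge above each
    non-root node, in postorder); ``tip_membership[e, t]`` is True when tip
    ``t`` descends from edge ``e``; ``tip_ids`` fixes the tip order.
    """

    lengths: np.ndarray
    tip_membership: np.ndarray
    tip_ids: list
    depths: np.ndarray  # distance from root to the child node of each edge

    @property
    def n_edges(self) -> int:
        return len(self.lengths)


@dataclass
class BranchProfile:
    """Branch lengths plus one sample's per-edge descendant proportions."""

    lengths: np.ndarray
    proportions: np.ndarray

    def __post_init__(self):
        if len(self.lengths) != len(self.proportions):
            raise ValidationError("branch profile arrays differ in length")


def branch_matrix(tree: skbio.TreeNode) -> BranchMatrix:
    """Decompose a rooted tree into edges with descendant-tip indicators."""
    tips = list(tree.tips())
    if not tips:
        raise ValidationError("tree has no tips")
    tip_ids = [t.name for t in tips]
    tip_index = {id(t): k for k, t in enumerate(tips)}
    n_tips = len(tips)

    lengths, rows, depths = [], [], []
    membership_of = {}
    # Postorder so each node's tip set is the union of its children's.
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            mask = np.zeros(n_tips, dtype=bool)
            mask[tip_index[id(node)]] = True
        else:
            mask = np.zeros(n_tips, dtype=bool)
            for child in node.children:
                mask |= membership_of[id(child)]
        membership_of[id(node)] = mask
        if node is not tree:  # the root has no edge above it
            lengths.append(float(node.length or 0.0))
            rows.append(mask)
    # Depths need a preorder pass.
    depth_of = {id(tree): float(tree.length or 0.0)}
    order = []
    for node in tree.preorder(include_self=False):
        depth_of[id(node)] = depth_of[id(node.parent)] + float(node.length or 0.0)
    # Align depths with the postorder edge list.
    for node in tree.postorder(include_self=False):
        order.append(depth_of[id(node)])
    return BranchMatrix(
        lengths=np.asarray(lengths, dtype=float),
        tip_membership=np.asarray(rows, dtype=bool),
        tip_ids=tip_ids,
        depths=np.asarray(order, dtype=float),
    )


def _align_counts(counts: pd.DataFrame, bm: BranchMatrix) -> np.ndarray:
    """Counts (ASV x sample) reordered to the branch matrix tip order.

    Every ASV in the table must be a tree tip; tips with no counts get
    zero rows.
    """
    missing = set(counts.index) - set(bm.tip_ids)
    if missing:
        raise ValidationError(
            f"ASVs absent from the tree: {sorted(missing)[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    aligned = counts.reindex(bm.tip_ids).fillna(0.0)
    return aligned.to_numpy(dtype=float)


def branch_profiles(
    counts: pd.DataFrame, tree: skbio.TreeNode, bm: BranchMatrix | None = None
) -> tuple[BranchMatrix, np.ndarray]:
    """Per-edge descendant proportions for every sample.

    Returns the branch matrix and an ``(n_edges, n_samples)`` array of
    ``p_i`` values; each sample's abundances are first converted to
    within-sample proportions, so any (positive) normalization of the
    counts leaves the result unchanged.
    """
    bm = bm or branch_matrix(tree)
    x = _align_counts(counts, bm)
    totals = x.sum(axis=0)
    if np.any(totals <= 0):
        bad = [counts.columns[i] for i in np.where(totals <= 0)[0]]
        raise UndefinedValueError(f"samples with zero total abundance: {bad}")
    props = x / totals
    return bm, bm.tip_membership.astype(float) @ props


def faith_pd(
    counts_row,
    tree: skbio.TreeNode,
    include_root_path: bool = True,
) -> float:
    """Faith's phylogenetic diversity of one sample.

    ``counts_row`` is a mapping / Series of abundances keyed by tip id
    (presence is what matters). The result is the total branch length of
    the minimal subtree spanning the observed tips; with
    ``include_root_path`` (default) the subtree is anchored at the root,
    otherwise the unbranched path from the root down to the crown of the
    observed tips is excluded (a single observed tip then contributes just
    its own pendant edge).
    """
    row = pd.Series(counts_row, dtype=float)
    present = [str(k) for k, v in row.items() if v > 0]
    if not present:
        raise UndefinedValueError("sample has no observed ASVs")
    bm = branch_matrix(tree)
    present_set = set(present)
    missing = present_set - set(bm.tip_ids)
    if missing:
        raise ValidationError(f"observed ASVs absent from tree: {sorted(missing)}")
    mask = np.array([tid in present_set for tid in bm.tip_ids])
    has_present = bm.tip_membership[:, mask].any(axis=1)
    total = float(bm.lengths[has_present].sum())
    if include_root_path:
        return total
    # Subtract the root-to-crown path. For >=2 tips the crown is their
    # lowest common ancestor; for a single tip it is the tip's parent so
    # the pendant edge itself is kept.
    if len(present) == 1:
        tip = tree.find(present[0])
        crown = tip.parent
    else:
        crown = tree.lca(present)
    depth = 0.0
    node = crown
    while node is not None and node.parent is not None:
        depth += float(node.length or 0.0)
        node = node.parent
    return total - depth


def alpha_diversity_table(
    counts: pd.DataFrame, tree: skbio.TreeNode, include_root_path: bool = True
) -> pd.DataFrame:
    """Per-sample Faith's PD and observed-ASV richness.

    Vectorized over samples; equivalent to calling :func:`faith_pd` per
    column.
    """
    bm = branch_matrix(tree)
    x = _align_counts(counts, bm)
    present = x > 0
    pd_values = np.empty(counts.shape[1])
    membership = bm.tip_membership
    for j in range(counts.shape[1]):
        has = membership[:, present[:, j]].any(axis=1)
        pd_values[j] = bm.lengths[has].sum()
        if not include_root_path:
            tips = [bm.tip_ids[k] for k in np.where(present[:, j])[0]]
            if not tips:
                continue
            if len(tips) == 1:
                crown = tree.find(tips[0]).parent
            else:
                crown = tree.lca(tips)
            depth, node = 0.0, crown
            while node is not None and node.parent is not None:
                depth += float(node.length or 0.0)
                node = node.parent
            pd_values[j] -= depth
    return pd.DataFrame(
        {
            "faith_pd": pd_values,
            "observed_asvs": present.sum(axis=0),
        },
        index=counts.columns,
    )


def _check_alpha(alpha: float) -> float:
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"gunifrac alpha must be in [0, 1], got {alpha}")
    return float(alpha)


def gunifrac(a: BranchProfile, b: BranchProfile, alpha: float = 0.5) -> float:
    """Generalized UniFrac distance between two branch profiles."""
    alpha = _check_alpha(alpha)
    if len(a.lengths) != len(b.lengths) or not np.allclose(a.lengths, b.lengths):
        raise ValidationError("branch profiles come from different trees")
    pa, pb, lengths = a.proportions, b.proportions, a.lengths
    s = pa + pb
    support = s > 0
    if not support.any():
        raise UndefinedValueError("both samples empty on every branch")
    s, pa, pb = s[support], pa[support], pb[support]
    w = lengths[support] * s**alpha
    num = float((w * np.abs(pa - pb) / s).sum())
    den = float(w.sum())
    if den == 0.0:
        raise UndefinedValueError("zero total branch weight")
    return num / den


def pairwise_distance_matrix(
    counts: pd.DataFrame, tree: skbio.TreeNode, alpha: float = 0.5
) -> skbio.DistanceMatrix:
    """Sample-by-sample generalized UniFrac distance matrix.

    Semantically identical to applying :func:`gunifrac` to every pair;
    computed with one pass over the branch-profile matrix per sample.
    """
    alpha = _check_alpha(alpha)
    _, profiles = branch_profiles(counts, tree)
    lengths = branch_matrix(tree).lengths
    n = profiles.shape[1]
    out = np.zeros((n, n))
    for i in range(n - 1):
        pa = profiles[:, i : i + 1]
        pb = profiles[:, i + 1 :]
        s = pa + pb
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(s > 0, np.abs(pa - pb) / np.where(s > 0, s, 1.0), 0.0)
            w = np.where(s > 0, lengths[:, None] * s**alpha, 0.0)
        num = (w * ratio).sum(axis=0)
        den = w.sum(axis=0)
        if np.any(den == 0):
            raise UndefinedValueError("pair of samples with zero branch weight")
        out[i, i + 1 :] = num / den
        out[i + 1 :, i] = out[i, i + 1 :]
    return skbio.DistanceMatrix(out, ids=[str(c) for c in counts.columns])


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity between two non-negative abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors differ in length")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("abundances must be non-negative")
    denom = float((x + y).sum())
    if denom == 0.0:
        raise UndefinedValueError("both abundance vectors are all-zero")
    return float(np.abs(x - y).sum()) / denom


def bray_curtis_matrix(profiles: pd.DataFrame) -> skbio.DistanceMatrix:
    """Pairwise Bray-Curtis over the rows of a unit-by-feature table."""
    values = profiles.to_numpy(dtype=float)
    n = values.shape[0]
    out = np.zeros((n, n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(values[i], values[j])
    return skbio.DistanceMatrix(out, ids=[str(i) for i in profiles.index])
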