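"""Group-membership permutation tests on distance matrices.

The group test asks whether samples from members of the same social group
are more similar than samples from different groups. Its statistic is the
difference of two means over sample pairs,

    stat = mean(d | different group) - mean(d | same group),

with pairs of samples from the *same individual* excluded from the
within-group mean by default (self-similarity is a separate question).
Because individuals are sampled repeatedly, sample labels are not
exchangeable: the null distribution is built by reassigning whole
*individuals* to groups — every sample of an individual moves with it —
uniformly over assignments that preserve the observed number of
individuals per group. The observed data count as one permutation and the
p-value is the proportion of permutations with a statistic at least as
large (one-tailed; group structure predicts a positive statistic).

When the number of distinct reassignments is small the test enumerates
them all and the p-value is exact.

:func:`mantel_pearson` is the classic Mantel test (Pearson correlation of
two distance matrices' upper triangles, label-permutation null), used for
the group-level habitat/diet comparisons.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import skbio

from .core import StudyMetadata, UndefinedValueError, ValidationError

__all__ = [
    "PermutationTestResult",
    "group_membership_stat",
    "restricted_group_test",
    "per_season_group_tests",
    "mantel_pearson",
]

_TIE_TOL = 1e-12


@dataclass
class PermutationTestResult:
    """Observed statistic, permutation null, and p-value.

    ``null_stats`` includes the observed statistic as one entry, so
    ``p_value >= 1 / n_perm`` always.
    """

    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    n_perm: int
    mode: str  # "monte-carlo" or "exhaustive"
    mean_within: float = float("nan")
    mean_between: float = float("nan")
    seed: int | None = None
    two_sided: bool = False
    extra: dict = field(default_factory=dict)

    def __str__(self) -> str:
        lines = [
            f"observed statistic : {self.observed_stat:.6g}",
            f"p-value            : {self.p_value:.6g} ({self.mode}, n_perm={self.n_perm})",
        ]
        if not math.isnan(self.mean_within):
            lines.insert(1, f"mean within groups : {self.mean_within:.6g}")
            lines.insert(2, f"mean between groups: {self.mean_between:.6g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# individual-level aggregation of a sample distance matrix


def _individual_pair_sums(d: skbio.DistanceMatrix, individuals):
    """Sum and count of sample-pair distances per individual pair.

    Returns (unique individuals, S, C) where for i != j, S[i, j] is the
    sum over all cross pairs of samples of i and j, and for i == j the sum
    over unordered distinct sample pairs of i; C holds the corresponding
    pair counts.
    """
    ind = np.asarray(individuals)
    uniq, inverse = np.unique(ind, return_inverse=True)
    n = len(uniq)
    member = np.zeros((n, len(ind)))
    member[inverse, np.arange(len(ind))] = 1.0
    sizes = member.sum(axis=1)
    s_full = member @ d.data @ member.T
    c_full = np.outer(sizes, sizes)
    s = s_full.copy()
    c = c_full.copy()
    np.fill_diagonal(s, np.diag(s_full) / 2.0)
    np.fill_diagonal(c, sizes * (sizes - 1) / 2.0)
    return uniq, s, c


def _stat_from_assignment(s, c, group_codes, exclude_same_individual=True):
    """Group statistic given per-individual-pair sums and group codes."""
    n = s.shape[0]
    iu = np.triu_indices(n, 1)
    same = group_codes[iu[0]] == group_codes[iu[1]]
    s_off, c_off = s[iu], c[iu]
    sw, cw = s_off[same].sum(), c_off[same].sum()
    if not exclude_same_individual:
        sw += np.diag(s).sum()
        cw += np.diag(c).sum()
    sb, cb = s_off[~same].sum(), c_off[~same].sum()
    if cw == 0:
        raise UndefinedValueError("no eligible within-group sample pairs")
    if cb == 0:
        raise UndefinedValueError("no between-group sample pairs")
    mean_within = sw / cw
    mean_between = sb / cb
    return mean_between - mean_within, mean_within, mean_between


def group_membership_stat(
    d: skbio.DistanceMatrix,
    meta: StudyMetadata,
    exclude_same_individual: bool = True,
):
    """Observed group statistic: (stat, mean_within, mean_between)."""
    individuals = meta.sample_individuals(d.ids)
    groups_of_sample = meta.sample_groups(d.ids)
    uniq, s, c = _individual_pair_sums(d, individuals)
    group_of_ind = {}
    for ind, grp in zip(individuals, groups_of_sample):
        group_of_ind[ind] = grp
    codes = np.array([group_of_ind[u] for u in uniq])
    if len(set(codes)) < 2:
        raise ValidationError("group test needs at least two groups")
    _, codes_int = np.unique(codes, return_inverse=True)
    return _stat_from_assignment(s, c, codes_int, exclude_same_individual)


# ---------------------------------------------------------------------------
# restricted permutation test


def _n_distinct_partitions(sizes) -> int:
    """Number of distinct partitions of n individuals into groups of the
    given sizes, with groups of equal size interchangeable."""
    n = sum(sizes)
    count = math.factorial(n)
    for s in sizes:
        count //= math.factorial(s)
    for mult in Counter(sizes).values():
        count //= math.factorial(mult)
    return count


def _equal_blocks(pool, size, m):
    """Partitions of ``pool`` into ``m`` unlabelled blocks of equal
    ``size``; each block anchors the smallest remaining element, which
    makes every partition appear exactly once."""
    if m == 0:
        yield []
        return
    first, rest = pool[0], pool[1:]
    for extra in itertools.combinations(rest, size - 1):
        block = (first,) + extra
        block_set = set(block)
        left = [x for x in rest if x not in block_set]
        for tail in _equal_blocks(left, size, m - 1):
            yield [block] + tail


def _enumerate_partitions(n: int, sizes):
    """All distinct partitions of range(n) into unlabelled groups of the
    given sizes, as arrays of group codes.

    Size classes (distinct size values) are handled in turn: first the
    elements belonging to the class are chosen, then split into equal
    blocks with an anchoring rule so interchangeable blocks are not
    double-counted.
    """
    classes = sorted(Counter(sizes).items(), reverse=True)  # (size, multiplicity)

    def recurse(elements, class_list):
        if not class_list:
            yield []
            return
        size, mult = class_list[0]
        for subset in itertools.combinations(elements, size * mult):
            subset_set = set(subset)
            rest = [x for x in elements if x not in subset_set]
            for blocks in _equal_blocks(list(subset), size, mult):
                for tail in recurse(rest, class_list[1:]):
                    yield blocks + tail

    for blocks in recurse(list(range(n)), classes):
        codes = np.empty(n, dtype=int)
        for code, block in enumerate(blocks):
            for idx in block:
                codes[idx] = code
        yield codes


def restricted_group_test(
    d: skbio.DistanceMatrix,
    meta: StudyMetadata,
    n_perm: int = 1000,
    seed: int | None = None,
    mode: str = "auto",
    exclude_same_individual: bool = True,
    two_sided: bool = False,
) -> PermutationTestResult:
    """Block-restricted permutation test of group membership.

    All samples of one individual are permuted as a block: each
    permutation reassigns individuals to groups uniformly at random among
    assignments preserving the observed per-group individual counts. With
    ``mode="auto"`` the test enumerates all distinct assignments
    exhaustively when there are at most ``n_perm`` of them (exact p);
    otherwise it draws ``n_perm - 1`` Monte-Carlo assignments and counts
    the observed data as one permutation.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    if mode not in ("auto", "exhaustive", "monte-carlo"):
        raise ValueError(f"unknown mode {mode!r}")
    individuals = meta.sample_individuals(d.ids)
    groups_of_sample = meta.sample_groups(d.ids)
    uniq, s, c = _individual_pair_sums(d, individuals)
    group_of_ind = dict(zip(individuals, groups_of_sample))
    observed_groups = np.array([group_of_ind[u] for u in uniq])
    group_labels, observed_codes = np.unique(observed_groups, return_inverse=True)
    if len(group_labels) < 2:
        raise ValidationError("group test needs at least two groups")
    sizes = np.bincount(observed_codes)
    n_ind = len(uniq)

    obs_stat, mean_within, mean_between = _stat_from_assignment(
        s, c, observed_codes, exclude_same_individual
    )

    def score(stat):
        return abs(stat) if two_sided else stat

    n_distinct = _n_distinct_partitions(sizes.tolist())
    exhaustive = mode == "exhaustive" or (mode == "auto" and n_distinct <= n_perm)

    stats = []
    if exhaustive:
        for codes in _enumerate_partitions(n_ind, sizes.tolist()):
            stat, _, _ = _stat_from_assignment(s, c, codes, exclude_same_individual)
            stats.append(stat)
        used_mode = "exhaustive"
    else:
        rng = np.random.default_rng(seed)
        stats.append(obs_stat)
        order = np.arange(n_ind)
        # assignment template: first sizes[0] individuals -> group 0, etc.
        template = np.repeat(np.arange(len(sizes)), sizes)
        codes = np.empty(n_ind, dtype=int)
        for _ in range(n_perm - 1):
            rng.shuffle(order)
            codes[order] = template
            stat, _, _ = _stat_from_assignment(s, c, codes, exclude_same_individual)
            stats.append(stat)
        used_mode = "monte-carlo"

    stats = np.asarray(stats)
    observed_score = score(obs_stat)
    null_scores = np.abs(stats) if two_sided else stats
    p = float(np.mean(null_scores >= observed_score - _TIE_TOL))
    return PermutationTestResult(
        observed_stat=float(obs_stat),
        null_stats=stats,
        p_value=p,
        n_perm=len(stats),
        mode=used_mode,
        mean_within=float(mean_within),
        mean_between=float(mean_between),
        seed=seed,
        two_sided=two_sided,
        extra={"n_individuals": n_ind, "n_samples": len(d.ids)},
    )


def per_season_group_tests(
    d: skbio.DistanceMatrix,
    meta: StudyMetadata,
    n_perm: int = 1000,
    seed: int | None = None,
    **kwargs,
) -> dict:
    """Run the restricted group test separately within each field season."""
    seasons = meta.sample_seasons(d.ids)
    results = {}
    children = np.random.SeedSequence(seed).spawn(len(meta.seasons))
    for child, season in zip(children, meta.seasons):
        ids = [sid for sid, t in zip(d.ids, seasons) if t == season]
        if len(ids) < 3:
            continue
        sub = d.filter(ids)
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        results[season] = restricted_group_test(
            sub, meta, n_perm=n_perm, seed=sub_seed, **kwargs
        )
    return results


# ---------------------------------------------------------------------------
# Mantel


def mantel_pearson(
    d1: skbio.DistanceMatrix,
    d2: skbio.DistanceMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
    mode: str = "auto",
) -> PermutationTestResult:
    """Mantel test: Pearson correlation of two distance matrices.

    The observed statistic is the Pearson correlation of the two upper
    triangles (matrices aligned by label); the null relabels one matrix
    with random label permutations. Two-sided p, observed included; when
    the number of distinct label permutations is at most ``n_perm``, all
    of them are enumerated and the p-value is exact.
    """
    if set(d1.ids) != set(d2.ids):
        raise ValidationError("distance matrices have different labels")
    if len(d1.ids) < 3:
        raise ValidationError("Mantel test needs at least three units")
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    d2 = d2.filter(d1.ids)  # align label order
    n = len(d1.ids)
    iu = np.triu_indices(n, 1)
    x = d1.data[iu]

    def corr_with(perm):
        y = d2.data[np.ix_(perm, perm)][iu]
        sy = y.std()
        if sy == 0:
            raise UndefinedValueError("zero variance in permuted triangle")
        return float(np.corrcoef(x, y)[0, 1])

    sx = x.std()
    y0 = d2.data[iu]
    if sx == 0 or y0.std() == 0:
        raise UndefinedValueError("zero variance in a distance-matrix triangle")
    identity = np.arange(n)
    r_obs = corr_with(identity)

    exhaustive = mode == "exhaustive" or (
        mode == "auto" and math.factorial(n) <= n_perm
    )
    stats = []
    if exhaustive:
        for perm in itertools.permutations(range(n)):
            stats.append(corr_with(np.array(perm)))
        used_mode = "exhaustive"
    else:
        rng = np.random.default_rng(seed)
        stats.append(r_obs)
        for _ in range(n_perm - 1):
            stats.append(corr_with(rng.permutation(n)))
        used_mode = "monte-carlo"
    stats = np.asarray(stats)
    p = float(np.mean(np.abs(stats) >= abs(r_obs) - _TIE_TOL))
    return PermutationTestResult(
        observed_stat=r_obs,
        null_stats=stats,
        p_value=p,
        n_perm=len(stats),
        mode=used_mode,
        seed=seed,
        two_sided=True,
        extra={"n_units": n},
    )
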