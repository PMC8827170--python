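"""Restricted block-permutation group test and Mantel correlations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import skbio

import dyadome as dy
from dyadome.core import UndefinedValueError, ValidationError
from dyadome.permutation import _enumerate_partitions, _n_distinct_partitions

from conftest import make_metadata


class TestGroupStatistic:
    def test_two_group_toy(self, two_group_toy):
        d, meta = two_group_toy
        stat, mean_within, mean_between = dy.group_membership_stat(d, meta)
        assert (stat, mean_within, mean_between) == pytest.approx((0.8, 0.1, 0.9))

    def test_constant_matrix_zero_stat(self):
        ids = ["s1", "s2", "s3", "s4"]
        m = np.full((4, 4), 0.3)
        np.fill_diagonal(m, 0.0)
        d = skbio.DistanceMatrix(m, ids=ids)
        meta = make_metadata(
            {"s1": ("a", "g1"), "s2": ("b", "g1"), "s3": ("c", "g2"), "s4": ("d", "g2")}
        )
        stat, _, _ = dy.group_membership_stat(d, meta)
        assert stat == pytest.approx(0.0)

    def test_same_individual_pairs_excluded_by_default(self):
        # individual a has two samples at distance 0; including them would
        # drag the within mean down
        ids = ["a1", "a2", "b1", "c1"]
        m = np.array(
            [
                [0.0, 0.0, 0.4, 0.8],
                [0.0, 0.0, 0.4, 0.8],
                [0.4, 0.4, 0.0, 0.8],
                [0.8, 0.8, 0.8, 0.0],
            ]
        )
        d = skbio.DistanceMatrix(m, ids=ids)
        meta = make_metadata(
            {"a1": ("a", "g1"), "a2": ("a", "g1"), "b1": ("b", "g1"), "c1": ("c", "g2")}
        )
        _, mean_within, _ = dy.group_membership_stat(d, meta)
        assert mean_within == pytest.approx(0.4)
        _, mean_within_incl, _ = dy.group_membership_stat(
            d, meta, exclude_same_individual=False
        )
        assert mean_within_incl == pytest.approx(0.8 / 3)


class TestPartitionEnumeration:
    @pytest.mark.parametrize(
        "sizes", [(2, 2), (3, 2), (2, 2, 2), (3, 3, 1), (4, 2, 2)]
    )
    def test_count_matches_closed_form(self, sizes):
        parts = list(_enumerate_partitions(sum(sizes), list(sizes)))
        assert len(parts) == _n_distinct_partitions(list(sizes))
        # all partitions distinct as set-partitions
        keys = set()
        for codes in parts:
            blocks = frozenset(
                frozenset(np.where(codes == g)[0]) for g in np.unique(codes)
            )
            keys.add(blocks)
        assert len(keys) == len(parts)

    def test_sizes_preserved(self):
        for codes in _enumerate_partitions(7, [3, 2, 2]):
            assert sorted(np.bincount(codes).tolist()) == [2, 2, 3]


class TestRestrictedGroupTest:
    def test_exhaustive_toy_exact_p(self, two_group_toy):
        d, meta = two_group_toy
        res = dy.restricted_group_test(d, meta, n_perm=1000, seed=0)
        assert res.mode == "exhaustive"
        assert res.observed_stat == pytest.approx(0.8)
        assert res.p_value == pytest.approx(1 / 3)
        assert sorted(np.round(res.null_stats, 10)) == pytest.approx([-0.4, -0.4, 0.8])

    def test_constant_matrix_p_one(self):
        ids = [f"s{i}" for i in range(6)]
        m = np.full((6, 6), 0.5)
        np.fill_diagonal(m, 0.0)
        d = skbio.DistanceMatrix(m, ids=ids)
        meta = make_metadata(
            {f"s{i}": (f"i{i}", "g1" if i < 3 else "g2") for i in range(6)}
        )
        res = dy.restricted_group_test(d, meta, n_perm=50, seed=1)
        assert res.p_value == 1.0

    def test_p_at_least_one_over_nperm(self, small_study):
        d = dy.pairwise_distance_matrix(small_study.counts, small_study.tree)
        res = dy.restricted_group_test(d, small_study.metadata, n_perm=49, seed=2,
                                       mode="monte-carlo")
        assert res.p_value >= 1 / res.n_perm

    def test_label_invariance(self, two_group_toy):
        d, meta = two_group_toy
        order = ["sc", "sa", "sd", "sb"]
        d_perm = d.filter(order)
        res = dy.restricted_group_test(d, meta, n_perm=1000, seed=3)
        res_perm = dy.restricted_group_test(d_perm, meta, n_perm=1000, seed=4)
        assert res.observed_stat == pytest.approx(res_perm.observed_stat)
        assert res.p_value == pytest.approx(res_perm.p_value)

    def test_monte_carlo_agrees_with_exhaustive(self, small_study):
        d = dy.pairwise_distance_matrix(small_study.counts, small_study.tree)
        season = small_study.metadata.seasons[0]
        keep = [
            sid
            for sid in d.ids
            if small_study.metadata.samples.loc[sid, "season_id"] == season
        ]
        sub = d.filter(keep)
        exact = dy.restricted_group_test(
            sub, small_study.metadata, n_perm=10**6, mode="exhaustive"
        )
        mc = dy.restricted_group_test(
            sub, small_study.metadata, n_perm=4000, seed=5, mode="monte-carlo"
        )
        se = math.sqrt(exact.p_value * (1 - exact.p_value) / 4000)
        assert abs(mc.p_value - exact.p_value) < 4 * se + 1e-3

    def test_nperm_contract(self, two_group_toy):
        d, meta = two_group_toy
        with pytest.raises(ValueError):
            dy.restricted_group_test(d, meta, n_perm=1)

    def test_block_restriction_controls_type_one_error(self):
        """With correlated repeat samples per individual and random groups,
        the restricted test stays calibrated while a naive sample-level
        permutation anti-conservatively inflates (direction-only check)."""
        rng = np.random.default_rng(6)
        n_ind, n_rep = 8, 3
        n = n_ind * n_rep
        inds = np.repeat(np.arange(n_ind), n_rep)
        rejections_restricted = rejections_naive = 0
        n_sims = 40
        for _ in range(n_sims):
            ind_pos = rng.normal(0, 1.0, size=n_ind)
            pos = ind_pos[inds] + rng.normal(0, 0.1, size=n)
            m = np.abs(pos[:, None] - pos[None, :])
            ids = [f"s{i}" for i in range(n)]
            d = skbio.DistanceMatrix(m, ids=ids)
            groups = np.repeat(["g1", "g2"], n_ind // 2)[rng.permutation(n_ind)]
            meta = make_metadata(
                {ids[i]: (f"i{inds[i]}", groups[inds[i]]) for i in range(n)}
            )
            res = dy.restricted_group_test(d, meta, n_perm=99, seed=int(rng.integers(2**31)),
                                           mode="monte-carlo")
            rejections_restricted += res.p_value <= 0.05
            # naive oracle: permute sample labels freely
            obs, *_ = dy.group_membership_stat(d, meta)
            grp = meta.sample_groups(ids)
            count = 0
            for _ in range(99):
                perm = rng.permutation(n)
                gperm = grp[perm]
                iu = np.triu_indices(n, 1)
                same = gperm[iu[0]] == gperm[iu[1]]
                same_ind = inds[iu[0]] == inds[iu[1]]
                vals = m[iu]
                stat = vals[~same & ~same_ind].mean() - vals[same & ~same_ind].mean()
                count += stat >= obs - 1e-12
            p_naive = (1 + count) / 100
            rejections_naive += p_naive <= 0.05
        assert rejections_naive > rejections_restricted
        assert rejections_restricted / n_sims < 0.2


class TestMantel:
    def _toy_pair(self):
        m1 = np.zeros((4, 4))
        vals = iter([1, 2, 3, 4, 5, 6])
        for i in range(4):
            for j in range(i + 1, 4):
                m1[i, j] = m1[j, i] = next(vals)
        ids = ["u1", "u2", "u3", "u4"]
        d1 = skbio.DistanceMatrix(m1, ids=ids)
        d2 = skbio.DistanceMatrix(2 * m1, ids=ids)
        return d1, d2

    def test_identical_matrices_r_one(self):
        d1, _ = self._toy_pair()
        res = dy.mantel_pearson(d1, d1, n_perm=100, seed=0)
        assert res.observed_stat == pytest.approx(1.0)

    def test_exhaustive_p_matches_enumeration_oracle(self):
        d1, d2 = self._toy_pair()
        res = dy.mantel_pearson(d1, d2, n_perm=1000, seed=0)
        assert res.mode == "exhaustive"
        assert res.observed_stat == pytest.approx(1.0)
        # independent enumeration oracle over all 4! relabellings
        iu = np.triu_indices(4, 1)
        x = d1.data[iu]
        count = total = 0
        for perm in itertools.permutations(range(4)):
            y = d2.data[np.ix_(perm, perm)][iu]
            r = np.corrcoef(x, y)[0, 1]
            count += abs(r) >= 1.0 - 1e-12
            total += 1
        assert res.p_value == pytest.approx(count / total)
        assert res.n_perm == 24

    def test_agreement_with_skbio_statistic(self):
        rng = np.random.default_rng(7)
        m1 = np.abs(rng.normal(size=(6, 6)))
        m1 = (m1 + m1.T) / 2
        np.fill_diagonal(m1, 0)
        m2 = np.abs(rng.normal(size=(6, 6)))
        m2 = (m2 + m2.T) / 2
        np.fill_diagonal(m2, 0)
        ids = [f"u{i}" for i in range(6)]
        d1, d2 = skbio.DistanceMatrix(m1, ids=ids), skbio.DistanceMatrix(m2, ids=ids)
        res = dy.mantel_pearson(d1, d2, n_perm=99, seed=1)
        r_skbio, _, _ = skbio.stats.distance.mantel(
            d1, d2, method="pearson", permutations=0
        )
        assert res.observed_stat == pytest.approx(float(r_skbio), abs=1e-12)

    def test_zero_variance_rejected(self):
        m = np.full((4, 4), 0.5)
        np.fill_diagonal(m, 0.0)
        ids = ["u1", "u2", "u3", "u4"]
        d_const = skbio.DistanceMatrix(m, ids=ids)
        d1, _ = self._toy_pair()
        with pytest.raises(UndefinedValueError):
            dy.mantel_pearson(d1, d_const, n_perm=99, seed=0)

    def test_label_mismatch_rejected(self):
        d1, _ = self._toy_pair()
        other = skbio.DistanceMatrix(np.zeros((3, 3)), ids=["a", "b", "c"])
        with pytest.raises(ValidationError):
            dy.mantel_pearson(d1, other)


class TestPerSeason:
    def test_one_result_per_season(self, small_study):
        d = dy.pairwise_distance_matrix(small_study.counts, small_study.tree)
        results = dy.per_season_group_tests(
            d, small_study.metadata, n_perm=99, seed=11
        )
        assert set(results) == set(small_study.metadata.seasons)
        for res in results.values():
            assert 0 < res.p_value <= 1
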