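"""Faith's PD, generalized UniFrac, Bray-Curtis — checked against naive
independent reimplementations that iterate branches explicitly."""

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.spatial.distance import braycurtis as scipy_braycurtis

import dyadome as dy
from dyadome.core import UndefinedValueError, ValidationError


# ---------------------------------------------------------------------------
# naive oracles (kept deliberately independent of the package internals)


def naive_edges(tree):
    """[(length, frozenset of descendant tip names)] by explicit recursion."""
    edges = []

    def walk(node):
        if node.is_tip():
            tips = frozenset([node.name])
        else:
            tips = frozenset()
            for child in node.children:
                tips |= walk(child)
        if node.parent is not None:
            edges.append((float(node.length or 0.0), tips))
        return tips

    walk(tree)
    return edges


def naive_faith_pd(present, tree):
    return sum(b for b, tips in naive_edges(tree) if tips & set(present))


def naive_gunifrac(counts, tree, s1, s2, alpha):
    p1 = counts[s1] / counts[s1].sum()
    p2 = counts[s2] / counts[s2].sum()
    num = den = 0.0
    for b, tips in naive_edges(tree):
        pa = sum(p1.get(t, 0.0) for t in tips)
        pb = sum(p2.get(t, 0.0) for t in tips)
        if pa + pb == 0:
            continue
        w = b * (pa + pb) ** alpha
        num += w * abs(pa - pb) / (pa + pb)
        den += w
    return num / den


def naive_weighted_unifrac(counts, tree, s1, s2):
    """Classic normalized weighted UniFrac: sum b|pA-pB| / sum b(pA+pB)."""
    p1 = counts[s1] / counts[s1].sum()
    p2 = counts[s2] / counts[s2].sum()
    num = den = 0.0
    for b, tips in naive_edges(tree):
        pa = sum(p1.get(t, 0.0) for t in tips)
        pb = sum(p2.get(t, 0.0) for t in tips)
        num += b * abs(pa - pb)
        den += b * (pa + pb)
    return num / den


def random_toy(rng, min_tips=4, max_tips=10, n_samples=2, allow_zeros=True):
    n = int(rng.integers(min_tips, max_tips + 1))
    tree = dy.generate_tree(n, seed=rng)
    tips = [t.name for t in tree.tips()]
    counts = pd.DataFrame(
        rng.integers(0 if allow_zeros else 1, 20, size=(n, n_samples)),
        index=tips,
        columns=[f"s{j}" for j in range(n_samples)],
    )
    counts.iloc[0] += 1  # no all-zero samples
    return tree, counts


class TestFaithPd:
    def test_hand_examples(self, four_tip_tree):
        assert dy.faith_pd({"A": 1, "B": 1}, four_tip_tree) == pytest.approx(3.0)
        assert dy.faith_pd(
            {"A": 1, "B": 1, "C": 1, "D": 1}, four_tip_tree
        ) == pytest.approx(6.0)
        assert dy.faith_pd({"A": 1}, four_tip_tree) == pytest.approx(2.0)
        assert dy.faith_pd(
            {"A": 1}, four_tip_tree, include_root_path=False
        ) == pytest.approx(1.0)

    def test_empty_sample_rejected(self, four_tip_tree):
        with pytest.raises(UndefinedValueError):
            dy.faith_pd({"A": 0, "B": 0}, four_tip_tree)

    def test_matches_naive_oracle_and_skbio(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tree, counts = random_toy(rng, n_samples=1)
            present = [t for t in counts.index if counts.iloc[:, 0][t] > 0]
            mine = dy.faith_pd(counts.iloc[:, 0], tree)
            assert mine == pytest.approx(naive_faith_pd(present, tree), abs=1e-12)
            # independent cross-check against scikit-bio
            from skbio.diversity.alpha import faith_pd as skbio_faith

            theirs = skbio_faith(
                counts.iloc[:, 0].to_numpy(), taxa=list(counts.index), tree=tree
            )
            assert mine == pytest.approx(float(theirs), abs=1e-9)

    def test_monotone_under_adding_taxa(self):
        rng = np.random.default_rng(1)
        tree, _ = random_toy(rng, min_tips=8, max_tips=8)
        tips = [t.name for t in tree.tips()]
        values = []
        for k in range(1, len(tips) + 1):
            values.append(dy.faith_pd({t: 1 for t in tips[:k]}, tree))
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        total = sum(n.length for n in tree.traverse(include_self=False))
        assert values[-1] == pytest.approx(total)

    def test_alpha_table_matches_per_sample_calls(self, small_study):
        table = dy.alpha_diversity_table(small_study.counts, small_study.tree)
        sample = table.index[3]
        assert table.loc[sample, "faith_pd"] == pytest.approx(
            dy.faith_pd(small_study.counts[sample], small_study.tree)
        )
        assert (
            table.loc[sample, "observed_asvs"]
            == (small_study.counts[sample] > 0).sum()
        )


class TestGunifrac:
    def test_identical_samples_zero(self, star_tree):
        counts = pd.DataFrame({"s1": [3, 1], "s2": [6, 2]}, index=["X", "Y"])
        d = dy.pairwise_distance_matrix(counts, star_tree, alpha=0.5)
        assert d["s1", "s2"] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_is_one(self, star_tree):
        counts = pd.DataFrame({"s1": [1, 0], "s2": [0, 1]}, index=["X", "Y"])
        for alpha in (0.0, 0.5, 1.0):
            d = dy.pairwise_distance_matrix(counts, star_tree, alpha=alpha)
            assert d["s1", "s2"] == pytest.approx(1.0)

    def test_hand_oracle_half(self, star_tree):
        counts = pd.DataFrame({"s1": [3, 1], "s2": [1, 3]}, index=["X", "Y"])
        d = dy.pairwise_distance_matrix(counts, star_tree, alpha=0.5)
        assert d["s1", "s2"] == pytest.approx(0.5, abs=1e-12)

    def test_alpha_out_of_range_rejected(self, star_tree):
        counts = pd.DataFrame({"s1": [1, 0], "s2": [0, 1]}, index=["X", "Y"])
        with pytest.raises(ValueError):
            dy.pairwise_distance_matrix(counts, star_tree, alpha=1.5)

    def test_matrix_matches_naive_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            tree, counts = random_toy(rng, n_samples=4)
            alpha = float(rng.uniform(0, 1))
            d = dy.pairwise_distance_matrix(counts, tree, alpha=alpha)
            for i, si in enumerate(counts.columns):
                for sj in counts.columns[i + 1 :]:
                    assert d[si, sj] == pytest.approx(
                        naive_gunifrac(counts, tree, si, sj, alpha), abs=1e-12
                    )

    def test_alpha_one_equals_weighted_unifrac(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            tree, counts = random_toy(rng, n_samples=2)
            d = dy.pairwise_distance_matrix(counts, tree, alpha=1.0)
            assert d["s0", "s1"] == pytest.approx(
                naive_weighted_unifrac(counts, tree, "s0", "s1"), abs=1e-12
            )

    def test_metric_properties_on_random_toys(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            tree, counts = random_toy(rng, n_samples=5)
            d = dy.pairwise_distance_matrix(counts, tree, alpha=0.5)
            m = d.data
            assert np.allclose(m, m.T)
            assert np.all(np.diag(m) == 0)
            assert m.min() >= 0 and m.max() <= 1 + 1e-12

    def test_profile_api_symmetry(self, small_study):
        _, profiles = dy.branch_profiles(small_study.counts, small_study.tree)
        from dyadome.diversity import BranchProfile, branch_matrix

        lengths = branch_matrix(small_study.tree).lengths
        a = BranchProfile(lengths, profiles[:, 0])
        b = BranchProfile(lengths, profiles[:, 1])
        assert dy.gunifrac(a, b) == pytest.approx(dy.gunifrac(b, a))


class TestBrayCurtis:
    def test_examples(self):
        assert dy.bray_curtis([1, 2], [1, 2]) == 0.0
        assert dy.bray_curtis([1, 0], [0, 1]) == 1.0
        assert dy.bray_curtis([2, 4], [4, 2]) == pytest.approx(4 / 12)

    def test_both_zero_rejected(self):
        with pytest.raises(UndefinedValueError):
            dy.bray_curtis([0, 0], [0, 0])

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.integers(0, 20, size=8).astype(float)
            y = rng.integers(0, 20, size=8).astype(float)
            x[0] += 1
            assert dy.bray_curtis(x, y) == pytest.approx(
                scipy_braycurtis(x, y), abs=1e-12
            )

    def test_matrix_form(self):
        profiles = pd.DataFrame(
            [[2, 4], [4, 2], [2, 4]], index=["g1", "g2", "g3"]
        )
        d = dy.bray_curtis_matrix(profiles)
        assert d["g1", "g3"] == 0.0
        assert d["g1", "g2"] == pytest.approx(4 / 12)
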