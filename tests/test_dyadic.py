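"""Dyad tables, z-transform, and the mixed-model machinery."""

import numpy as np
import pandas as pd
import pytest
import skbio

import dyadome as dy
from dyadome.core import ValidationError

from conftest import make_metadata


class TestBuildDyadTable:
    def _toy(self):
        # A and B each with 2 samples, same group; one season
        ids = ["a1", "a2", "b1", "b2"]
        m = np.array(
            [
                [0.0, 0.2, 0.5, 0.6],
                [0.2, 0.0, 0.7, 0.8],
                [0.5, 0.7, 0.0, 0.3],
                [0.6, 0.8, 0.3, 0.0],
            ]
        )
        d = skbio.DistanceMatrix(m, ids=ids)
        meta = make_metadata(
            {"a1": ("A", "g1"), "a2": ("A", "g1"), "b1": ("B", "g1"), "b2": ("B", "g1")}
        )
        return d, meta

    def test_cross_pair_mean(self):
        d, meta = self._toy()
        table = dy.build_dyad_table(d, meta, level="individual", scope="within-group")
        row = table[table["dyad"] == "A--B"].iloc[0]
        assert row["response"] == pytest.approx((0.5 + 0.6 + 0.7 + 0.8) / 4)

    def test_self_dyad_mean(self):
        d, meta = self._toy()
        table = dy.build_dyad_table(
            d, meta, level="individual", scope="within-group", include_self_dyads=True
        )
        self_a = table[(table["dyad"] == "A--A")].iloc[0]
        assert self_a["response"] == pytest.approx(0.2)
        assert self_a["same_id"] == 1

    def test_group_level_matches_flat_loop_oracle(self, small_study):
        d = dy.pairwise_distance_matrix(small_study.counts, small_study.tree)
        table = dy.build_dyad_table(d, small_study.metadata, level="group")
        meta = small_study.metadata
        groups = meta.sample_groups(d.ids)
        seasons = meta.sample_seasons(d.ids)
        n_groups = len(meta.group_ids)
        assert (
            len(table)
            == n_groups * (n_groups - 1) // 2 * len(meta.seasons)
        )
        for _, row in table.head(5).iterrows():
            acc = []
            for i in range(len(d.ids)):
                for j in range(len(d.ids)):
                    if (
                        groups[i] == row["unit_a"]
                        and groups[j] == row["unit_b"]
                        and seasons[i] == row["season"]
                        and seasons[j] == row["season"]
                    ):
                        acc.append(d.data[i, j])
            assert row["response"] == pytest.approx(np.mean(acc))

    def test_relabelling_invariance(self, small_study):
        d = dy.pairwise_distance_matrix(small_study.counts, small_study.tree)
        shuffled = d.filter(list(reversed(d.ids)))
        t1 = dy.build_dyad_table(d, small_study.metadata, small_study.relatedness)
        t2 = dy.build_dyad_table(shuffled, small_study.metadata, small_study.relatedness)
        key = ["dyad", "season"]
        merged = t1.merge(t2, on=key, suffixes=("_1", "_2"))
        assert len(merged) == len(t1)
        np.testing.assert_allclose(merged["response_1"], merged["response_2"])

    def test_unknown_individual_in_relatedness_rejected(self):
        d, meta = self._toy()
        rel = pd.DataFrame([[0.0]], index=["zz"], columns=["zz"])
        with pytest.raises(ValidationError):
            dy.build_dyad_table(d, meta, rel)

    def test_covariates_joined(self, small_study):
        d = dy.pairwise_distance_matrix(small_study.counts, small_study.tree)
        table = dy.build_dyad_table(
            d, small_study.metadata, small_study.relatedness, scope="all"
        )
        assert {"rc", "same_group", "sex_dyad", "age_class_dyad"} <= set(table.columns)
        kin = small_study.relatedness
        row = table[(table["rc"] > 0)].iloc[0]
        assert kin.loc[row["unit_a"], row["unit_b"]] == row["rc"]


class TestZTransform:
    def test_hand_example(self):
        z, mean, sd = dy.z_transform([1, 2, 3])
        np.testing.assert_allclose(z, [-1, 0, 1])
        assert (mean, sd) == (2.0, 1.0)

    def test_idempotent_on_standardized(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        z, _, _ = dy.z_transform(x)
        z2, _, _ = dy.z_transform(z)
        np.testing.assert_allclose(z, z2, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            dy.z_transform([5, 5, 5], name="flat")


def simulate_lmm_frame(rng, n_groups=15, per_group=6, beta=2.0, sd_group=1.0, sd_e=0.5):
    groups = np.repeat([f"g{i}" for i in range(n_groups)], per_group)
    x = rng.normal(size=len(groups))
    u = dict(zip(np.unique(groups), rng.normal(0, sd_group, size=n_groups)))
    y = beta * x + np.array([u[g] for g in groups]) + rng.normal(0, sd_e, size=len(groups))
    return pd.DataFrame({"y": y, "x": x, "grp": groups})


SIMPLE_SPEC = dy.LmmSpec(
    name="simple", response="y", fixed=("x",), random_intercepts=("grp",)
)


class TestFitAndLrt:
    def test_fixed_effect_recovery(self):
        rng = np.random.default_rng(1)
        fit = dy.fit_lmm(simulate_lmm_frame(rng), SIMPLE_SPEC)
        assert fit.converged
        assert fit.params["x"] == pytest.approx(2.0, abs=0.3)

    def test_zero_variance_component_recovered_near_zero(self):
        rng = np.random.default_rng(2)
        frame = simulate_lmm_frame(rng, sd_group=0.0)
        fit = dy.fit_lmm(frame, SIMPLE_SPEC)
        assert fit.sigma2_random == pytest.approx(0.0, abs=0.05)

    def test_identical_models_rejected(self):
        rng = np.random.default_rng(3)
        fit = dy.fit_lmm(simulate_lmm_frame(rng), SIMPLE_SPEC)
        with pytest.raises(ValidationError):
            dy.lrt(fit, fit)

    def test_lrt_detects_strong_effect(self):
        rng = np.random.default_rng(4)
        frame = simulate_lmm_frame(rng, beta=2.0)
        full = dy.fit_lmm(frame, SIMPLE_SPEC)
        null = dy.fit_lmm(frame, SIMPLE_SPEC.null_spec())
        chi2, df, p = dy.lrt(full, null)
        assert df == 1
        assert chi2 > 0
        assert p < 1e-6

    def test_aliased_design_reported(self):
        rng = np.random.default_rng(5)
        frame = simulate_lmm_frame(rng)
        frame["x2"] = frame["x"]  # perfect alias
        spec = dy.LmmSpec(
            name="alias", response="y", fixed=("x", "x2"), random_intercepts=("grp",)
        )
        with pytest.raises(ValidationError, match="aliased"):
            dy.fit_lmm(frame, spec)


class TestR2:
    def test_generative_truth_partition(self):
        # sigma2_f = 1, sigma2_r = 1, sigma2_e = 2 => R2m ~ .25, R2c ~ .5
        rng = np.random.default_rng(6)
        frame = simulate_lmm_frame(
            rng, n_groups=60, per_group=8, beta=1.0, sd_group=1.0, sd_e=np.sqrt(2.0)
        )
        fit = dy.fit_lmm(frame, SIMPLE_SPEC)
        r2m, r2c = dy.r2_nakagawa(fit)
        assert r2m == pytest.approx(0.25, abs=0.07)
        assert r2c == pytest.approx(0.50, abs=0.07)
        assert r2m <= r2c <= 1.0

    def test_ols_fallback_equalizes_marginal_conditional(self):
        rng = np.random.default_rng(7)
        frame = simulate_lmm_frame(rng, sd_group=0.0)
        spec = dy.LmmSpec(name="ols", response="y", fixed=("x",))
        fit = dy.fit_lmm(frame, spec)
        assert "least squares" in fit.structure_note
        r2m, r2c = dy.r2_nakagawa(fit)
        assert r2m == pytest.approx(r2c)


class TestBootstrap:
    def test_determinism(self):
        rng = np.random.default_rng(8)
        fit = dy.fit_lmm(simulate_lmm_frame(rng, n_groups=8, per_group=4), SIMPLE_SPEC)
        ci1 = dy.parametric_bootstrap_ci(fit, n_boot=15, seed=9)
        ci2 = dy.parametric_bootstrap_ci(fit, n_boot=15, seed=9)
        pd.testing.assert_frame_equal(ci1, ci2)

    def test_interval_covers_estimate_and_shrinks_with_noise(self):
        rng = np.random.default_rng(10)
        quiet = simulate_lmm_frame(rng, sd_group=0.2, sd_e=1e-4)
        fit = dy.fit_lmm(quiet, SIMPLE_SPEC)
        ci = dy.parametric_bootstrap_ci(fit, n_boot=20, seed=11)
        width = ci.loc["x", "ci_upper"] - ci.loc["x", "ci_lower"]
        assert ci.loc["x", "ci_lower"] <= fit.params["x"] <= ci.loc["x", "ci_upper"]
        assert width < 0.05


class TestPresets:
    def test_nine_models(self):
        specs = dy.preset_models()
        assert len(specs) == 9
        assert [s.name for s in specs] == [f"LMM_{r}" for r in
                                           ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX")]

    def test_lmm_i_structure(self):
        spec = {s.name: s for s in dy.preset_models()}["LMM_I"]
        assert spec.fixed == ("same_id",)
        assert set(spec.random_intercepts) == {"dyad", "group"}
        assert "season" in spec.controls
        assert spec.random_slopes.get("dyad") == ("season",)

    def test_lmm_v_predictors(self):
        spec = {s.name: s for s in dy.preset_models()}["LMM_V"]
        assert set(spec.fixed) == {"rank_dyad", "residence_years"}

    def test_null_specs_nested(self):
        for spec in dy.preset_models():
            null = spec.null_spec()
            assert null.fixed == ()
            assert null.random_intercepts == spec.random_intercepts


class TestRunModelOnStudy:
    def test_same_individual_more_similar(self, small_study):
        d = dy.pairwise_distance_matrix(small_study.counts, small_study.tree)
        table = dy.build_dyad_table(
            d, small_study.metadata, small_study.relatedness,
            scope="within-group", include_self_dyads=True,
        )
        spec = {s.name: s for s in dy.preset_models()}["LMM_I"]
        out = dy.run_model(table, spec)
        assert out["full"].params["same_id"] < 0
        assert out["p_value"] < 0.05
        assert 0 <= out["r2_marginal"] <= out["r2_conditional"] <= 1
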