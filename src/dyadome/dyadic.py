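"""Dyadic response tables and Gaussian linear mixed models.

The dyadic stage turns a sample-level distance matrix into one row per
(unit dyad, field season): the response is the mean dissimilarity over
all qualifying sample pairs of the dyad in that season, and the dyadic
covariates (same-individual flag, same-group flag, maternal relatedness
RC, sex/age/rank dyad categories, affiliation time, co-residence years,
and for group dyads home-range overlap and diet/habitat dissimilarity)
are joined from the study metadata.

Models are Gaussian LMMs fitted by maximum likelihood (ML rather than
REML, so that likelihood-ratio tests between nested fixed-effect
structures are valid). A full model carries the predictors of interest;
its null model keeps the intercept, the random-effect structure, and any
control terms. Effect sizes are the variance-partition R² of mixed
models: R²_marginal = s²_f / (s²_f + s²_r + s²_e) for the fixed effects
and R²_conditional = (s²_f + s²_r) / (s²_f + s²_r + s²_e) for fixed plus
random, where s²_f is the variance of the fixed-effect linear predictor
over the data, s²_r the summed random-effect variances, and s²_e the
residual variance. Confidence intervals come from a parametric
bootstrap: responses are simulated from the fitted model and the model
refitted.

The fitting backend is :class:`statsmodels` MixedLM. Structures it
cannot express are simplified in a deterministic, documented order —
random slopes are dropped before random intercepts, and multiple crossed
intercepts are encoded as variance components on a constant grouping —
with every substitution recorded in the result's ``structure_note``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats
import skbio
import statsmodels.formula.api as smf

from .core import (
    DyadomeError,
    StudyMetadata,
    UndefinedValueError,
    ValidationError,
)

logger = logging.getLogger("dyadome")

__all__ = [
    "build_dyad_table",
    "build_alpha_table",
    "z_transform",
    "LmmSpec",
    "LmmFitResult",
    "fit_lmm",
    "lrt",
    "r2_nakagawa",
    "parametric_bootstrap_ci",
    "run_model",
    "preset_models",
]


# ---------------------------------------------------------------------------
# dyad tables


def _dyad_label(a, b) -> str:
    a, b = sorted((str(a), str(b)))
    return f"{a}--{b}"


def _pair_category(x, y) -> str:
    if pd.isna(x) or pd.isna(y):
        return np.nan
    return "-".join(sorted((str(x), str(y))))


def build_dyad_table(
    d: skbio.DistanceMatrix,
    meta: StudyMetadata,
    relatedness: pd.DataFrame | None = None,
    level: str = "individual",
    scope: str = "within-group",
    include_self_dyads: bool = False,
    group_covariates: dict | None = None,
) -> pd.DataFrame:
    """One row per (dyad, season) with mean dissimilarity and covariates.

    ``level`` is ``"individual"`` or ``"group"``; ``scope`` restricts
    individual dyads to group mates (``"within-group"``) or keeps all
    pairs (``"all"``). A self-dyad (individual paired with itself)
    averages over its unordered pairs of distinct samples. Dyads with no
    qualifying sample pair in a season are omitted.
    """
    if level not in ("individual", "group"):
        raise ValueError(f"unknown level {level!r}")
    if scope not in ("within-group", "all"):
        raise ValueError(f"unknown scope {scope!r}")
    ids = list(d.ids)
    inds = meta.sample_individuals(ids)
    grps = meta.sample_groups(ids)
    seas = meta.sample_seasons(ids)
    if relatedness is not None:
        missing = set(inds) - set(relatedness.index)
        if missing:
            raise ValidationError(
                f"individuals absent from relatedness matrix: {sorted(missing)}"
            )

    units = inds if level == "individual" else grps
    group_of = dict(zip(inds, grps))
    data = d.data
    rows = []
    for season in meta.seasons:
        in_season = np.where(seas == season)[0]
        if len(in_season) == 0:
            continue
        season_units = units[in_season]
        uniq = np.unique(season_units)
        member = {u: in_season[season_units == u] for u in uniq}
        for a_idx in range(len(uniq)):
            for b_idx in range(a_idx, len(uniq)):
                ua, ub = uniq[a_idx], uniq[b_idx]
                if ua == ub:
                    if level == "group" or not include_self_dyads:
                        continue
                    idx = member[ua]
                    if len(idx) < 2:
                        continue
                    sub = data[np.ix_(idx, idx)]
                    iu = np.triu_indices(len(idx), 1)
                    response = float(sub[iu].mean())
                else:
                    if (
                        level == "individual"
                        and scope == "within-group"
                        and group_of[ua] != group_of[ub]
                    ):
                        continue
                    block = data[np.ix_(member[ua], member[ub])]
                    response = float(block.mean())
                rows.append(
                    _dyad_row(
                        ua, ub, season, response, level, meta,
                        relatedness, group_covariates, group_of,
                    )
                )
    table = pd.DataFrame(rows)
    if len(table):
        table = table.reset_index(drop=True)
    return table


def _dyad_row(
    ua, ub, season, response, level, meta, relatedness, group_covariates, group_of
):
    row = {
        "dyad": _dyad_label(ua, ub),
        "unit_a": min(str(ua), str(ub)),
        "unit_b": max(str(ua), str(ub)),
        "season": season,
        "response": response,
    }
    if level == "individual":
        ind = meta.individuals
        a, b = row["unit_a"], row["unit_b"]
        row["same_id"] = int(a == b)
        row["same_group"] = int(group_of[a] == group_of[b])
        row["group"] = group_of[a] if row["same_group"] else np.nan
        if relatedness is not None and a != b:
            row["rc"] = float(relatedness.loc[a, b])
        else:
            row["rc"] = np.nan if a != b else np.nan
        row["sex_dyad"] = _pair_category(ind.loc[a, "sex"], ind.loc[b, "sex"])
        row["age_class_dyad"] = _pair_category(
            ind.loc[a, "age_class"], ind.loc[b, "age_class"]
        )
        if "rank_category" in ind.columns:
            row["rank_dyad"] = _pair_category(
                ind.loc[a, "rank_category"], ind.loc[b, "rank_category"]
            )
        if meta.dyads is not None and a != b:
            hit = meta.dyads[
                (meta.dyads["individual_a"] == a) & (meta.dyads["individual_b"] == b)
            ]
            if len(hit):
                for col in ("affiliation_minutes", "residence_years"):
                    if col in hit.columns:
                        row[col] = float(hit.iloc[0][col])
    else:
        a, b = row["unit_a"], row["unit_b"]
        if group_covariates:
            overlap = group_covariates.get("home_range_overlap")
            if overlap is not None and season in overlap:
                row["home_range_overlap"] = float(overlap[season].loc[a, b])
            diet = group_covariates.get("diet_dissimilarity")
            if diet is not None and season in diet:
                row["diet_dissimilarity"] = float(diet[season][a, b])
            habitat = group_covariates.get("habitat_dissimilarity")
            if habitat is not None:
                row["habitat_dissimilarity"] = float(habitat[a, b])
    return row


def build_alpha_table(alpha: pd.DataFrame, meta: StudyMetadata) -> pd.DataFrame:
    """Per-sample alpha diversity joined with individual covariates.

    ``alpha`` is the table from
    :func:`dyadome.diversity.alpha_diversity_table` (indexed by sample
    id). Adds individual, group, season, and the individual covariates;
    ``affiliation_minutes`` is the individual's mean dyadic affiliation
    over its within-group dyads when dyadic data are present.
    """
    rows = alpha.copy()
    rows["individual"] = meta.sample_individuals(rows.index)
    rows["group"] = meta.sample_groups(rows.index)
    rows["season"] = meta.sample_seasons(rows.index)
    ind = meta.individuals
    for col in ("sex", "age", "age_class", "rank_category", "reproductive_state",
                "fgcm", "leaf_intake"):
        if col in ind.columns:
            rows[col] = ind.loc[rows["individual"], col].to_numpy()
    if meta.dyads is not None and "affiliation_minutes" in meta.dyads.columns:
        long = pd.concat(
            [
                meta.dyads.rename(columns={"individual_a": "individual"})[
                    ["individual", "affiliation_minutes"]
                ],
                meta.dyads.rename(columns={"individual_b": "individual"})[
                    ["individual", "affiliation_minutes"]
                ],
            ]
        )
        mean_aff = long.groupby("individual")["affiliation_minutes"].mean()
        rows["affiliation_minutes"] = (
            rows["individual"].map(mean_aff).to_numpy()
        )
    return rows


def z_transform(x, name: str = "covariate"):
    """Standardize to mean 0, SD 1 (denominator n - 1).

    Returns ``(standardized, mean, sd)`` so the transform can be
    reported and inverted.
    """
    arr = np.asarray(x, dtype=float)
    finite = arr[np.isfinite(arr)]
    if len(np.unique(finite)) < 2:
        raise ValidationError(f"cannot z-transform constant covariate {name!r}")
    mean = float(finite.mean())
    sd = float(finite.std(ddof=1))
    return (arr - mean) / sd, mean, sd


# ---------------------------------------------------------------------------
# model specification and fitting


@dataclass
class LmmSpec:
    """Declarative mixed-model structure.

    ``fixed`` are the predictors of interest, ``controls`` the terms kept
    in the null model; ``random_intercepts`` lists grouping factors and
    ``random_slopes`` maps a grouping factor to the terms whose effect
    may vary within it. The null model is intercept + controls + the
    full random structure, so the LRT against the full model isolates the
    predictors of interest.
    """

    name: str
    response: str
    fixed: tuple
    controls: tuple = ()
    random_intercepts: tuple = ()
    random_slopes: dict = field(default_factory=dict)
    table: str = "dyad"  # which response table the spec expects
    description: str = ""

    def __post_init__(self):
        self.fixed = tuple(self.fixed)
        self.controls = tuple(self.controls)
        self.random_intercepts = tuple(self.random_intercepts)
        self.random_slopes = {k: tuple(v) for k, v in self.random_slopes.items()}

    def null_spec(self) -> "LmmSpec":
        return replace(self, name=self.name + "_null", fixed=())

    def formula(self) -> str:
        terms = list(self.fixed) + [c for c in self.controls if c not in self.fixed]
        rhs = " + ".join(terms) if terms else "1"
        return f"{self.response} ~ {rhs}"

    def columns_used(self) -> set:
        cols = {self.response}
        for term in list(self.fixed) + list(self.controls):
            cols.update(t.strip() for t in term.split(":"))
        cols.update(self.random_intercepts)
        for terms in self.random_slopes.values():
            cols.update(terms)
        return cols


@dataclass
class LmmFitResult:
    """A fitted mixed model plus the pieces downstream stages need."""

    spec: LmmSpec
    params: pd.Series
    bse: pd.Series
    llf: float
    df_fixed: int
    sigma2_fixed: float
    sigma2_random: float
    sigma2_resid: float
    converged: bool
    n_obs: int
    structure_note: str = ""
    result: object = field(default=None, repr=False)
    data: pd.DataFrame = field(default=None, repr=False)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.params, "se": self.bse})


def _clean_data(data: pd.DataFrame, spec: LmmSpec) -> pd.DataFrame:
    cols = [c for c in spec.columns_used() if c in data.columns]
    missing = spec.columns_used() - set(data.columns)
    if missing:
        raise ValidationError(
            f"model {spec.name}: columns absent from table: {sorted(missing)}"
        )
    cleaned = data.dropna(subset=cols).copy()
    if cleaned.empty:
        raise ValidationError(f"model {spec.name}: no complete rows")
    return cleaned


class AliasedDesignError(ValidationError):
    """Singular fixed-effect design; carries the aliased column names."""

    def __init__(self, message, aliased):
        super().__init__(message)
        self.aliased = aliased


def _check_design(model, spec):
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # identify aliased columns by greedy rank growth
        aliased = []
        kept = np.empty((exog.shape[0], 0))
        for j, name in enumerate(model.exog_names):
            cand = np.column_stack([kept, exog[:, j]])
            if np.linalg.matrix_rank(cand) > kept.shape[1]:
                kept = cand
            else:
                aliased.append(name)
        raise AliasedDesignError(
            f"model {spec.name}: singular fixed-effect design; aliased terms: {aliased}",
            aliased,
        )


def fit_lmm(data: pd.DataFrame, spec: LmmSpec, reml: bool = False) -> LmmFitResult:
    """Fit a Gaussian LMM by maximum likelihood.

    Random structure mapping: one random-intercept factor fits natively
    (with any random slopes in ``re_formula``); several factors are
    encoded as crossed variance components on a constant grouping, and
    random slopes are then dropped (recorded in ``structure_note``). A
    slope structure that fails to converge is retried without slopes
    before the failure is reported.
    """
    cleaned = _clean_data(data, spec)
    notes = []
    ri = [
        f
        for f in spec.random_intercepts
        if cleaned[f].nunique() >= 2
    ]
    dropped_ri = set(spec.random_intercepts) - set(ri)
    if dropped_ri:
        notes.append(f"dropped single-level random intercepts {sorted(dropped_ri)}")

    formula = spec.formula()

    def build(groups_col, re_formula, vc_formula):
        if groups_col is None:
            cleaned["_const_group"] = 1
            groups_col = "_const_group"
        model = smf.mixedlm(
            formula,
            cleaned,
            groups=cleaned[groups_col],
            re_formula=re_formula,
            vc_formula=vc_formula,
        )
        return model

    attempts = []
    if len(ri) == 1:
        factor = ri[0]
        slopes = [t for t in spec.random_slopes.get(factor, ()) if t in cleaned.columns]
        other_slopes = {
            k: v for k, v in spec.random_slopes.items() if k != factor and v
        }
        if other_slopes:
            notes.append(
                f"dropped random slopes within {sorted(other_slopes)} "
                "(factor not in fitted random structure)"
            )
        if slopes:
            attempts.append((factor, "1 + " + " + ".join(slopes), None, ""))
        attempts.append(
            (
                factor,
                "1",
                None,
                "dropped random slopes (convergence fallback)" if slopes else "",
            )
        )
    elif len(ri) > 1:
        if any(spec.random_slopes.values()):
            notes.append(
                "dropped random slopes (crossed random intercepts encoded as "
                "variance components)"
            )
        vc = {f: f"0 + C({f})" for f in ri}
        attempts.append((None, "0", vc, ""))
    else:
        if any(spec.random_slopes.values()):
            notes.append("dropped random slopes (no usable grouping factor)")
        notes.append("no usable random factors; fitted by ordinary least squares")
        return _fit_ols(formula, cleaned, spec, notes)

    last_error = None
    for groups_col, re_formula, vc_formula, attempt_note in attempts:
        try:
            model = build(groups_col, re_formula, vc_formula)
            _check_design(model, spec)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = None
                fallback = None
                for method in ("lbfgs", "bfgs", "powell"):
                    try:
                        candidate = model.fit(reml=reml, method=method, maxiter=2000)
                    except Exception:
                        continue
                    if candidate.converged and np.isfinite(candidate.llf):
                        result = candidate
                        break
                    if fallback is None and np.isfinite(candidate.llf):
                        fallback = candidate
                if result is None:
                    result = fallback
                if result is None:
                    raise DyadomeError("no optimizer produced a finite likelihood")
        except ValidationError:
            raise
        except Exception as exc:  # retry with simpler structure
            last_error = exc
            continue
        if attempt_note:
            notes.append(attempt_note)
        return _package_fit(result, spec, cleaned, notes)
    raise DyadomeError(f"model {spec.name}: all fitting attempts failed: {last_error}")


def _fit_ols(formula, cleaned, spec, notes) -> LmmFitResult:
    model = smf.ols(formula, cleaned)
    _check_design(model, spec)
    result = model.fit()
    linpred = model.exog @ result.params.to_numpy()
    n = len(cleaned)
    return LmmFitResult(
        spec=spec,
        params=result.params,
        bse=result.bse,
        llf=float(result.llf),
        df_fixed=len(result.params),
        sigma2_fixed=float(np.var(linpred)),
        sigma2_random=0.0,
        sigma2_resid=float(result.ssr / n),  # ML residual variance
        converged=True,
        n_obs=n,
        structure_note="; ".join(x for x in notes if x),
        result=result,
        data=cleaned,
    )


def _package_fit(result, spec, cleaned, notes) -> LmmFitResult:
    model = result.model
    fe = result.fe_params
    linpred = model.exog @ fe.to_numpy()
    sigma2_fixed = float(np.var(linpred))
    sigma2_random = 0.0
    if model.exog_re is not None and result.cov_re.size:
        cov_re = np.asarray(result.cov_re)
        z = model.exog_re
        # variance contributed by the random part: mean of diag(Z G Z')
        sigma2_random += float(np.mean(np.einsum("ij,jk,ik->i", z, cov_re, z)))
    if result.vcomp is not None and len(result.vcomp):
        sigma2_random += float(np.sum(result.vcomp))
    return LmmFitResult(
        spec=spec,
        params=fe,
        bse=result.bse_fe,
        llf=float(result.llf),
        df_fixed=len(fe),
        sigma2_fixed=sigma2_fixed,
        sigma2_random=sigma2_random,
        sigma2_resid=float(result.scale),
        converged=bool(result.converged),
        n_obs=int(model.nobs),
        structure_note="; ".join(n for n in notes if n),
        result=result,
        data=cleaned,
    )


def lrt(full: LmmFitResult, reduced: LmmFitResult):
    """Likelihood-ratio test of nested ML fits: returns (chi2, df, p)."""
    full_names = set(full.result.model.exog_names)
    reduced_names = set(reduced.result.model.exog_names)
    if not reduced_names <= full_names:
        raise ValidationError("reduced model is not nested in the full model")
    df = full.df_fixed - reduced.df_fixed
    if df <= 0:
        raise ValidationError("models do not differ in fixed-effect parameters")
    if full.n_obs != reduced.n_obs:
        raise ValidationError("full and reduced models use different data rows")
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(scipy.stats.chi2.sf(chi2, df))
    return chi2, df, p


def r2_nakagawa(fit: LmmFitResult):
    """Variance-partition effect sizes (R2_marginal, R2_conditional)."""
    total = fit.sigma2_fixed + fit.sigma2_random + fit.sigma2_resid
    if total <= 0:
        raise UndefinedValueError("zero total variance; R2 undefined")
    r2m = fit.sigma2_fixed / total
    r2c = (fit.sigma2_fixed + fit.sigma2_random) / total
    return float(r2m), float(r2c)


def parametric_bootstrap_ci(
    fit: LmmFitResult,
    n_boot: int = 200,
    seed: int | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Percentile bootstrap intervals for the fixed effects.

    Responses are simulated from the fitted model (fixed predictor plus
    random effects drawn at their estimated variances plus residual
    noise) and the model refitted; refit failures are counted and more
    than 20% of them abort with an error suggesting a simpler structure.
    """
    if not fit.converged:
        raise DyadomeError("refusing to bootstrap a non-converged fit")
    rng = np.random.default_rng(seed)
    result = fit.result
    model = result.model
    mu = model.exog @ fit.params.to_numpy()
    n = len(mu)
    raw_cov_re = getattr(result, "cov_re", None)
    cov_re = np.asarray(raw_cov_re) if raw_cov_re is not None else np.empty((0, 0))
    has_re = getattr(model, "exog_re", None) is not None and cov_re.size > 0
    if has_re:
        chol_re = np.linalg.cholesky(cov_re + 1e-12 * np.eye(cov_re.shape[0]))
    raw_vcomp = getattr(result, "vcomp", None)
    vcomp = np.asarray(raw_vcomp) if raw_vcomp is not None else np.array([])
    scale = float(fit.sigma2_resid)
    row_indices = getattr(model, "row_indices", {})  # group label -> row positions

    estimates = []
    failures = 0
    for _ in range(n_boot):
        y = mu.copy()
        if has_re:
            for rows in row_indices.values():
                b = chol_re @ rng.standard_normal(cov_re.shape[0])
                y[rows] += model.exog_re[rows] @ b
        if vcomp.size:
            for j in range(len(vcomp)):
                sd = np.sqrt(max(vcomp[j], 0.0))
                for ig, lab in enumerate(model.group_labels):
                    mat = model.exog_vc.mats[j][ig]
                    rows = row_indices[lab]
                    y[rows] += np.asarray(mat @ (sd * rng.standard_normal(mat.shape[1]))).ravel()
        y += np.sqrt(scale) * rng.standard_normal(n)
        boot_data = fit.data.copy()
        boot_data[fit.spec.response] = y
        try:
            boot_fit = fit_lmm(boot_data, fit.spec)
            estimates.append(boot_fit.params.reindex(fit.params.index))
        except Exception:
            failures += 1
    if n_boot and failures > 0.2 * n_boot:
        raise DyadomeError(
            f"{failures}/{n_boot} bootstrap refits failed; "
            "consider a simpler random-effect structure"
        )
    boot = pd.DataFrame(estimates)
    lo = (1.0 - level) / 2.0
    out = pd.DataFrame(
        {
            "estimate": fit.params,
            "ci_lower": boot.quantile(lo),
            "ci_upper": boot.quantile(1.0 - lo),
        }
    )
    out.attrs["n_boot"] = n_boot
    out.attrs["failures"] = failures
    return out


def run_model(
    data: pd.DataFrame,
    spec: LmmSpec,
    n_boot: int = 0,
    seed: int | None = None,
    drop_aliased: bool = False,
) -> dict:
    """Full-vs-null fit with LRT, R², and optional bootstrap CIs.

    With ``drop_aliased``, fixed-effect terms that are perfectly aliased
    in this data set (e.g. an interaction with no supporting rows) are
    removed once and the simplification recorded.
    """
    aliased_note = ""
    try:
        full = fit_lmm(data, spec)
    except AliasedDesignError as exc:
        if not drop_aliased:
            raise
        bad_cols = set(exc.aliased)
        keep = tuple(
            t for t in spec.fixed
            if not any(col == t or col.startswith(t + "[") or col.replace(" ", "") ==
                       t.replace(" ", "") for col in bad_cols)
        )
        if not keep or keep == spec.fixed:
            raise
        aliased_note = f"dropped aliased fixed terms {sorted(set(spec.fixed) - set(keep))}"
        logger.warning("model %s: %s", spec.name, aliased_note)
        spec = replace(spec, fixed=keep)
        full = fit_lmm(data, spec)
    if aliased_note:
        full.structure_note = "; ".join(n for n in (full.structure_note, aliased_note) if n)
    null = fit_lmm(data, spec.null_spec())
    chi2, df, p = lrt(full, null)
    r2m, r2c = r2_nakagawa(full)
    out = {
        "spec": spec,
        "full": full,
        "null": null,
        "chi2": chi2,
        "df": df,
        "p_value": p,
        "r2_marginal": r2m,
        "r2_conditional": r2c,
    }
    if n_boot:
        out["ci"] = parametric_bootstrap_ci(full, n_boot=n_boot, seed=seed)
    return out


# ---------------------------------------------------------------------------
# preset model structures


def preset_models() -> list:
    """The nine study model structures as configuration data.

    Models I-V take dyadic beta-diversity tables (``table`` field says
    which); VI-IX take the per-sample alpha-diversity table.
    """
    return [
        LmmSpec(
            name="LMM_I",
            response="response",
            fixed=("same_id",),
            controls=("season",),
            random_intercepts=("dyad", "group"),
            random_slopes={"dyad": ("season",)},
            table="dyad_within_group_with_self",
            description=(
                "Are samples of the same individual more similar than "
                "samples of different group members?"
            ),
        ),
        LmmSpec(
            name="LMM_II",
            response="response",
            fixed=("home_range_overlap", "diet_dissimilarity"),
            controls=("season",),
            random_intercepts=("dyad",),
            random_slopes={"dyad": ("season",)},
            table="group_dyad",
            description=(
                "Do groups with larger home-range overlap or more similar "
                "diets share more similar gut communities?"
            ),
        ),
        LmmSpec(
            name="LMM_III",
            response="response",
            fixed=("rc", "rc:same_group"),
            controls=("season",),
            random_intercepts=("dyad",),
            random_slopes={"dyad": ("season",)},
            table="dyad_all",
            description=(
                "Do maternal relatives share more similar gut communities, "
                "within and between groups?"
            ),
        ),
        LmmSpec(
            name="LMM_IV",
            response="response",
            fixed=("age_class_dyad", "sex_dyad", "season", "affiliation_minutes"),
            controls=("rc",),
            random_intercepts=("dyad", "group"),
            random_slopes={"dyad": ("season", "rc", "affiliation_minutes")},
            table="dyad_within_group",
            description=(
                "Within groups: age, sex, season, and affiliation time vs "
                "dyadic dissimilarity, controlling for relatedness."
            ),
        ),
        LmmSpec(
            name="LMM_V",
            response="response",
            fixed=("rank_dyad", "residence_years"),
            controls=("season",),
            random_intercepts=("dyad", "group"),
            random_slopes={"dyad": ("season",)},
            table="dyad_within_group_adults",
            description=(
                "Within groups: rank dyad and co-residence time vs dyadic "
                "dissimilarity among adults."
            ),
        ),
        LmmSpec(
            name="LMM_VI",
            response="faith_pd",
            fixed=("season", "sex", "age", "fgcm", "group", "leaf_intake"),
            controls=(),
            random_intercepts=("individual",),
            random_slopes={"individual": ("season", "leaf_intake", "fgcm", "age")},
            table="alpha",
            description="Alpha diversity vs season, sex, age, fGCM, group, leaf intake.",
        ),
        LmmSpec(
            name="LMM_VII",
            response="faith_pd",
            fixed=("affiliation_minutes",),
            controls=("season",),
            random_intercepts=("individual", "group"),
            random_slopes={"individual": ("affiliation_minutes", "season")},
            table="alpha",
            description="Alpha diversity vs time spent affiliating.",
        ),
        LmmSpec(
            name="LMM_VIII",
            response="faith_pd",
            fixed=("rank_category",),
            controls=("season",),
            random_intercepts=("individual", "group"),
            random_slopes={"individual": ("season",)},
            table="alpha_adult_males_females",
            description="Alpha diversity vs male rank.",
        ),
        LmmSpec(
            name="LMM_IX",
            response="faith_pd",
            fixed=("reproductive_state", "reproductive_state:season"),
            controls=("season",),
            random_intercepts=("individual", "group"),
            random_slopes={"individual": ("season",), "group": ("reproductive_state",)},
            table="alpha_adult_females",
            description="Alpha diversity vs female reproductive state.",
        ),
    ]
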