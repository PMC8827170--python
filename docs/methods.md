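# Methods

This note documents the statistical procedures implemented in
`dyadome`, the choices made where the design was genuinely open, and
what the synthetic-data generator does and does not emulate.

## Data model

The unit of observation is a faecal sample from a known individual
living in a known social group during one of several field seasons.
Counts are ASV × sample non-negative integers; the phylogeny is a
rooted tree whose tips are the ASVs, with non-negative branch lengths;
metadata maps each sample to exactly one individual, group, and season
and carries individual covariates (sex, age class, rank category,
reproductive state, fGCM concentration, leaf intake) and dyadic
covariates (affiliation time, co-residence years). Maternal relatedness
is a symmetric matrix with entries restricted to the field's coding:
RC = 0.5 (mother–offspring, full siblings), 0.25 (half-siblings,
grandmother–grandchild, avuncular), 0.375 (siblings unresolved between
full and half), 0 otherwise.

## Normalization

**GMPR.** For samples *j*, *k*, the pairwise ratio is the median of
count ratios over ASVs observed in both samples; the size factor of *j*
is the geometric mean of its pairwise ratios. Two choices are fixed
here: the self-ratio `r_jj = 1` is included in the geometric mean, which
makes the factors equal depth ÷ geometric-mean-depth *exactly* on
perfectly proportional tables (a testable identity), and a sample must
share at least `min_shared` (default 1) nonzero ASVs with a partner for
the pair to contribute. A sample sharing nothing with anyone is an
error, not a silent 1.0. Normalized abundances are real-valued; no
re-rounding.

**Rarefaction.** Subsampling without replacement (multivariate
hypergeometric) to a fixed depth; samples below the depth are dropped
and logged. Marginal expectation `depth · c_ij / total_j` is verified by
simulation. Rarefied counts feed only the indicator analysis (which
compares abundances across samples at a common depth); the diversity
measures use GMPR-normalized abundances, converted to within-sample
proportions — the workflow's split between the two normalizations.

## Diversity

Both phylogenetic measures run off one decomposition of the tree: per
branch, its length and the set of descendant tips.

**Faith's PD** is the total branch length of the minimal subtree
spanning a sample's observed tips. Default includes the path to the
root (`include_root_path=True`, the common rooted convention); without
it, the unbranched root-to-crown path is subtracted, and a single
observed tip keeps its own pendant edge. Presence is evaluated on raw
counts — normalization cannot change presence.

**Generalized UniFrac** weights each branch by
`b_i (p_i^A + p_i^B)^α` and averages the normalized difference
`|p_i^A − p_i^B| / (p_i^A + p_i^B)`; branches with `p^A + p^B = 0`
contribute to neither numerator nor denominator. `α = 0.5` is the
default (the commonly reported compromise between presence-weighted and
abundance-weighted variants; at `α = 1` the measure equals the classic
normalized weighted UniFrac, which the tests verify numerically). The
batch matrix is one vectorized pass per sample and is tested to 1e-12
against a naive per-branch loop.

**Bray–Curtis** (`Σ|x−y| / Σ(x+y)`) serves the group-level habitat and
diet comparisons.

## Restricted group-membership test

The statistic is `mean_between − mean_within` over sample pairs, with
same-individual pairs excluded from the within term by default
(self-similarity is a separate, dyadic-model question; a flag includes
them). The exchangeability unit is the individual: a permutation
reassigns individuals to groups uniformly among assignments preserving
the observed per-group individual counts, and every sample follows its
individual. Group sizes are a design feature, not a hypothesis, so they
are preserved. The observed assignment counts as one permutation;
`p = #(stat ≥ stat_obs) / n_perm` one-tailed (group structure predicts a
positive statistic; a two-sided variant on |stat| is exposed). When the
number of distinct assignments — `n! / (Π size_k! · Π m_c!)` with `m_c`
the multiplicities of equal sizes — is at most `n_perm`, all of them are
enumerated and p is exact; otherwise Monte-Carlo draws are taken with
replacement. Per-season mode runs the test separately within each field
season, matching the repeated-measures design.

Why the restriction matters: with repeated, within-individual-correlated
samples and groups actually random, a naive sample-level permutation
null is anticonservative; the block-restricted test stays at the nominal
level. The suite demonstrates both the calibration (type-I error within
the binomial band around 5% over 200 null studies) and the inflation of
the naive alternative.

**Mantel tests** between distance matrices use the Pearson correlation
of upper triangles with a label-permutation null, two-sided p, observed
included, exhaustive below `n_perm` distinct relabellings.

## Indicator analysis

The association statistic is the group-equalized point-biserial
correlation: the Pearson correlation between abundance and 0/1
membership after weighting samples by `N / (K · n_k)` so each of the K
categories carries equal weight. It reduces exactly to the classic
point-biserial for equal category sizes. Each ASV gets its best single
category (argmax over categories); combinations of categories are out of
scope because the reported summary is "taxa uniquely associated with one
category". Significance: `n_perm` free relabellings of samples plus the
observed data, `p = (1 + #{perm max ≥ obs}) / (n_perm + 1)`.
Permutations are free (not blocked by individual); a blocked option is a
possible extension. p-values are not multiplicity-adjusted — the
procedure applies a raw cut-off — but a Benjamini–Hochberg column is
emitted for transparency. Rarefaction depth defaults to the observed
minimum sample depth. Constant-abundance ASVs are skipped with a log
entry; categories with fewer than two samples are excluded with a
warning.

## Dyadic tables and mixed models

The response for dyad (i, j) in season t is the mean distance over all
cross pairs of i-samples and j-samples in t; a self-dyad (i, i) averages
the unordered pairs of distinct samples of i; a group dyad averages all
cross-group sample pairs. Dyads without a qualifying pair in a season
are omitted. Dyad identity is unordered (A–B ≡ B–A) and the response is
invariant to sample relabelling (tested).

Models are Gaussian LMMs fitted by **maximum likelihood** whenever
likelihood-ratio tests are computed — REML likelihoods of models with
different fixed effects are not comparable — with REML available for
variance-component reporting. The null model keeps the intercept, the
control terms, and the full random structure, so the LRT isolates the
predictors of interest; degrees of freedom equal the difference in
estimated fixed-effect parameters (interactions counted by expansion).
Effect sizes are the variance-partition R²:
`R²_m = σ²_f / (σ²_f + σ²_r + σ²_e)` and
`R²_c = (σ²_f + σ²_r) / (σ²_f + σ²_r + σ²_e)`, with σ²_f the variance of
the fixed-effect linear predictor over the data, σ²_r the summed
random-effect variances, σ²_e the residual. Confidence intervals come
from a parametric bootstrap (simulate from the fitted model, refit,
percentile interval); refit failures are counted, and more than 20%
aborts with advice to simplify.

**Backend mapping.** statsmodels' MixedLM fits one grouping factor
natively (random slopes included via `re_formula`). Structures beyond
that are simplified in a deterministic, documented order: random slopes
are dropped before random intercepts, and multiple crossed intercepts
are encoded as variance components on a constant grouping. Every
substitution is recorded in the fit result (`structure_note`); the
declared structures are preserved in the `LmmSpec` objects regardless.
Optimizers are tried in a fixed order (L-BFGS, BFGS, Powell) and a
result is accepted only with a finite likelihood; non-convergence is
reported, never silently ignored. Terms perfectly aliased in a given
data set (e.g. an RC × same-group interaction when no between-group kin
exist) can optionally be dropped once, with the simplification recorded.

Dyadic non-independence beyond the declared random effects (each
individual appears in many dyads) is handled exactly by the declared
structure (random intercepts for dyad and group); no MRQAP-style
correction is added. Covariates are z-transformed (mean 0, SD 1,
denominator n−1) with the transform parameters recorded.

Nine preset `LmmSpec` structures cover the standard question battery:
self-similarity (I), environment between groups (II), maternal
relatedness within and between groups (III), within-group social and
intrinsic factors (IV), rank and co-residence (V), and four
alpha-diversity models (VI–IX). Open choices resolved here: self-dyads
are excluded from the within-group models IV and V (their responses are
"between group members"); season enters random-slope terms as a factor.
Diet dissimilarity between groups is Bray–Curtis on plant-family
relative-abundance profiles, after dropping samples with fewer than
1000 land-plant reads — Bray–Curtis chosen for consistency with the
habitat analysis, as the diet metric is otherwise unspecified.

## Synthetic-data generator

The generator emulates the target study design: seven groups of sizes
(10, 7, 3, 6, 5, 5, 5) = 41 individuals, four field seasons, Poisson
numbers of samples per individual per season with mean 3.9 (minimum 1),
log-normal library sizes centred near 4×10⁴ reads (SD 0.4 on the log
scale, spanning roughly 1×10⁴–2×10⁵), exactly one dominant male per
group (deterministically the oldest male), and maternal-kin dyads placed
at a configurable density (default 0.1 within groups, a quarter of that
between groups) with RC drawn from {0.5, 0.25, 0.375}.

Counts follow an additive model on the log relative-abundance scale:
`base_a + G[g,a] + I[i,a] + S[t,a] + ε[s,a]`, with i.i.d. normal group
and season effects, per-draw noise ε (Dirichlet-multinomial-like
overdispersion), and individual effects that are multivariate normal
with covariance `σ²_ind·Id + σ²_kin·RC` — so related individuals receive
more similar effects, the direction the dyadic models test. When the raw
covariance is not positive definite (possible because RC has a zero
diagonal), the nearest PD matrix (eigenvalue clipping) is used with a
warning. Counts are multinomial draws from the softmax composition at
the sampled library size.

Parameter defaults and why:

| parameter | default | meaning |
|---|---|---|
| `n_asvs` | 300 | desk-scale stand-in for thousands of ASVs; the distance-based statistics are insensitive to taxon count at this scale |
| `base_log_abundance_sd` | 2.0 | spread of baseline log abundances; yields realistic skewed, zero-inflated tables |
| `sigma_group` | 1.0 | between-group compositional effect |
| `sigma_individual` | 1.0 | individual signature |
| `sigma_kin` | 1.0 | kinship-shared component |
| `sigma_season` | 0.5 | seasonal shift shared by all hosts |
| `sigma_sample` | 0.5 | within-host, per-sample overdispersion |

The effect sigmas are calibration choices, not field estimates — no
estimate on the log-abundance scale exists for this system — fixed once
at values that give moderate, realistic group separation (within-group
GUniFrac distinctly below between-group, but far from saturation). All
randomness derives from one seed via spawned `SeedSequence` streams per
artifact (tree, metadata, counts, covariates), so every artifact is
byte-reproducible independently.

**What the generator does not emulate:** sequencing error, chimeras,
taxonomy, phylogenetic signal in the effects (effects are i.i.d. across
ASVs given the kinship kernel; real group differences may concentrate in
clades), spatial structure of home ranges, temporal autocorrelation
within a season, or missing metadata patterns. Passing tests therefore
show that the statistical machinery is correct and calibrated under a
plausible generative model — not that any particular field system will
show these effect sizes.

## Problem sizes used in validation

The test suite and the acceptance script run: exact enumeration on a
4-individual toy; 200 null and 100 group-effect studies of 4 groups × 5
individuals × 3 samples with 100 ASVs for calibration and power of the
restricted test; 1000 random small instances for the diversity oracles;
100 planted-indicator and 12 × 200-ASV null datasets for the indicator
analysis; 50 kinship-effect studies (σ_kin = 2.0, σ_ind = 0.5, kin
density 0.3 — a strong planted effect) and 500 null refits for the
mixed-model stage; and one full default-design study (≈640 samples) end
to end. These sizes were chosen as the smallest at which the binomial
/ KS acceptance bands are meaningful.

## Known limitations

- The restricted test assumes individuals are exchangeable across
  groups under the null; covariate-driven group assortment is not
  modelled.
- MixedLM cannot express correlated random slopes alongside crossed
  intercepts; the documented degradation changes the random structure
  of presets IV–IX relative to their declaration (always recorded in
  `structure_note`).
- Indicator permutations ignore the repeated-measures structure (free
  relabelling); with strong within-individual correlation and
  individuals spread unevenly over categories, its p-values can be
  liberal.
- GUniFrac is computed between all sample pairs in memory; studies far
  beyond ~10⁴ samples would need a blocked implementation.
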