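# Methods

This note documents the statistical models implemented in `ndproteo`, the
choices made where the underlying procedures admit more than one sensible
reading, and what the synthetic-data validation does and does not show.

## Synthetic cohorts

The generator produces a sample × aptamer RFU matrix from a log-normal
model. On the log10 scale, for sample *i* and aptamer *j*:

```
log10(RFU_ij) = mu_j + site_offset[site_i] + age_c_i * a_j + sex_i * s_j
                + beta[d_i, j] * sigma_j + eps_ij,   eps_ij ~ N(0, sigma_j)
```

with `mu_j ~ U[2, 4]` and `sigma_j ~ U[0.1, 0.3]`, mimicking the dynamic
range of an aptamer panel. Planted disease effects `beta` are expressed in
z-score units (multiplied by `sigma_j` on the log scale), so the
covariate-adjusted effect size estimated downstream on z-scored data
targets `beta` directly, up to a small attenuation from the disease effect
itself inflating the normalization variance (≈3% at `beta = 0.5` with
balanced arms — inside the ±0.05 recovery tolerance the validation uses).

Defaults describe a plausible multi-site consortium: 16 sites with
additive intercepts of s.d. 0.1 log10 units, one sodium citrate site among
EDTA sites, 10% of aptamers carrying signal at 0.5 z-units, MCAR
missingness at 5%, and outlier spikes at ±3 IQR beyond the quartile hinge
at rate 0.002. Outliers are planted relative to the per-group quartiles so
the 1.5×IQR masking rule catches them by construction; missingness and
outliers never coincide. Effects are drawn `N(0, effect_scale²)` by
default; `effect_distribution="fixed"` plants a constant `+effect_scale`
for calibration experiments.

Cross-disease sharing: for a disease pair with target squared correlation
`r²`, shared-block effects are built from a latent common draw `u` and
disease-specific draws `e_d` as `beta_d = a·u + sqrt(1−a²)·e_d` with
`a = (r²)^{1/4}`, giving `corr(beta_1, beta_2) = a² = sqrt(r²)` and hence
squared correlation `r²` in expectation. Recovery experiments use 400
samples per arm so that estimation noise (SE² ≈ 0.005) attenuates the
measured r² by under 4% — within the ±0.05 tolerance even at a target of
0.9.

All randomness flows from one integer seed through named per-artifact
streams (metadata, matrix, effects, missingness, outliers, networks), so
each component is independently reproducible and identical spec + seed is
bit-identical.

What the generator does **not** model: vendor plate/calibrator structure,
aptamer cross-reactivity, MNAR missingness, longitudinal visits, or
realistic protein–protein abundance correlation beyond what the planted
effects induce. Passing validation on these cohorts shows that the
*estimators are correct under their assumed models*, not that the
assumptions hold in any particular real data set.

## QC and harmonization

Quartiles use the linear-interpolation ("type 7") convention, configurable
via any `numpy.quantile` method. Fences are **strict**: only values
strictly below `Q1 − 1.5·IQR` or above `Q3 + 1.5·IQR` are masked, so a
zero IQR masks nothing. Fences are computed per aptamer within each
processing group (pooled EDTA vs each citrate site) to prevent an
anticoagulant shift from masquerading as outliers; a switch
(`per_group_fences=False`) computes them across all samples instead.
Aptamer/group cells with fewer than 4 observations are skipped (quartile
fences are undefined) and logged.

Call-rate filtering runs two passes (65%, then 85% after recomputation).
Within a pass, analytes are filtered first — evaluated on the samples
entering the pass — then samples, evaluated on the surviving analytes.
The order matters in edge cases and is therefore fixed and reported;
re-running the filter on its own output removes nothing.

Imputation resamples, per aptamer, from the observed values of that
aptamer (seeded). z-scoring uses the sample (n−1) standard deviation,
separately within each processing group; zero-variance aptamers become 0
with a warning. Principal components are computed by SVD on the complete
z-scored matrix, with each component's sign fixed by making its
largest-magnitude loading positive.

A practical caveat for small, signal-dense panels: when a large fraction
of aptamers move with disease, the disease contrast itself can become a
leading principal component, and adjusting for it absorbs signal. In the
intended regime (thousands of aptamers, sparse signal, sizable site
structure) the first PCs track technical/batch variation, which is what
the adjustment is for.

## Association models

Each aptamer is fit by OLS of z-scored abundance on a case indicator plus
covariates; because the design matrix is shared across aptamers on a
complete matrix, the fits are solved once via a single cross-product
inversion (numerically identical to per-aptamer `lm`). p-values use the t
distribution with n − p degrees of freedom; q-values are BH across all
aptamers in the contrast. Rank-deficient designs flag every affected
record rather than raising — a 7,000-fit loop must not abort.

Tertiles are assigned by empirical rank with ties broken by stable order
of appearance; the middle tertile is excluded and the top-vs-bottom
contrast is fit by logistic regression with Wald 95% CIs.
Quasi-separation is detected (unbounded SE) and flagged with an unbounded
CI. The symmetric mean OR replaces OR < 1 by its reciprocal before
averaging, so effect magnitude is summarized irrespective of direction.
Tertiles are defined on cases + controls jointly.

## Cross-disease comparison

The "95% band" around the effect–effect regression line is the
**prediction band** for individual points (the band that visually bounds
points in a scatter); the narrower mean-response band is available via
`band="mean"`. Three selection rules are first-class —
`union_significant`, `both_significant`, `all` — because the choice
changes the measured r² (disease-specific aptamers dilute union-level
correlation). Effects exactly 0 are never counted as concordant; they are
tallied separately and count against concordance.

## Site-level analyses

Random-effects pooling maximizes the restricted likelihood

```
ll(τ²) = −½ [ Σ log(v_i + τ²) + log Σ w_i + Σ w_i (b_i − μ̂)² ],
w_i = 1/(v_i + τ²)
```

by bounded one-dimensional optimization in τ² (tolerance 1e−10), with the
pooled effect the inverse-variance weighted mean at the REML τ² and a Wald
z p-value. At τ² = 0 this reduces exactly to fixed-effect inverse-variance
pooling. The implementation is checked against an independent iterative
grid-search maximizer (agreement to 1e−6) and against R's `metafor::rma`
on a fixed fixture.

Only sites containing both cases and controls are eligible, enforced
identically for by-site and joint analyses. The joint random-intercept
model uses a REML linear mixed model with a Wald z on the fixed effect;
Satterthwaite degrees of freedom are out of scope.

## Enrichment

Over-representation is the one-sided hypergeometric upper tail
`P(X ≥ overlap)`; the background universe defaults to the union of all set
members and is always explicit in the output. Cell-type specificity labels
a gene with its top cell type when that value is at least `ratio` (default
1.5) times the second-highest — on mean expression for brain-style
references and on row-normalized pseudobulk proportions for blood-style
references; the "half-fold higher" blood phrasing is read as ≥1.5-fold,
with the ratio exposed as a parameter because the phrase is ambiguous.
Reported odds ratios are always the sample cross-product of the 2×2
table; Fisher tests are one-sided (enrichment). Multi-target aptamer
annotations ("A | B") contribute each symbol once.

## Boolean regulatory networks

Update rule (default): a node with parents becomes 1 iff at least one
activating parent is 1 and no inhibiting parent is 1; parentless nodes
hold their state; a majority rule is available. Synchronous updates run to
a fixed point or a revisited state; on a limit cycle each node reports its
majority value over the cycle, ties resolving to the initial state.

Reconstruction searches over one gene per undirected PPI edge with five
values (absent, →activating, →inhibiting, ←activating, ←inhibiting) using
a genetic algorithm (tournament selection of size 3, uniform crossover
0.7, per-gene mutation 0.02, elitism 2, population 100, 300 generations, 5
restarts by default; all seeded). Fitness is

```
(#nodes whose observed state is a fixed point given observed parent
 states) + μ·(#nodes with ≥1 parent) − λ·(#retained edges)
```

with μ = 0.25 and λ = 0.05. The explanation reward μ is essential: without
it the empty network (every node parentless, hence trivially consistent)
is always optimal. With λ per-edge cost, the optimum keeps a minimal
consistent parent set per explainable node. On small skeletons (≤ 8
edges) the GA's best fitness is verified against exhaustive enumeration of
the full 5^|E| chromosome space; tests and the acceptance script use
reduced GA budgets (population 60, generations 120, 2 restarts) that still
reach the enumerated optimum on those sizes.

Identifiability caveat: a single fixed-point state vector cannot determine
the sign of an edge whose source node is 0 (the edge is inert), so sign
recovery against ground truth is near-perfect for active-source edges and
chance-level for inactive ones; the aggregate recovery rate reported by
the validation reflects that mixture.

Perturbation analysis clamps each node to the opposite of its observed
state (permanent clamping), relaxes the rest of the network from the
observed states, and scores the node by the number of *reachable*
downstream nodes whose steady state differs from observation. When the
observed states are a fixed point, no unreachable node can move — this is
asserted as a sanity invariant. Ranking ties break by out-degree, then
node id.

## Biomarker panels

Correlation pruning walks candidates in ascending FDR order and drops any
protein with squared correlation above 0.8 to an already-kept protein —
"keep the more significant member of each correlated pair", made
deterministic. Stability selection runs 50 iterations of L1-penalized
logistic regression on random (unbalanced) 70% training splits, the
penalty chosen per iteration by 10-fold cross-validated deviance over a
fixed log-spaced grid (the CV-minimum rule; a 1-SE option is exposed but
not default). The panel is the top 10 by selection frequency, ties broken
by mean |coefficient| then id.

Evaluation is deliberately class-balanced: per iteration, 70% of cases
plus an equal number of controls train an *unpenalized* logistic model on
the panel; the remaining 30% of cases plus an equal number of unused
controls are scored. AUC is the Mann–Whitney statistic with ties counted
½ (verified exactly against pairwise counting); the operating point
maximizes Youden's J (ties to the lower cutoff). Because test prevalence
is 50% by design, PPV/NPV are balanced-prevalence quantities and will
overstate performance at population prevalence. Cross-disease testing
trains on the target disease and scores balanced samples of another
disease's cases and controls.

Leave-one-site-out evaluation z-scores each site independently (including
the held-out site, using only its own distribution — no cross-site
leakage), imputes training-fold missingness from training values and test
missingness from the *training* distribution only, trains an L1 model on
all proteins plus age and sex, and reports per-site AUCs with DeLong
normal-approximation CIs plus the sample-size-weighted mean AUC. The
DeLong variance uses the standard structural components of the
Mann–Whitney kernel; coverage is validated at ≈95% on binormal synthetic
replicates.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run at desk scale, chosen so
each experiment's Monte-Carlo error is well inside its tolerance: QC
operating characteristics on 300×300 cohorts (5 seeds), null FDR on
2,000-aptamer cohorts with 200 per arm (5 seeds), effect recovery on
1,000 aptamers at 200 per arm (2 seeds, 600 CIs), r² recovery on 2,000
aptamers at 400 per arm (3 seeds per target), stability selection on 510
features at 200 per arm (5 seeds), and 100 random Boolean networks of up
to 10 nodes for the exhaustive-simulation cross-checks.

## Known limitations

* The Boolean update rule, GA fitness and hyperparameters are this
  package's documented defaults for a procedure whose original details
  are not public; conclusions about specific regulators depend on them.
* Wald inference throughout (ORs, mixed models, meta-analysis) — no
  profile-likelihood or small-sample corrections by default.
* The synthetic generator's independence assumptions (aptamer-wise noise,
  MCAR) make some tasks easier than real data; calibration results should
  be read as software correctness checks, not clinical performance
  claims.
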