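# Methods

## The model family

All analyses are single-trait repeatability animal models

    y = Xβ + Za + W pe + S d + e

- `a` — additive genetic effects for **every** pedigree animal, with
  `Var(a) = A σ²ₐ`; ancestors without records obtain EBVs through the
  relationship matrix.
- `pe` — permanent-environment effects, one per cow with records,
  `Var(pe) = I σ²ₚₑ`; identifiable only because some cows have repeated
  records (and, weakly, through the pedigree).
- `d` — herd–year contemporary-group (CG) effects, `Var(d) = I σ²_cg`,
  present only when the model treats CG as random (M3/M4); under M1/M2 the
  CG levels sit in `X`.
- `e` — residual, `Var(e) = D σ²ₑ` with known diagonal weights `D`
  (identity for ordinary fits; the threshold working model supplies
  per-record weights).

The four model variants differ only in the fixed-effect list (screened vs
full) and the CG role (fixed vs random).  The screening step fits an
all-fixed-effects linear model and applies marginal (drop-one) F-tests at
α = 0.05; tests are marginal rather than sequential because each effect's
retention is reported individually — a switch to sequential testing would
only require refitting nested models in order.  The dam-age covariate
obeys a hierarchy: the quadratic term is retained only together with the
linear one, and a significant quadratic pulls the linear term in.

## Pedigree machinery

Inbreeding coefficients come from the Meuwissen & Luo recursion (each
animal's diagonal of `A` accumulated over its ancestor set), which also
yields the Mendelian-sampling variance ratios `dᵢ`; these give `log|A| =
Σ log dᵢ` for the REML likelihood and the within-family variances for
gene-dropping simulation.  `A⁻¹` is assembled directly by Henderson's
rules with inbreeding (never by inverting `A`); the dense tabular `A` is
retained only as a small-pedigree oracle, guarded at 10,000 animals.
Unknown parents are unrelated non-inbred founders; there are no genetic
groups.  Identifiers are opaque tokens; the internal integer coding is
topological (parents precede offspring).  A generation-depth pruning
utility (`prune_generations`) can cut ancestors beyond a chosen depth for
herdbooks recorded over many decades; it is off by default — nothing in
the pipeline needs it and deep pedigrees cost little here.

## REML

Variance components maximise the restricted likelihood via
average-information (AI) updates with EM fallback:

- The mixed-model equations are built in information scale
  (`C = M'R⁻¹M + G̃⁻¹`), so `C⁻¹` is directly the posterior covariance of
  the solutions and the animal-block diagonal is the prediction-error
  variance that feeds EBV standard errors and accuracies.
- The permanent-environment equations couple only to their own animal's
  equation, so their (diagonal) block is absorbed exactly and the
  remaining fixed+animal+CG core is factorised densely (LAPACK Cholesky,
  guarded at 8,000 equations).  One factorisation per iteration provides
  solutions, `log|C|`, and — through the inverse of the absorbed core —
  the selected-inverse traces `tr(G⁻¹C^{kk})` needed by the REML gradient
  and EM updates.  The trace identities and the likelihood value are
  verified against a brute-force dense `P`-matrix oracle in the test
  suite.
- AI steps are Newton-like (`θ ← θ + AI⁻¹g`), halved into the parameter
  space, and replaced by an EM step whenever they would decrease the
  restricted likelihood, so accepted iterations are monotone.
- Convergence: relative log-likelihood change < 1e-8 and relative change
  of every component < 1e-6; maximum 200 iterations (non-convergence
  flags the fit rather than raising).  Components are floored at 1e-8 of
  the phenotypic variance; a component driven below 1e-5 of the
  phenotypic variance is snapped to the floor — without this boundary fix
  a vanishing component decays only geometrically under EM and the
  parameter tolerance is never met.
- Standard errors of the components come from the inverse AI matrix;
  h²/r standard errors by the delta method.

Fixed factors use reference-level (corner) coding with an intercept; a
pivoted QR drops aliased columns with a log entry.  EBVs, variance
components and estimable contrasts are invariant to this choice (asserted
by the translation-invariance and oracle tests).

## Threshold model

Score traits (1–9) are modelled as interval censoring of a logistic
liability: category k is observed when `τₖ₋₁ < l ≤ τₖ`, `l = η + e`,
`Var(e) = π²/3` fixed by the link.  No intercept is fitted; the cutpoints
absorb location.  Unobserved interior categories are merged at fit time
(logged), never in the data; only the order of observed categories
matters, so any strictly increasing relabelling gives an identical fit.

Two estimators:

- **Gibbs (default).**  Liability augmentation with the logistic residual
  represented by its Student-t scale-mixture approximation (ν = 7.3,
  scaled to variance π²/3; the CDF discrepancy to the logistic is below
  1e-3).  Every conditional is then Gaussian/standard: truncated-normal
  liabilities, inverse-gamma mixture scales, a joint effects draw through
  the absorbed MME (core draw by triangular solve, permanent-environment
  effects conditionally independent), uniform cutpoint updates between
  adjacent liability extremes, and scaled inverse-χ² variance draws under
  flat priors.  Estimates are posterior means; EBV standard errors are
  posterior standard deviations.  The chain is warm-started from a short
  PQL fit (cutpoints, linear predictor, variances), default 1,800 sweeps
  with 600 burn-in.
- **PQL** (`method="pql"`).  Fisher-scoring working variates for the
  cumulative-logit likelihood feed the shared weighted REML engine with
  the residual scale fixed; cutpoints update by Newton steps.  Fast and
  useful for warm starts and structural checks, but with mostly
  single-record cows it attenuates the latent variance components by
  15–25% (a well-known property of the PQL/Laplace family at low
  per-level information), which is why the sampler is the default for
  estimation.

## Synthetic herdbook generator

The generator emulates the structure of a zebu dairy herdbook: cows with
one to four evaluations (default probabilities 0.78/0.10/0.07/0.05, so
~78% of cows are evaluated once and the mean is ~1.4 records), herd–year
CGs, two evaluation seasons derived from a simulated month (dry April–
September), evaluators pooled within herds, a diet factor, and dam age
uniform over 1820 ± 2·788 days recentred before the linear+quadratic
covariate acts.  Breeding values are gene-dropped (founders `N(0, σ²ₐ)`,
descendants parent-average plus Mendelian sampling with inbreeding-
corrected variance), so `Var(a) = Aσ²ₐ` by construction.  Ordinal traits
cut a latent liability at 8 cutpoints; default cutpoints are equally
spaced and shifted left so the modal score sits at 3–4, mimicking the
right-skewed profile of milking scores.  The latent residual is Gaussian
by default; `residual_law="logistic"` generates exactly from the
cumulative-logit model, which is what the threshold parameter-recovery
study uses (recovery should test an estimator against its own generative
model; the Gaussian/logistic CDF discrepancy is ~0.01 and would otherwise
be conflated with estimator bias).

What the generator does **not** emulate: selection and genetic trend
(matings are random), culling or missing-data mechanisms, evaluator drift
over years, heterogeneous residual variance across herds, and genotypes.
Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the stated variance structure, not robustness
to these real-data features.

## Data editing

Filter order: biological range (continuous traits only) → evaluators with
fewer than five records → CGs with fewer than five records → CG
connectedness → one re-check of the two minimum-count filters.  A
"genetic link" between two CGs is a cross-CG pair of recorded animals
sharing at least one known common ancestor within 3 generations (the
animal itself counts, so a cow recorded in both CGs links them); a CG
needs ten or more links to an already-connected CG, and only the largest
connected component survives.  Component ties break by record count, then
by the lexicographically smallest CG label.  The link definition, depth
and thresholds are configuration knobs: the connectedness literature
counts links in several non-equivalent ways, and the pair-with-common-
ancestor definition was chosen as the most direct reading, documented
here rather than hidden.  Traits whose model carries no CG effect at all
skip the CG-based steps and are analysed on the larger dataset this
produces.

## Transformation

Score traits entering linear models are transformed; candidates are log,
square root, cube root, Yeo–Johnson (maximum-likelihood λ) and ordered
quantile normalisation `zᵢ = Φ⁻¹((rᵢ − 0.5)/n)` with average ranks for
ties.  The selection criterion is `|skewness| + |kurtosis − 3|` after
transformation (moment conventions: g₁ = m₃/m₂^1.5, non-excess kurtosis
m₄/m₂²); the criterion is pluggable.  Candidates with inadmissible
domains are skipped with a log entry.  Threshold fits always use the raw
scores; the pipeline enforces this.

## Model comparison

- Adjusted R² = 1 − (N−1)(1−R²)/(N−r_x) with R² the squared correlation
  of observed and fitted values.  Fitted values include the random-effect
  predictions (Xβ̂+Zâ+Wp̂e+Sd̂): moving CG from fixed to random would
  otherwise mechanically lower R² and make the M1-vs-M3 comparison
  meaningless.  `r_x` is the rank of `X` including the intercept.
- Proven bulls: sires with ≥ 20 distinct phenotyped daughters.  Accuracy
  `sqrt(1 − SEᵢ²/((1+fᵢ)σ²ₐ))` uses each model's own σ²ₐ; values pushed
  outside [0,1] by < 1e-8 are clipped with a warning, larger violations
  raise.
- Paired two-sided t-tests on per-bull accuracies; Spearman correlations
  on per-bull EBVs (average ranks for ties).  The default comparison
  families are M1–M2, M1–M3, M2–M4, and linear-vs-threshold at M3 and M4.

## Validation-study problem sizes

The validation sweeps (shared by the test suite and
`scripts/acceptance.py`) use compact study conditions chosen so a full
sweep completes in minutes on one core: linear parameter recovery uses
20 herdbooks of ~1,080 recorded cows (120 founders, three generations of
400), threshold recovery 20 herdbooks of ~720 cows with 1,500 Gibbs
sweeps each, the oracle sweeps 100 random pedigrees up to 500 animals and
12 GLS fixtures, screening calibration 1,000 replicates of 200 records,
and the CG-pattern study 20 herdbooks of ~450 cows.  Replicate means at
these sizes have Monte-Carlo standard errors well inside the tolerance
bands being checked.

## Known limitations

- Single-trait only; no maternal effects, no genomic information.
- The dense-core guard (8,000 equations after absorption) bounds the
  problem size; national-scale evaluations would need a sparse-factor
  selected inverse in its place.
- PQL attenuation (above) and the ~0.1% logistic-vs-t approximation in
  the sampler.
- Adjusted R² is a pragmatic device for comparing models that differ in
  fixed effects; it ignores the variance partition, and the restricted
  likelihoods of such models are not comparable — a full-likelihood
  comparison would require ML refits.
- Delta-method standard errors for h² and r are first-order.
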