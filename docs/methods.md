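# Methods

`phenoqg` estimates the quantitative-genetic architecture of tree phenology
from clonally replicated pedigree trials: how heritable the timing of spring
and autumn transitions is, and how strongly it is genetically coupled to
lifetime growth.  This note documents the models, the numerical choices, and
what the synthetic trial generator does and does not emulate.

## The animal model

For record *i* (one tree in one year) with response vector
*y<sub>i</sub>* over *t* traits:

```
y_i = X_i β + u_g(i) + e_i ,   e_i ~ N(0, R) ,   vec(U) ~ N(0, G ⊗ A)
```

* **A** is the additive relationship matrix among *genotypes*, built from the
  pedigree by the tabular method (`A[i,i] = 1 + 0.5·A[sire,dam]`,
  `A[i,j] = 0.5·(A[j,sire] + A[j,dam])`, unknown parents contribute zero).
  Founders are assumed non-inbred and mutually unrelated — the standard
  base-population assumption, appropriate for wild-collected parents.
  A is dense and inverted directly; at ~10² genotypes sparse machinery
  buys nothing.
* Clonal ramets are **repeated measures** of one genotype: the genetic
  effect is defined at the genotype level and among-ramet variation is
  residual.  Heritability is therefore a genotype-level quantity,
  h² = V<sub>a</sub>/(V<sub>a</sub> + V<sub>ε</sub>).
* Two model shapes are built in: the **bivariate cross-year model** (one
  trait's two years as a 2-vector response, intercept only), whose G
  off-diagonal gives the cross-year genetic correlation; and the
  **stacked multi-trait model** (per-tree-per-year records of bb2, bb4,
  co3, co8, ls3, CD, DBH with a fixed year effect), whose 7×7 G gives the
  trait–trait genetic correlations.  DBH is measured once and enters only
  its measurement year's records; elsewhere it is missing.

### Gibbs sampler

A systematic-scan cycle with fully conjugate conditionals:

1. **Data augmentation.**  Missing responses (DBH outside its measurement
   year, unbracketed transition days) are drawn from their Gaussian
   conditionals given the observed entries of the same record.  This keeps
   every subsequent update complete-data conjugate.
2. **Joint location draw.**  The generalized eigendecomposition
   `eigh(G, R)` rotates traits to a canonical scale where residuals are
   iid N(0,1) and canonical genetic variances are the eigenvalues; each
   canonical trait is then one single-trait mixed-model-equations solve
   with a stochastic right-hand side (a one-block Gaussian draw of
   (β, U) jointly — no single-site scanning).  This costs one Cholesky of
   a (p+q)² system per canonical trait per iteration and mixes far better
   than updating β and U separately.
3. **G | U** ~ InvWishart(ν<sub>g</sub> + q, ν<sub>g</sub>V<sub>g</sub> + U′A⁻¹U).
4. **R | E** ~ InvWishart(ν<sub>r</sub> + n, ν<sub>r</sub>V<sub>r</sub> + E′E).

**Prior parameterization.**  The (V, ν) weak-belief convention: the prior
density on a covariance Σ is inverse-Wishart with *scale matrix νV* and
*degrees of freedom ν*, i.e. p(Σ) ∝ |Σ|^−(ν+t+1)/2 exp(−½ tr(νV Σ⁻¹)).
ν = 0.002, V = 1 is the conventional near-flat variance prior; ν below
t − 1 leaves the prior improper but every conditional proper (ν + q and
ν + n far exceed t − 1).  For the 7-trait model the default analysis prior
sets V to half the measured phenotypic covariance diagonal with the same
low belief.  Fixed effects get an independent N(0, 10⁸) prior (precision
1e−8 added to the X′X block).

**Numerics.**  One seeded `numpy` generator drives everything; records are
sorted canonically (tree, year) at assembly, so retained draws are
invariant to input row order and exactly reproducible.  Non-PD conditional
scale matrices (never observed in practice) are jittered once by 1e−8·I and
otherwise abort loudly.  Canonical eigenvalues are floored at 1e−12.
Chains default to 20,000 iterations, burn-in 2,000, thinning 20 (900
retained draws) — posterior medians from this scale sit within the
parameters' Monte-Carlo noise of much longer chains; study-scale settings
(10⁶ iterations, thinning 10³) are one `ChainSettings` call away.

**CD collinearity.**  Canopy duration is co3 − bb2 *exactly*, so the
7-trait response is linearly degenerate and the residual cross-product
matrix is rank-6.  The weak prior scale keeps the R conditional proper;
the canonical decomposition tolerates the resulting ill-conditioning
(condition numbers ~10⁵–10⁶ in double precision).  Retained G and R draws
remain PD by construction, which also guarantees every per-draw genetic
correlation lies in [−1, 1] — derived quantities are always computed per
draw and only then summarized, never from a summarized G.

### Posterior summaries

Point estimates are posterior medians (means alongside).  Intervals default
to highest-posterior-density (the shortest sorted-draw window containing
the stated mass), with central quantile intervals available; reports print
an excludes-zero flag per correlation.  The effective sample size uses
ESS = n / (1 + 2·Σρ<sub>k</sub>) with the sum truncated at the first
non-positive autocorrelation.  A caution for chain-hygiene bounds: a lag-1
autocorrelation estimated from ~1000 retained draws has a sampling SE of
about 1/√1000 ≈ 0.032 even for perfectly independent draws, so observed
|lag-1| values of a few hundredths are indistinguishable from zero, and
bounds much tighter than that noise floor cannot be verified empirically
at such chain lengths.

## Transition-day imputation

Ordinal surveys (budburst 1–5, crown colouration 1–8, leaf senescence 1–3,
every 2–5 days) observe development piecewise-constantly, so trees cross
milestones *between* visits.  Per tree × trait × year:

1. **First-crossing reduction** keeps, for each attained stage, the first
   day it was seen; regressing scores (biologically impossible within a
   season) are dropped with a logged warning.
2. **Developmental curve**: LOESS (span 0.75, locally linear, no
   robustness iterations — configurable) through the first-crossing
   points.  The fit is evaluated at the observed days and carried between
   them by a monotonicity-preserving PCHIP interpolant; with exactly two
   points the curve degrades to the line through them.
3. **Milestone day**: a direct observation at the threshold stage always
   wins.  Otherwise the crossing is solved by bisection (0.01-day
   tolerance) *inside the bracketing raw-visit pair* — the last visit
   scored below the threshold and the first scored at/above it.  When the
   curve does not cross inside that bracket (a multi-stage jump between
   two visits leaves LOESS uninformed there), the chord between the
   bracketing observations is used.  Either way the estimate is strictly
   inside the bracket, so its error is bounded by the visit gap (≤ 5
   days).  Thresholds outside the observed stage range are *undefined* —
   no extrapolation — and propagate as missing responses.
4. **Canopy duration** is day(co3) − day(bb2) per tree-year, omitted when
   either endpoint is undefined.

Validation holds out every directly observed crossing (all visits at that
exact stage), refits the curve, re-imputes, and correlates imputed against
observed days — pooled over stages and per stage.  Pooled correlations on
synthetic surveys are ≥ 0.99; per-stage values are lower (~0.88–0.96)
because within-stage day variance is a fraction of the pooled spread.

The milestone set {bb2, bb4, co3, co8, ls3} is configurable
(`transitions.DEFAULT_STAGES`); ordinal scales are fixed per trait.

## The synthetic trial generator

The generator emulates a two-year clonal *Populus trichocarpa* trial so the
whole pipeline is testable without field data: 9 female × 10 male founders,
34 distinct full-sib families, 120 offspring genotypes allocated
near-uniformly, 564 trees with 1–20 ramets per genotype and median exactly
6 (a deterministic count multiset satisfying sum, range and median exactly,
assigned by seeded permutation), surveys every 2–5 days in spring and
autumn windows, DBH once.

**Generative covariances.**  Six traits are free (bb2, bb4, co3, co8, ls3,
DBH); CD is derived, so its genetic row is induced.  G is assembled from a
published-scale genetic correlation table and per-trait heritabilities
(bb2 0.60, bb4 0.55, co3 0.50, co8 0.45, ls3 0.62, DBH 0.76) on day²
scales; phenology phenotypic SDs are ~6 days, DBH 5 cm.  bb2 and co3 are
given *equal genetic variances* (20.25 d²), which makes the induced CD row
reproduce the target CD correlations almost exactly (r(CD,DBH) 0.430,
r(CD,bb2) −0.660, h²(CD) 0.51).  R is diagonal: residual cross-trait
correlations are not separately parameterized (the induced CD residual row
is again an exact consequence).  Non-PD assemblies are projected by
eigenvalue clipping at 1e−6 and the *realized* matrices are what `truth`
reports.

**Cross-year structure.**  Per-trait cross-year genetic correlations
r<sub>t</sub> enter through a 12×12 (trait × year) covariance
[[G, D G D], [D G D, G]] with D = diag(√r<sub>t</sub>).  The trial default
is r<sub>t</sub> = 1 (genotype effects constant across years), which is
exactly the assumption of the stacked multi-trait model — fitting that
model to data with r < 1 biases its correlations, a model-mismatch effect,
not an estimation error.  Cross-year experiments set r explicitly through
the bivariate model, which estimates it consistently.

**Exact-moment breeding values.**  Latent normals are whitened before the
Cholesky transport so that U′A⁻¹U/q equals the generative G *exactly* (the
`mvrnorm(empirical = TRUE)` convention).  With only 120 genotypes in 34
families the realized genetic correlation of an unconstrained draw scatters
around its target with SD ≈ 0.13; parameter-recovery experiments are meant
to measure pipeline error, not that design-level draw noise.  Residual
draws are left random, so recovered medians still scatter by ~0.05–0.07
per replicate; recovery scoring should average a few seeded replicates
(the acceptance script uses 3, and 5 for the noisiest target).

**Latent phenotypes and surveys.**  Trait value = mean + year shift +
breeding value + residual; the within-tree-year ordering
bb2 < bb4 < co3 < co8 < ls3 (1-day margins, all milestones inside their
survey windows) is enforced by rejection-resampling the residual vector,
aborting with diagnostics if 1000 attempts fail.  Non-milestone stages
(bb3, bb5, co2, co4–co7, ls2) are drawn inside the milestone brackets to
give surveys their full ordinal resolution.  Second-year means shift
earlier by 3–10 days depending on the trait.  Visits observe the highest
threshold whose true day has passed.  Calendar anchors (bb2 ≈ day 115,
co3 ≈ 255, ls3 ≈ 295) matter only through differences.

**What the generator does not emulate** — and hence what passing recovery
says nothing about: spatial field structure and neighbour competition,
weather-driven year effects beyond a mean shift, dominance and epistasis
(breeding values are purely additive), observer error in ordinal scoring,
survey-date sharing across trees (real crews survey everyone the same
day; the generator schedules per tree), and mortality/thinning.

## Acceptance experiments

`scripts/acceptance.py --seed S --out results/acceptance.json` regenerates
everything from scratch at desk scale: three replicate trials (seeds
derived from S) for the 7-trait correlation recovery and the univariate
growth-heritability recovery; five replicates of the co8 cross-year
bivariate experiment (generative r = 0.6, per-year h² ≈ 0.5); the pooled
holdout-validation correlation of the imputation; and the absolute lag-1
autocorrelation of retained genetic-variance draws from a 200,000-iteration
bivariate chain thinned at the study's 1000:1 iteration-to-thinning ratio.
Replicate averaging of posterior medians is a precision choice, not a
tolerance change: single replicates carry the residual-level scatter
quantified above.

## Known limitations

* Gaussian responses only; ordinal scores enter through imputed continuous
  days, not a threshold model.
* Single-chain diagnostics (autocorrelation, ESS); no multi-chain
  convergence statistics.
* No dominance/epistatic variance: with a shallow pedigree, any such
  variance would inflate the additive estimates.
* The 7-trait model inherits the exact CD = co3 − bb2 collinearity by
  design; estimates are stable in practice, but the residual covariance is
  intrinsically singular in that direction.
* Recovery tolerances are calibrated to the emulated design size; smaller
  trials will not recover weak correlations to ±0.1.
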