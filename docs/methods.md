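# Methods

## The phenotyping model

A cow's general environmental resilience is quantified from how its
test-day milk yield fluctuates around its own expected lactation curve.
For each cow with at least 10 edited records, a fourth-order polynomial
in days in milk (DIM) is fitted by quantile regression at τ = 0.7:

    yield_t = β0 + β1 t + β2 t² + β3 t³ + β4 t⁴ + ε_t.

Fitting an upper quantile rather than the conditional mean makes
transient, disturbance-induced yield drops pull the curve down far less
than high yields pull it up, so the fitted curve approximates the
undisturbed production potential. τ = 0.6 is available as the
documented alternative. The check-loss minimisation is solved exactly
as a linear program (HiGHS dual simplex via `scipy.optimize.linprog`),
which behaves correctly even on degenerate inputs such as noise-free
records that the quartic interpolates exactly. Internally DIM is
scaled to t/400 before powers are taken to control the conditioning of
the quartic basis; predictions are invariant to this scaling and are
the contract (the LP may have tied coefficient solutions). Predicted
yields are floored at ε = 0.01 kg, since standardized deviations divide
by the expectation.

From the observed and expected yields two deviation series are formed:
actual (observed − expected, kg) and standardized
((observed − expected)/expected, unitless). Standardization removes
the production-level scale effect: a 3 kg shortfall is 60% of a 5 kg
expectation but only 15% of a 20 kg expectation. From each series three
statistics are computed per cow:

* **LnVar** — natural log of the (n−1)-denominator sample variance.
  Lower = more resilient.
* **r_auto** — lag-1 autocorrelation: sum of consecutive
  cross-products about the series mean over the full sum of squares.
  Lower = faster recovery from disturbances.
* **Skew** — adjusted Fisher–Pearson skewness,
  n/((n−1)(n−2)) · Σ((x−x̄)/s)³ with s the sample SD. For
  milk-depressing disturbances, less negative = more resilient. The
  divisor is s (not s²): the n/((n−1)(n−2)) prefactor uniquely
  identifies the adjusted Fisher–Pearson estimator.

Suffix 1 denotes actual-deviation indicators, suffix 2 standardized.
**RawVar** is the log sample variance of the raw yields themselves,
and **AMY** the arithmetic mean of the test-day yields. A series with
zero variance (or too few points) yields a missing value rather than a
sentinel; with a perfectly flat fitted curve rauto1 = rauto2 and
skew1 = skew2 exactly, and lnvar2 = lnvar1 − 2 ln E.

## Data edits

Applied in this order: yield bounds 0.5–45 kg (inclusive) → DIM 1–400 →
cow-level windows (age at first calving 21–60 months; birth year
1980–2019) → at least 10 surviving records per cow → year-season
contemporary groups of ≥ 5 cows. The order is a design choice: the
≥10-records rule exists to guarantee enough points for curve fitting,
so it is evaluated on records that survived the record-level edits, and
it is not re-applied after the year-season exclusion (which removes
whole cows, not records). The cascade is idempotent and its edit-log
counts sum to the row difference.

Breed groups by taurine fraction f: BG1 f ≤ 0.5, BG2 0.5 < f ≤ 0.875,
BG3 f > 0.875. Seasons follow the per-zone month calendar (semi-arid
arable, semi-arid pasture, semi-humid; two dry and two green seasons
each); year-season labels combine calving year with the season of the
calving month in the cow's own zone. After assembling the phenotypes,
each indicator column is edited in a single non-iterative pass: values
more than 4 SD from the pre-edit column mean are set missing,
independently per indicator.

## Fixed-effects analysis and least-squares means

Per indicator an OLS model with breed group, environment, breed×env,
year-season of calving, age at first calving (factor), number of
records (continuous) and first/last DIM class (10 equal 40-day bins
over DIM 1–400) is fitted on the full-dummy encoding; a pivoted QR
selects a deterministic full-rank column subset, so least-squares
means — which are estimable functions — do not depend on the
parameterization. LSMs average predictions uniformly over the levels
of all other factors (continuous covariates at their means), the
standard LSM convention. Pairwise t-tests at α = 0.05, unadjusted, are
summarised by a compact letter display built from the maximal cliques
of the non-significance graph (Bron–Kerbosch; exact at these level
counts), so two levels share a letter exactly when their difference is
not significant. The number of records enters as a continuous
covariate (10–400 would imply up to 391 factor levels); age at first
calving enters as a factor, switchable to continuous.

## Genetic analysis

The numerator relationship matrix A is built by the tabular recursion
(A_ii = 1 + ½A_{sire,dam}; A_ij = ½(A_{j,sire} + A_{j,dam})) over the
pedigree pruned to phenotyped animals plus all ancestors.

**Univariate animal model** y = Xβ + Za + e with a ~ N(0, A σ²a),
e ~ N(0, I σ²e). The restricted likelihood is maximised by projecting
y onto the orthogonal complement of col(X), eigendecomposing the
projected relationship kernel once, and profiling the total variance,
leaving a 1-D bounded search over h² = σ²a/σ²p (Brent, tolerance
1e-10). Boundary estimates (σ²a → 0) are reported as zero with a flag.
Standard errors come from the central-difference observed information
in (σ²a, σ²e) with the delta method for h². Because the
eigendecomposition depends only on (X, K), Monte-Carlo replication over
phenotypes costs O(n) per replicate — this is what makes the 50–500
replicate recovery and calibration suites cheap.

**Bivariate model** with genetic covariance A ⊗ G and residual I ⊗ R
(G, R 2×2). When both traits share the cow set and design matrix the
same projection/eigen trick reduces each likelihood evaluation to a
product of 2×2 problems; otherwise a dense stacked-covariance REML is
maximised directly (suitable for the indicator × longevity pairs, where
the exit-recorded subset is smaller). Both paths optimise a
Cholesky-log parameterisation (L-BFGS-B with Nelder-Mead polish, log
diagonals bounded in ±8), which keeps G and R positive definite; an
estimate driven to |rg| > 0.999 is reported with a boundary flag. With
the genetic and residual covariances both pinned at zero the fit
decomposes into the two univariate problems (verified to ~1e-4 in
tests).

**Inference.** Heritabilities and genetic correlations are tested by
likelihood ratio against the model without the animal effect (or with
σ_a1a2 = 0), statistic 2Δlog L clipped at zero, referred to χ²₁ — the
conventional choice; a 50:50 χ²₀/χ²₁ boundary mixture is available
behind a flag, and the plain χ²₁ test is conservative at the boundary
(null rejection ≈ 2–3% at α = 0.05 in the calibration suite). GCV is
√σ²a/|µ|, except for the already-log-transformed variance indicators
(LnVar1/2, RawVar) where GCV = √σ²a: the additive SD of a log trait is
itself unitless, and the printed variance–GCV pairs (0.057 → 0.24,
0.047 → 0.22) confirm this reading. Phenotypic correlations are tested
by Fisher's r-to-z (z = ½ln((1+r)/(1−r)), SD 1/√(n−3)). p-values are
reported unadjusted.

**Longevity.** Productive lifespan = days from first calving to exit;
herd life = days from birth to exit; only exits coded death-from-
disease or disposal-for-slaughter are eligible. The herd-life model
uses the productive-lifespan fixed effects minus age at first calving,
with AMY as a covariate in both.

## The synthetic-herd generator

The generator supplies ground-truth-bearing inputs with the statistical
structure of low-input tropical dairy herds; it is first-class, tested
code, not a fixture.

* **Pedigree.** Founder sires and dams (unknown parents) plus one
  generation of recorded cows, each drawing a random sire and dam —
  paternal half-sib families carry the additive signal.
* **Breeding values.** Multivariate over latent traits (deviation
  log-variance "lnvar", log yield level "amy", longevity days), with
  G built from h²·σ²p diagonals and target-rg off-diagonals (checked
  PSD). Founders draw a ~ N(0, G); descendants use the
  mendelian-sampling recursion a = ½(a_s + a_d) + m with
  Var(m) = ½(1 − ½(F_s + F_d))G, so Var(a) = A ⊗ G without factoring
  the dense A. Inbreeding coefficients come from a memoized kinship
  recursion.
* **Lactations.** Baseline is a Wilmink-type curve a + b·e^(−kt) + ct
  parameterised by peak yield (12 kg — AMY then lands near 9 kg, the
  low production level typical of the system emulated), time to peak
  (50 d) and persistency (−0.012 kg/d), scaled per cow by zone and
  breed multipliers and by exp(v) with v the cow's latent log yield
  level. Disturbance episodes arrive as a Poisson process (default 1
  per 100 days), each depressing yield by a fractional depth (default
  0.3) that recovers exponentially with a 10-day half-life. The cow's
  latent resilience u scales both the residual CV (default 0.15) and
  episode depth by exp(u/2), so ln Var(deviations) ≈ u + constant:
  LnVar is heritable by construction. Records are taken every 14 days
  (test-day intervals in such herds are irregular and undocumented;
  14 d is the fixed default) over a per-cow span of 200–400 days, and
  truncated to (0, 45] kg.
* **Calibration, not tuning.** The non-genetic variance assigned to u
  is the configured phenotypic variance minus the genetic part minus
  the within-cow sampling variance of LnVar, which the generator
  estimates by a short internal Monte Carlo of the full within-cow
  process (episodes, residual, quantile fit) rather than assuming a
  closed form. This is what makes the realized heritability of LnVar
  match the configured target end to end.
* **Longevity.** Productive lifespan = 1000 d mean plus the latent
  longevity value, floored at 1 d; a fraction (default 0.45) of cows
  receives an eligible exit record, the rest stay censored. Default
  genetic correlation between the resilience latent and longevity is
  −0.45.

What the generator does **not** emulate: weather-driven disturbances
from real climate series, irregular test-day intervals, multi-parity
lactations, genomic relationships, heterogeneous herd-management
trends, or selection (culling correlated with phenotype). Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the stated generative model, not that real herd data
would yield the same estimates.

## Numerical choices and degenerate inputs

* LP tolerance is HiGHS's default primal/dual feasibility (~1e-9);
  curve ties are broken by the solver's deterministic pivoting.
* REML: eigenvalues clipped at 1e-9; profile search tolerance 1e-10 on
  h²; likelihood reparameterisation (σ²a, σ²e) ↔ (σ²p, h²) is exact.
* Zero-variance deviation series produce missing indicators (the log
  is undefined); "zero" is judged against a relative floating-point
  threshold so constant series stored in floating point behave as
  constants.
* An all-equal phenotype column passes the 4-SD edit untouched
  (SD = 0 means no value can exceed the threshold).
* Aliased fixed-effect columns are dropped deterministically
  (first-listed kept) by pivoted QR; REML handles rank-deficient X by
  projecting on its actual column space.

## Problem sizes

The recovery suites follow the sizes the checks are specified at:
univariate h² ∈ {0.05, 0.2, 0.4} with 50 replicates of 1,000 cows
(mean within 0.03); bivariate rg = −0.5 with 20 replicates of 2,000
cows (within 2 SE of the replicate mean); LRT null calibration with
500 replicates of 400 cows; quantile coverage on 200 cows; the demo
pipeline on 500 cows. Replicates share one pedigree and design and
redraw breeding values and residuals — Monte Carlo over data given
structure — which is what keeps these suites to minutes on one core.

## Known limitations

* The bivariate dense path (unequal cow sets) uses derivative-free
  optimisation and reports no SE for rg; use the shared-design fast
  path for SEs.
* AMY is analysed on the kg scale while the generator's yield merit is
  multiplicative, so the realized AMY heritability sits slightly below
  the configured latent target (convexity attenuation).
* Single parity only; no permanent-environment effect is fitted
  (one record per cow per trait makes it unidentifiable).
* The 4-SD edit is single-pass by design; an iterated edit would
  remove marginally more points.
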