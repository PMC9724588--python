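# Methods

## Model

Two-sample summary-data MR treats each SNP j as an instrumental
variable for the exposure X. With β_Xj (SE σ_Xj) the per-allele effect
on X from one cohort and β_Yj (SE σ_Yj) the effect on the outcome Y
from a non-overlapping cohort, the per-SNP Wald ratio θⱼ = β_Yj/β_Xj
estimates the causal effect of X on Y under the three instrumental
assumptions: the SNP associates with X; it is independent of
confounders of X and Y; and it affects Y only through X (exclusion
restriction). For a binary outcome from a logistic GWAS, θ is a
log-odds ratio per SD of exposure and is reported as exp(θ).

Estimators implemented (closed form throughout):

* **IVW**: θ̂ = Σwⱼθⱼ/Σwⱼ with wⱼ = 1/se(θⱼ)², algebraically the
  weighted least-squares slope of β_Y on β_X through the origin with
  weights 1/σ_Yj². Fixed-effect SE is (Σwⱼ)^(−1/2); the
  multiplicative-random-effects SE multiplies it by √(Q/(J−1)) without
  truncation below 1, so the fixed-effect SE is recovered exactly at
  Q = J−1 and under-dispersed data yield a smaller SE (the pure
  multiplicative-regression convention; some packages truncate at 1).
* **Wald-ratio SE**: first order, σ_Yj/|β_Xj|, ignoring exposure-side
  noise — adequate when all instruments have F > 10, which the
  strength diagnostics enforce by warning. The second-order
  delta-method term is available behind a flag.
* **MR-Egger**: weighted regression of β_Y on β_X with intercept,
  after orienting every SNP so β_X ≥ 0. The slope is a
  pleiotropy-adjusted causal estimate under InSIDE (pleiotropic
  effects independent of instrument strength); the intercept's
  two-sided test is the directional-pleiotropy diagnostic. SEs carry
  the √(Q_Egger/(J−2)) multiplicative scale, untruncated.
* **Weighted median**: Wald ratios ordered, inverse-variance weights
  normalized; the estimate is the value at cumulative weight 0.5 with
  each ratio placed at the center of its weight mass and linear
  interpolation between bracketing ratios (so equal weights reproduce
  the ordinary median). Consistent while valid instruments carry >50%
  of the weight. SE by seeded parametric bootstrap (default 1000
  draws) resampling β_X and β_Y from their normal sampling errors.
* **Cochran's Q**: Σwⱼ(θⱼ − θ_ref)², df J−1 (J−2 against the Egger
  slope), upper-tail χ².
* **Leave-one-out**: IVW re-estimated J times, ranked by
  |θ̂₍₋ⱼ₎ − θ̂_full| to surface single-SNP leverage.
* **MR-PRESSO**: observed RSS = Σwⱼ(β_Yj − β_Xj·θ̂₍₋ⱼ₎)² with
  leave-one-out IVW slopes; the null distribution redraws
  β*_X ~ N(β_X, σ_X²) and β*_Y ~ N(β_X·θ̂₍₋ⱼ₎, σ_Y²) and recomputes the
  statistic (1000 draws by default). Global and per-SNP p-values are
  empirical with the +1 correction, so they are bounded below by
  1/(n_sim+1) — which also means the per-SNP Bonferroni cut α/J is
  only reachable when n_sim ≥ J/α. Outliers are flagged at α/J
  (configurable to raw α); removal is single-pass. The distortion
  test compares the observed relative change in θ̂ against removal of
  equally many random SNPs (1000 sets, without replacement, seeded).
* **MVMR**: weighted multiple regression of β_Y on the J×K
  exposure-beta matrix, no intercept, weights 1/σ_Y², requiring
  J > K+1 and full column rank; SEs scaled by √(Q_cond/(J−K)),
  untruncated. The coefficient of each exposure is its direct effect,
  mutually adjusted. Instruments are the clumped union of SNPs
  significant for any included exposure, looked up in every exposure's
  full table. A per-exposure conditional-F approximation (weighted
  regression of each exposure's betas on the co-exposures', then
  Σr²/σ² / (J−K+1)) warns below 10; with K = 1 it reduces to the mean
  per-SNP F.
* **Two-step mediation**: indirect = a·b (step 1: exposure→mediator
  UVMR; step 2: mediator→outcome from MVMR adjusted for the exposure);
  proportion = a·b/θ_total. Delta-method SEs with Cov(a,b) = 0 — the
  two estimates come from separate regressions on separate cohorts.
  The proportion SE propagates both indirect and total variances by
  default (total can be held fixed). CIs are symmetric on the computed
  scale; ratio-scale intervals for proportions are inherently
  approximate near θ_total = 0. A gate (step-1 p < 0.05, strict)
  routes non-significant mediator candidates to "not a mediator". The
  total effect defaults to the pre-outlier-removal IVW estimate (the
  post-removal corrected estimate is available via
  `mediation_total: post_presso`). The step-1 UVMR disables the
  outcome-significance exclusion: that filter protects the exclusion
  restriction for the disease outcome, not for a mediator trait.
* **Power (binary outcome)**: attenuated association
  b = K·(OR/(1 + K·(OR−1)) − 1) with K the case fraction, sampling
  variance v = (K(1−K) − b²)/(N·R²), two-sided power
  Φ(|b|/√v − z₁₋α/₂). This linearization is accurate for modest
  effects; for rare outcomes with OR ≳ 1.5 it overstates power by
  several percentage points relative to an individual-level logistic
  simulation (the test suite pins the comparison at OR = 1.08, K = 0.1
  where the two agree). The formula is asymmetric in log-OR by
  construction; monotonicity in N, R², |log OR| and α is tested, not
  symmetry.

P-values are two-sided normal-theory on θ̂/SE throughout (not t), the
summary-data MR convention.

## Harmonization rules

Effects are aligned to the primary exposure's effect allele, after
canonicalizing that allele to the alphabetically first of the pair —
this makes the harmonized set invariant to how the input happens to
label effect/other alleles. Swapped labels negate β and complement
EAF; palindromic (A/T, C/G) SNPs are dropped unconditionally (no
frequency-based rescue); SNPs with outcome p below the configurable
outcome-significance threshold (default 5×10⁻⁸) are dropped; SNPs
missing from the outcome may be replaced by the best LD proxy with
r² > 0.8 when an LD table is supplied. Every input SNP ends up either
in the harmonized set or in the exclusion log with exactly one reason
code. Clumping is greedy by ascending p (ties by rsID): a candidate
within ±1 Mb of an accepted SNP on the same chromosome is kept only if
the pair's r² is known and < 0.001 — pairs absent from the LD table
are treated as dependent, the conservative choice when no full
reference panel ships with the analysis. Positions are 1-based.
Per-exposure instrument strength aggregates per-SNP F as the
arithmetic mean (min and median are also reported), with a warning
below 10; total R² sums per-SNP 2·EAF·(1−EAF)·β², skipping SNPs
without EAF.

## Synthetic data

The generator draws summary statistics directly at the summary level
(no individual genotypes): EAF ~ U(0.05, 0.95); true SNP→exposure
effects γⱼ ~ N(0, γ_sd²); σ_Xj = 1/√(2·EAF(1−EAF)·N_X); observed
β_Xj ~ N(γⱼ, σ_Xj²); outcome truth Γⱼ = θ·γⱼ + αⱼ with pleiotropy
αⱼ ~ N(μ_α, σ_α²) drawn independently of γⱼ (InSIDE holds);
binary-outcome σ_Yj = 1/√(2·EAF(1−EAF)·N_Y·K(1−K)); planted outliers
add a fixed multiple of σ_Yj to Γⱼ. Mediation runs add a mediator
trait with per-SNP truth a·γⱼ plus mediator-specific effects for extra
SNPs (zero exposure effect) that identify the mediator's direct effect
in MVMR; the exposure's total effect is c + a·b by construction.

Defaults mirror the biobank-scale design the package targets: 100
instruments explaining ≈5% of a continuous exposure measured in
360,000 samples (γ_sd = 0.037 gives E[R²] = n_snp·0.365·γ_sd² ≈ 0.05),
a binary outcome GWAS of 213,746 samples at case fraction
3283/213746 ≈ 0.0154, a mediator GWAS of 700,000, causal effect
θ = 0.174 (OR ≈ 1.19 per SD), pleiotropy off, mediation paths
(a, b, c) = (0.05, 0.53, 0.15) when enabled — a proportion mediated of
≈15%. What the generator does **not** emulate: LD between instruments
(tables are post-clumping by construction), winner's curse from
discovery selection, sample overlap, population stratification, and
allele-frequency differences between cohorts. Passing recovery tests
therefore demonstrates estimator correctness under the stated
two-sample model, not robustness to those real-data pathologies.

Simulation scales used by the test suite are chosen to put each
estimand in its informative regime: type-I error uses 2,000 null
replicates at J = 20; estimator recovery 500 replicates at J = 100;
MR-PRESSO sensitivity/specificity 200 replicates at J = 25 (so the
Bonferroni cut α/J stays above the empirical-p floor 1/(n_sim+1));
MVMR direct-effect recovery 500 replicates. The mediation-proportion
recovery uses a precise-regime design (exposure R² ≈ 10%, cystatin-C
Table-1-like, and an outcome cohort of 8×10⁶) because the proportion
is a ratio estimator whose finite-sample bias is quadratic in the
total-effect CV; at the default cohort size its spread, not its mean,
dominates. Directional-pleiotropy recovery for the Egger intercept
uses all-positive instrument effects: with symmetric γ the β_X ≥ 0
orientation flips the sign of half the pleiotropic effects, so a
directional mean is only identified relative to instrument
orientation — a genuine identifiability fact, not an implementation
choice.

## Numerical and design choices

* Empirical p-values (+1 correction) never equal zero; normal-theory
  p-values are floored at 5×10⁻³²⁴ to stay in (0, 1].
* Ties in clumping and proxy search break by lexicographic rsID;
  leave-one-out influence ties break by rsID. All orderings are
  deterministic, and every stochastic step (weighted-median bootstrap,
  MR-PRESSO draws, distortion removals) takes an explicit seed; the
  pipeline derives per-stage seeds from the single config seed via
  SHA-256, so reports reproduce byte-for-byte.
* Degenerate inputs fail fast with `MRError`: β_X = 0 Wald ratios,
  < 2 SNPs for IVW, < 3 for Egger/median/leave-one-out, < 4 for
  MR-PRESSO, J ≤ K+1 or rank-deficient exposure matrices for MVMR,
  θ_total = 0 for the mediation proportion.
* Exposure-side SEs enter the MR-PRESSO null draws when available;
  with no exposure SE the draw degenerates to fixed β_X and the result
  notes it.
* Continuous-trait betas are assumed to be in SD units; the package
  never rescales.

## Known limitations

* No mode-based estimators, Steiger filtering, MVMR-Egger/median, or
  iterated MR-PRESSO re-testing.
* No remote clumping or LD-panel computation; LD information must be
  supplied as a pairwise r² table, and unknown within-window pairs are
  conservatively treated as correlated.
* The delta-method proportion CI is symmetric and can cross 0 or 1 for
  weak total effects; profile or bootstrap intervals are out of scope.
* The binary-outcome power formula is an approximation (see above);
  treat power near 1 for large OR with caution.
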