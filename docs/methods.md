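# Methods

## Scope

`feedquant` re-implements, as a tested pipeline, the quantitative-genetics
workflow used to evaluate feed efficiency in a pedigreed two-sex chicken
population: derivation of residual feed intake (RFI) and feed conversion
ratio (FCR) from daily feeding-station records, animal-model REML estimation
of heritabilities and genetic/phenotypic correlations, relative efficiency of
indirect selection, and a candidate-gene SNP analysis (Hardy-Weinberg,
pairwise linkage disequilibrium, EM haplotype frequencies, genotype-trait
association with LSD post-hoc letters). Because no real records are
distributed, a synthetic-data generator with known ground truth stands in for
the study birds and is itself first-class, tested code.

## Phenotype derivation

For each bird, body weight over the test window is modelled as a straight
line, BW = μ + a·DOT + e, where DOT is the day of testing (DOT = 1 on the
first test day, age 56 d, so a 50-day window ends at 105 d and the window
midpoint is DOT 25). The slope `a` is the bird's average daily gain (ADG).
Mid-test body weight is the line evaluated at `mid_dot` (default 25), and
mid-test metabolic body weight is MMBW = MBW^0.75 (Kleiber scaling). Average
daily feed intake is ADFI = total FI / number of test days.

Within each sex, expected feed intake is the OLS regression
ADFI = b0 + b1·MMBW + b2·ADG + e, partitioning intake into maintenance
(metabolic weight) and production (growth) components; RFI is the residual
`e`. By OLS construction ADFI ≡ EFI + RFI per bird, within-sex RFI sums to
zero, and RFI is orthogonal to MMBW and ADG at machine precision — this is
the algebra behind RFI's phenotypic independence from growth and metabolic
weight, and the suite asserts it as an invariant rather than an estimate.

FCR is total feed intake divided by body-weight gain. Three choices here
were genuinely open and are package decisions:

* **BW endpoints.** BW8/BW15 (start/end-of-test weights) and the FCR gain use
  the fitted growth-line predictions at the first and last test day, damping
  weighing noise; `use_fitted_endpoints=False` switches to raw weighings.
* **Non-growing birds** get a missing FCR (flagged NaN, excluded from FCR
  analyses) but keep their RFI; a handful of such birds should not abort a
  batch run.
* **Decile contrast.** The high/low comparison takes the floor(0.10·n)
  largest- and smallest-RFI birds and compares each trait with Welch's
  two-sample t-test (the unequal-variance form is the safer default when the
  source of the P-values is unstated).

## Animal-model REML

Genetic parameters come from the animal model y = Xb + Za + e with fixed
effects sex (2 levels) and pen (6 levels), a ~ N(0, A·σ²ₐ) with A the
pedigree numerator relationship matrix (tabular method), and independent
residuals. Because pens are nested within sex, a sex dummy is linearly
dependent on the pen dummies; the design builder drops aliased columns
(order-preserving greedy rank check) and logs the fact.

With a single record per phenotyped bird, V = σ²ₐ·A_s + σ²ₑ·I, where A_s is
the relationship matrix restricted to phenotyped birds. One symmetric
eigendecomposition A_s = U D U' per dataset rotates the model so V is
diagonal (single trait) or block-diagonal in 2×2 blocks d_i·G + R (two
traits), making every REML quantity O(n) per iteration. Estimation is
average-information (AI) REML: Newton steps on the variance components using
the AI matrix, with an EM-REML step whenever the AI step fails or would
decrease the restricted likelihood. Controls: convergence when the
restricted log-likelihood changes by < 1e-6, at most 200 iterations (an
explicit error with the iteration trace otherwise), variances floored at
1e-8 on a per-trait standardised scale so h² stays in [0, 1], and non-PD
bivariate updates bent to the nearest PD matrix by eigenvalue clipping at
1e-8 (bending events are counted on the result). Traits are standardised
internally and estimates rescaled, so tolerances are scale-free.

Heritability is h² = σ²ₐ/(σ²ₐ+σ²ₑ); genetic and phenotypic correlations are
r_g = G₁₂/√(G₁₁G₂₂) and r_p = (G₁₂+R₁₂)/√((G₁₁+R₁₁)(G₂₂+R₂₂)). Standard
errors are delta-method values from the inverse AI matrix at convergence.
Identifiability is checked up front: if A_s is (numerically) a multiple of
the identity — unrelated birds with single records — σ²ₐ and σ²ₑ are
confounded and the fit raises instead of returning an arbitrary split.

An independent oracle validates the implementation: on balanced paternal
half-sib data the animal-model covariance (A blocks 0.75·I + 0.25·J per
family) coincides with a sire model, so REML must equal the one-way ANOVA
estimator (σ̂²ₛ = (MS_between − MS_within)/k, σ̂²ₐ = 4σ̂²ₛ); the suite checks
this to ~1e-3 relative.

## Relative selection efficiency

The efficiency of indirect selection on a primary trait for changing a
secondary trait is computed as (h₁/h₂)·r_g with the tabulated heritability
values used directly. The classical correlated-response ratio uses the
square roots of the heritabilities (i·h₁·r_g·σ_A2 / i·h₂·σ_A2 =
(h₁/h₂)^½·r_g); the convention adopted here is the one under which the
published cross-table is internally consistent (e.g. 0.282/0.288 × 0.334 =
0.327), and the deviation from the textbook form is deliberate and
documented rather than silently resolved. `selection_efficiency(h, h, r) = r`
holds for any h > 0 under either convention and is property-tested.

## SNP statistics

Genotypes are minor-allele dosages (0/1/2, NaN missing). Hardy-Weinberg
conformity uses the 1-df Pearson chi-square against p², 2pq, q² expectations
without continuity correction (the convention of standard haplotype-analysis
software); `conforms` means P > 0.05, and out-of-equilibrium loci are
excluded (threshold configurable) before LD/haplotype analysis.

Two-locus haplotype frequencies are estimated by EM over the unobserved
phase: all genotype pairs except the double heterozygote determine their two
gametes; the double heterozygote is resolved with posterior weight
h₁₁h₂₂/(h₁₁h₂₂ + h₁₂h₂₁) on the coupling phase. Iteration runs to a
log-likelihood change < 1e-8 (max 1,000 sweeps) from the
linkage-equilibrium start, plus 5 random restarts to guard the symmetric
stationary point (all-double-heterozygote samples leave the LE start
exactly at (¼,¼,¼,¼)); the highest-likelihood run wins, ties resolved
toward the lexicographically smallest frequency vector. The likelihood is
asserted non-decreasing at every sweep. Because both phase resolutions of a
double heterozygote carry the same allele margins, the MLE preserves sample
allele frequencies; the test oracle exploits this to reduce the brute-force
check to a 1-D likelihood grid over h₁₁ (step 0.001).

From haplotype frequencies: D = h₁₁ − p₁p₂; D′ = |D|/D_max with
D_max = min(p₁q₂, q₁p₂) for D > 0 and min(p₁p₂, q₁q₂) otherwise;
r² = D²/(p₁q₁p₂q₂). "Strong LD" is D′ strictly greater than 0.75,
cross-tabulated with r² bands at 0.6 and 0.3. Monomorphic loci yield
flagged undefined results, not exceptions. Missingness is handled pairwise
complete-case; no imputation.

## Association

Each SNP is tested against each trait with the fixed-effects GLM
Y = μ + genotype + family + sex + e, fit by OLS with genotype as a
categorical factor (three genotype means, not an additive dosage slope).
"Family" defaults to sire family (configurable to dam or full-sib). Genotype
classes with fewer than 2 birds are dropped and logged; a genotype factor
aliased with family raises an explicit error naming the columns. The
genotype test is the type-III (partial) F-test — with no interactions this
is the full-vs-reduced comparison, cross-checked in the suite against
statsmodels' type-III ANOVA on sum-coded factors. Genotype least-squares
means average predictions over the family × sex grid.

Pairwise genotype comparisons use Fisher's LSD at α = 0.05: |Δ LS means|
against t(1−α/2, df_resid) times the SE of the difference from the model
residual mean square. Letters come from the insert-and-absorb compact
letter display, which guarantees two genotypes share a letter exactly when
their LSD comparison is non-significant. No multiple-testing correction is
applied across the locus × trait grid (nominal reporting, as conventional
for ~10-SNP candidate panels); a Bonferroni column is emitted alongside.

## Synthetic data

The generator simulates what the analysis consumes, at the trait level
rather than via mechanistic physiology:

* **Pedigree.** Founder sires and dams (defaults 100 and 200) are mated
  round-robin, giving paternal half-sib families; offspring (default target
  1,220 phenotyped, mirroring the study scale) are sexed to a 0.5 ratio
  (deterministic counts, within one bird) and balanced over 3 pens per sex.
* **Breeding values.** Founders ~ N(0, G); non-founders are the parental
  mean plus a Mendelian-sampling deviation ~ N(0, G/2) — the non-inbred
  base-population approximation, adequate for shallow two-generation
  pedigrees.
* **Latent traits.** (ADG, BW8, RFI) are simulated jointly; the default G
  and R are assembled from the heritabilities (0.383, 0.305, 0.282),
  phenotypic SDs realistic for a slow-growing meat line (3.9 g/d, 86 g,
  5.5 g/d), genetic correlations (ADG–RFI −0.198, BW8–RFI 0.0281, ADG–BW8
  0.30 — the last not estimated in the source population, set to a typical
  moderate value) and phenotypic correlations (0, 0.111, 0.25). ADFI, MMBW,
  BW15 and FCR are *not* simulated separately: under the linear growth
  model they are deterministic functions of the simulated three, which keeps
  the generator consistent with the derivation stage (simulating them
  jointly as free traits would contradict the structural model and break the
  closure property below).
* **Daily records.** BW(d) is the latent line through BW8 plus iid weighing
  noise (default SD 25 g); daily FI is the structural intake
  b0 + b1·MMBW + b2·ADG + RFI plus iid noise (default SD 8 g), with
  sex-specific coefficients chosen so mean intake matches the observed
  ~80 g/d scale. With both noise SDs at zero the full pipeline returns the
  configured parameters exactly (closure), which the suite asserts.
* **SNPs.** Ten biallelic loci emulate a candidate-gene panel: founder
  haplotypes are drawn to target minor-allele frequencies and pairwise r²
  (two-locus coupling-phase blocks per `ld_partner` pair; an unattainable
  r² raises an error stating the maximum attainable value), then transmitted
  through the pedigree without recombination within a block (within-gene
  SNPs). Additive effects per minor-allele copy can be attached to ADG
  (growth-mediated intake effects) or to the intake channel itself; note
  that an intake effect at fixed growth *is* residual feed intake by
  definition, so such effects necessarily surface in derived RFI.
* **Determinism.** Every generator consumes `numpy` Generators seeded from
  `SeedSequence([seed, stage])`; identical configurations reproduce
  byte-identical outputs.

What the generator does not emulate: dominance, epistasis,
genotype-environment interaction, mortality/dropout, selection, or
long-range haplotype structure. Passing tests therefore demonstrate that the
estimators recover the parameters of this generating process at the study's
scale — not that real feeding-station data are this well behaved (real
records have missing days, station misreads, non-linear late growth and
selection on the recorded cohort).

## Replicated recovery studies and problem sizes

`feedquant.studies.recovery_study` simulates replicate populations of 2,000
phenotyped birds (100 sires × 4 dams × 5 offspring) with sex and pen fixed
effects and a trait pair generated at configured h², r_g, r_p, then
re-estimates everything by REML. Thirty replicates are used by the
acceptance checks: at that size the Monte-Carlo SE of the replicate mean is
≈ 0.01 for h² and ≈ 0.015 for r_g, comfortably inside the ±0.05 recovery
band, while one full battery (simulation, relationship matrix,
eigendecomposition, one bivariate and two univariate fits per replicate)
runs in about two minutes on one core.

## Numerical notes and limitations

* The eigendecomposition trick requires a single record per bird and Z
  selecting phenotyped individuals — exactly this design; repeated records
  or maternal effects would need the general MME path, which is out of
  scope (as are genomic relationship matrices, >2-trait joint REML and
  Bayesian alternatives).
* AI-REML convergence is checked on the restricted log-likelihood; the AI
  step is rejected in favour of EM whenever it would lower the likelihood,
  so the accepted sequence is monotone. Pure-EM mode (`algorithm="em"`)
  exists mainly for diagnostics; EM converges linearly and may need
  thousands of sweeps to meet the 1e-6 tolerance.
* Near-degenerate bivariate fits (duplicated traits) survive via bending but
  converge to boundary estimates; r_g/r_p approach 1 as expected.
* FCR of non-growing birds, monomorphic loci in LD, and genotype classes
  below 2 birds are flagged-and-excluded conditions, not exceptions;
  malformed pedigrees (cycles, phantom parents), unattainable LD targets,
  non-PSD covariance inputs and unidentifiable REML designs raise errors
  naming the offending structure.
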