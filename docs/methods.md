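# Methods

`sexvar` simulates and analyses a sex-specific quantitative-genetics
experiment: how sexually antagonistic (SA) versus male-limited (ML) family
selection on body mass reshapes the sex-specific genetic variance of a
population, measured before and after selection with a Bayesian bivariate
animal model.  Everything here is synthetic and self-contained: the
breeding designs, the genetic architectures, the selection protocol and the
estimation machinery are all implemented in the package, so every claim the
tests make is about quantities whose ground truth is known by construction.

## Breeding design

The variance-decomposition pedigree is a three-generation nested half-sib
design.  Unrelated founder pairs produce one sex-balanced offspring per
grandparental (GP) family; GP offspring are paired at random into parental
(P) families; from each P family one son and four daughters are taken and
every P son is mated to four P daughters from distinct other families.  The
defaults (120 GP families, 60 P families, 4 dams per sire, 7 measured
offspring per F1 family) give 240 full-sib families nested in 60 paternal
half-sib groups and 2340 pedigree records, roughly two thousand measured
individuals.  The mix of full sibs, paternal half sibs, parent–offspring
pairs and X/Y-asymmetric relatives is what separates autosomal additive,
dominance, X-linked, Y-linked and maternal components.  A `REDUCED_DESIGN`
preset (60/30/4/5, ~800 measured individuals) is the same design at a size
where a full Bayesian fit takes a couple of minutes; analysis scripts and
tests state which preset they use.

Double-first-cousin blocks, which the ancestral version of this design used
to separate maternal from dominance variance, are deliberately absent; the
package treats maternal variance as a modelled component instead (see
limitations).

## Relatedness kernels

Four expected-relatedness matrices are built from the pedigree:

* **A** — numerator relationship matrix by the tabular recursion; its sparse
  inverse comes from the parent-triplet rules with inbreeding.
* **D** — dominance relatedness in the non-inbred approximation
  `d_ij = (a_ss' a_dd' + a_sd' a_ds') / 4`.  Generated designs are
  non-inbred through F1, where the approximation is exact; on inbred
  pedigrees it deliberately is not (identity-coefficient dominance is out of
  scope) and the gene-drop oracle quantifies the gap.
* **X** — from the X-kinship recursion (sons take their single X from the
  dam; daughters take the sire's X and one of the dam's two).  Stored as
  `2*phi` between females, `phi` between males and `sqrt(2)*phi` cross-sex.
  No dosage-compensation constant is applied: the male/female scale
  difference is absorbed by the sex-specific X variance parameters, which is
  legitimate *because* the model fixes the cross-sex X covariance to zero.
  The `sqrt(2)` cross-sex scaling makes the stored matrix PSD
  (a diagonally scaled kinship matrix); the model never uses that block.
* **Y** — patriline membership (1 among males sharing an unbroken
  father-to-son chain to the same founder), equivalent to a grouped random
  effect.  The non-recombining Y acts as a single inherited haplotype.

A Monte-Carlo gene-dropping oracle (unique founder alleles, per-chromosome
transmission rules, IBD statistics averaged over replicates) provides
estimator-independent ground truth for every kernel and is run against the
analytic matrices in the tests (100k replicates keep every entry's standard
error below ~0.005, comfortably inside the 0.02 assertion band).

## Genetic architectures and simulation

Simulation is locus-explicit: biallelic loci with founder frequency `p`,
chromosome class (autosome/X/Y) and sex-specific additive and dominance
effects in mg.  Genotypic values follow the textbook −a/d/+a coding per
sex; hemizygous male X and the haploid Y contribute `a_m` per copy.
Phenotype = sex intercept + genetic value + maternal effect (one draw per
dam, scaled per offspring sex) + Gaussian residual.  `expected_components`
returns the exact base-population variance components implied by an
architecture (standard single-locus decomposition, `alpha = a + d(q−p)`),
optionally at evolved allele frequencies — that is the bridge between the
selection simulator and the estimand.

Presets (the study conditions; fixed, not tuned):

* `ancestral_preset` — the ancestral-population pattern: shared additive
  background with cross-sex correlation ~1, female-limited dominance, male
  X and Y variance, no female X variance, no maternal variance (set to zero
  because the modelled system showed none; the machinery exists and is
  tested).
* `sa_reversal_preset` — adds 8 sexually antagonistic loci with sex-specific
  dominance reversal: the allele that enlarges both sexes is dominant in
  females and recessive in males, so heterozygotes are simultaneously large
  as females and small as males.  SA family selection on the female/male
  weight ratio therefore favours heterozygotes and holds these loci at
  intermediate frequency, while ML selection drives them toward fixation —
  the mechanism by which SA selection maintains female dominance variance.
* `polygenic_preset` / `oligogenic_preset` — 200 small loci vs 5 large + 50
  small, because the true effect-size spectrum is unknowable from the
  phenotypic data alone; both are exposed rather than asserting one.

Residual variances default to 1 mg² per sex and effect sizes are chosen so
genetic variance is a realistic fraction of phenotypic variance (h² roughly
0.3–0.6); intercepts 5.8/4.0 mg give a female-biased baseline dimorphism.

A matrix-Gaussian shortcut draws breeding values and the other effects
directly from the pedigree kernels at specified true components.  It cannot
respond to selection (no allele frequencies) and exists to give estimator
tests an exactly known truth.

## Selection protocol

Each generation, full-sib family means are computed per sex; the top 8 of
56 families are kept — highest female/male mean-mass ratio (SA), lowest
male mean (ML), or uniformly at random (RS) — and crossed fully
factorially excluding within-family crosses: one virgin male and seven
virgin females per selected family, every ordered pair of distinct families
yielding exactly one cross, so 8 selected families regenerate exactly
8×7 = 56 families.  After 10 generations the top families are pooled and
random-mated for one (replicate a) or two (replicate b) panmictic
generations; the follow-up variance-decomposition design draws its founders
from that pool, carrying the evolved genotypes.

Choices the protocol description leaves open, fixed here once: the
individuals representing a selected family are drawn uniformly at random;
each female mates once; ranking ties break by a seeded random key; families
missing a required sex are unrankable and excluded; selection-phase
families consist of 16 collected offspring with sex-balanced collection
(seven virgin females plus a male must be available per selected family,
which a 7-offspring family with random sexes cannot guarantee — the
measured-design default of 7 per family applies to the quantitative-
genetics pedigree, not the selection phase).  Selection differentials are
(mean of the parents actually used) − (cohort mean), per sex, accumulated
over generations.

## The animal model

Body mass is a bivariate Gaussian trait (female and male expression); each
individual is observed for its own sex's trait only.  Components: the 2×2
autosomal additive covariance `G` on kernel A (the free cross-sex
covariance defines `r_mf = COV / sqrt(VA_f VA_m)`); per-sex dominance and
X-linked variances with their cross-sex covariances structurally zero;
a patriline-level Y effect on the male trait; per-sex dam-level maternal
effects; per-sex residuals with the cross-trait residual covariance fixed
to zero (unidentifiable when no individual expresses both traits).  Fixed
effects are per-trait intercepts plus an optional categorical block.

Latent effects are kept for observed individuals only — restricting a
kernel to observed rows marginalizes unobserved relatives exactly, and for
the per-sex components further to that sex's rows.  The sampler is Gibbs
with three non-textbook choices, each load-bearing:

1. **Fixed effects ride in the breeding-value blocks.**  The trait
   intercept is nearly collinear with the mean breeding value; updating
   them in separate blocks mixes pathologically.  `[beta, u_trait]` is
   drawn jointly given the other trait's values (conditional prior
   `u_f | u_m ~ N((g_fm/g_mm) u_m, (g_ff − g_fm²/g_mm) A)`).
2. **Marginal updates for scalar variances.**  A variance conditioned on
   its own effect vector random-walks along the component-vs-residual ridge
   (both kernels have unit-ish diagonals) and never converges.  Each scalar
   variance is instead slice-sampled from the likelihood with its effect
   integrated out — `r ~ N(0, sigma² K + sigma_R² I)`, diagonal in the
   kernel eigenbasis — and the effect redrawn afterwards.
3. **Interweaving for `G`.**  The conjugate inverse-Wishart update
   conditions on the current breeding values and barely moves `G`.  An
   ancillarity move resamples the Cholesky factor of `G` with the whitened
   values `w = L⁻¹u` held fixed: the records are linear in the three free
   entries of `L`, so the likelihood conditional is Gaussian and is used as
   a Metropolis proposal corrected only by the prior × Jacobian ratio.

Priors: inverse-Wishart (ν = 3, scale `0.05 V_P I`) for `G` — ν = p + 1
makes the marginal cross-sex correlation uniform on (−1, 1), and the scale
must not be made much smaller: a near-zero scale matrix concentrates prior
mass on singular `G` and traps the correlation at ±1.  Scalar variances get
scaled-inverse-chi-square (ν = 0.2, scale `V_P`), weak enough that null
components pile at zero.  Posterior draws automatically respect
`|COV| ≤ sqrt(VA_f VA_m)`.

Chain defaults are 5000 iterations, 1000 burn-in, thinning 4, one chain —
sized for the reduced design, where the sampler produces effective sample
sizes of a few dozen for the slowest parameters in ~2 minutes; the
analysis scripts state the sizes they use.  Effective sample size and a
split-chain diagnostic are available per parameter on the returned object.

Degenerate inputs (constant response per sex) are refused at design-build
time; non-finite conditional draws abort with the iteration index.

### Direct-likelihood verifier and the boundary LRT

`ml_fit` maximizes the full multivariate-normal likelihood of the identical
covariance structure (fixed effects profiled; analytic gradients; bounded
L-BFGS; warm-startable so nested fits satisfy
`loglik(full) ≥ loglik(reduced)` by construction).  It is the independent
route used to cross-check the Gibbs posterior and to form likelihood-ratio
tests.  For a variance component on the boundary of its parameter space the
LRT statistic is referred to the 50:50 `chi²_0 : chi²_1` mixture
(binomial mixture for several boundary components).  At the test scale used
(≈220 observations) the mixture is known to be slightly conservative, and
the type-I-error simulation in the acceptance suite measures exactly that.

## Posterior comparisons

Regimes and lines are compared by posterior differences: the distribution
of index-matched differences between two parameters' draws, significant
when its 95% equal-tailed credible interval excludes zero.  Posterior modes
are located by maximizing a Gaussian KDE over the draws at twice the Scott
bandwidth (the argmax of a plug-in-bandwidth KDE is noisy; oversmoothing
stabilizes it at negligible bias for these unimodal marginals), evaluated
on the non-negative axis for variances.  Credible intervals are
equal-tailed (HPD was considered and not adopted: equal-tailed intervals
are order-statistics of the draws, reproducible without density
estimation).  Heritabilities use the inclusive additive numerator —
`(VA_sex,a + VA_sex,X [+ VA_Y for males]) / VP_sex` — documented as this
package's convention.

`rmf_star` fits the same data twice — full partition versus autosomal-plus-
residual only — and returns both correlations.  With sex-limited variance
present in the truth, the unpartitioned fit absorbs it into the sex-specific
additive variances, inflating the *denominator* of the correlation while
the cross-sex numerator gains nothing, so `r_mf*` is biased downward
relative to the full-partition `r_mfa`; once selection erodes the
sex-limited variance the bias disappears and `r_mf*` rises toward `r_mfa`.
Both the ML and the Bayesian routes reproduce this direction in simulation,
and the acceptance suite asserts it.

## What the synthetic data do and do not show

The generator reproduces the design's relatedness structure, sex-specific
architectures with known components, selection response and drift.  It does
not emulate: linkage or genetic maps (loci are unlinked; sex-shared and
sex-limited variance can be coupled only through pleiotropy at a locus),
epistasis, genotype-by-environment interaction, viability or fecundity
differences, overlapping generations, or measurement-protocol artefacts.
Passing tests therefore demonstrate that the estimation machinery recovers
the truth *of this generative model* at the stated sample sizes, and that
the selection mechanism produces the predicted direction of variance
change; they cannot certify the biology of any real population.

## Numerical choices

Kernel eigenvalues are floored at 1e-8; the additive matrix gets a 1e-8
jitter before Cholesky in the Gaussian simulator; correlation draws with
either additive variance below 1e-12 are dropped and counted (more than
50% dropped flags the summary unreliable).  The slice sampler uses a
stepping-out width of `V_P / 10`.  Expected-component cross-sex covariance
is clipped to the Cauchy–Schwarz bound against float rounding at `r = 1`.
Pedigree founders are marked by the parent token `"0"`; records re-sort
topologically on read.

## Known limitations

* Posterior means of weakly identified components (female dominance at
  0.1 V_P, Y-linked at 0.05 V_P) have realization-level sampling spreads
  comparable to their true values at the reduced design size: even the ML
  estimator's SD across simulated datasets is ~0.12 for V_D,f at ~800
  observations.  Point-recovery checks at that scale are therefore
  direction- and coverage-oriented; credible intervals are honest about the
  uncertainty.
* The dominance kernel ignores inbreeding identity coefficients.
* Maternal effects share the dam's draw across sexes in the locus-explicit
  simulator (scaled per sex) but are modelled as independent per-sex dam
  effects — with zero maternal variance in all presets this distinction is
  dormant.
* X dominance in females is simulatable but not part of the component
  vector; presets keep X dominance effects at zero.
* The Gibbs sampler's slowest parameters (male-side additive block) reach
  effective sample sizes of tens, not hundreds, per 5000 iterations at the
  reduced design; multiply chains or iterations for publication-grade
  summaries.
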