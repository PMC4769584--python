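# Methods

## Model

`bayesrc` fits the linear mixed model

    y = X b + Z a + W v + e

to a quantitative trait measured on n individuals genotyped at m variants:

- **y** — phenotypes (one record per individual);
- **X b** — fixed effects with a flat prior (always an intercept; typically a
  population/breed indicator and any user covariates);
- **Z a** — an optional polygenic term, a ~ N(0, A σ²ₐ), where A is the
  pedigree numerator relationship matrix. It absorbs familial resemblance not
  captured by the genotyped variants and is omitted when no pedigree is given
  (Z = I in the supported one-record-per-individual layout);
- **W v** — the genomic term. W holds allele dosages centred and scaled to
  unit variance per column; each variant effect v_i follows a four-component
  normal mixture N(0, γ_d σ²_g) with γ = (0, 0.0001, 0.001, 0.01) and σ²_g
  the additive genetic variance. The point mass at zero lets most variants
  drop out of the model;
- **e** — residuals, e ~ N(0, E σ²ₑ) with E = diag(1/w_j). The reliability
  weight w_j expresses how precise record j is (e.g. a progeny-test average
  versus a single lactation record); w_j = 1 for ordinary phenotypes.

The class extension ("BayesRC") attaches each variant to one annotation class
c ∈ {1..C} (for example: nonsynonymous-coding variants in candidate genes /
other variants near candidate genes / everything else). Each class carries
its own mixture proportions with a uniform Dirichlet prior,
P_c ~ Dir(1,1,1,1), updated each Gibbs iteration as
P_c ~ Dir(α_c + β_c) where β_c counts the class's variants currently in each
component. A class enriched for causal variants therefore learns a higher
inclusion rate, raising the posterior inclusion probability (PIP) of its
members; a class that carries no signal learns (to the extent the data
identify it — see *Limitations*) a higher null proportion. With C = 1 the
model is exactly the single-mixture model ("BayesR"); the implementation
shares one code path, so the equivalence is bitwise under a common seed.

## Gibbs sampler

Each iteration samples, in order: the fixed effects from their joint
weighted-least-squares conditional; the polygenic vector and σ²ₐ (when a
pedigree is present); every variant's component indicator and effect in a
fresh random permutation; the per-class proportions; and σ²ₑ. For variant i
with score r_i = W_i' E⁻¹ r̃ (r̃ the residual with the variant's own
contribution restored) and S_i = W_i' E⁻¹ W_i, the component log-weights are

    L_d = log P_c(i),d − ½ log(1 + τ²_d S_i / σ²ₑ) + ½ r_i² τ²_d / (σ²ₑ (τ²_d S_i + σ²ₑ))

with τ²_d = γ_d σ²_g (the null component contributes log P_c(i),1 only); z_i
is drawn by log-sum-exp softmax and, when non-null, v_i from its conjugate
normal conditional. This update was verified against numerical quadrature of
the exact one-variant marginal likelihood, and the residual vector is
recomputed from scratch every 500 iterations with a hard 1e-6 agreement
check.

Numerical and design choices:

- **σ²_g is fixed**, by default at h² × the weighted variance of the
  fixed-effect-adjusted phenotypes, keeping the mixture scales interpretable;
  a switch (`update_sigma2_g`) re-estimates it from the current effects.
- **Variance priors**: scaled inverse-χ² with ν₀ = −2, scale 0
  (uninformative; posteriors are entirely data-driven) for both σ²ₑ and σ²ₐ.
  Proper (ν₀, s₀²) priors are accepted, and the prior-recovery (Geweke-style
  successive-conditional) test uses them, since prior recovery is undefined
  under the improper default.
- **Initialisation**: b from weighted least squares, v = 0, all variants in
  the null component, P_c = (¼,¼,¼,¼), σ²ₑ = 0.5 var(y), σ²ₐ = 0.05 var(y).
- **Proportions** are floored at 1e-300 before taking logs; pinning
  P_c (`fixed_proportions`) and σ²ₑ (`fix_sigma2_e`) turns the chain into a
  Gaussian sampler whose stationary mean is the closed-form ridge solution —
  used as a conjugate-limit oracle in the tests.
- **Performance**: the per-variant sweep is a compiled (numba) loop over
  int8 dosage columns with the centring/scaling folded into per-column
  scalars, a float32 weighted-residual accumulator refreshed every sweep, and
  float64 residual bookkeeping. A generic float32 path accepts arbitrary
  standardized designs. All randomness comes from one NumPy generator per
  chain, so runs are reproducible to the bit on the same build.
- **Summaries**: per-chain post-burn-in means are computed first and then
  averaged across chains; across-chain spread is reported as SD/√(#chains).
  PIP is the fraction of post-burn-in iterations with a non-null component,
  averaged across chains. Production defaults are 5 chains of 40,000
  iterations (20,000 burn-in); the bundled analyses use scaled-down runs
  (below).

## Data handling

MAF filtering excludes variants with minor allele frequency strictly below
the threshold. LD pruning removes one member of every variant pair whose
squared genotypic (dosage) correlation exceeds 0.999 within sliding windows
of 500 variants advanced by 50, per chromosome; it runs first within each
annotation category and then across categories with priority NSC > REG >
CHIP, so putatively functional variants survive in preference to array
fillers. Within a category the later variant (position order) is dropped.
Missing genotypes are mean-imputed per column. Standardization uses the
sample SD of the dosages, and the training means/scales are retained to
transform validation genotypes. The pedigree relationship matrix uses the
tabular method with unknown parents treated as unrelated non-inbred
founders; its Cholesky factor receives 1e-8 diagonal jitter when needed
(logged).

## Synthetic data

The generator emulates a two-population dairy-cattle-style study:

- **Genotypes**: per-variant base frequencies U(0.05, 0.95) with a
  per-population truncated-normal drift (SD 0.1, giving Hudson F_ST ≈
  0.01–0.2); haplotypes are latent AR(1) Gaussians (correlation 0.7) within
  blocks of 20 adjacent variants, thresholded at the population frequency
  quantile; dosage = sum of two independent haplotypes. This gives
  controllable local LD but not coalescent-accurate LD decay, recombination
  hotspots or rare-variant site-frequency spectra.
- **Annotation**: categories NSC/REG/CHIP drawn at 5%/58%/37% per variant
  (mirroring a pruned sequence panel); the candidate-gene scheme places 100
  gene regions of 20 variants with a 10-variant flanking window, class I =
  NSC inside genes, class II = other variants within the window, class III =
  the rest.
- **Trait**: 200 additive QTL at tier counts 174/25/1 with effect variances
  0.0001/0.001/0.01 σ²_g (a 1/20 scale of the full design's 3485/500/15),
  applied to raw 0/1/2 dosages; environmental noise scaled from the
  *realized* genetic variance so h² = 0.6 holds per replicate; a single
  N(10, 1) breed offset added to the first population. QTL placement follows
  the class scheme (candidate-gene regions only / coding+regulatory only /
  uniform) and can be overridden independently of the class definitions
  (`qtl_placement`), which is how the uniform-QTL no-penalty condition is
  simulated while keeping informed classes.
- Defaults: 2 × 1000 training and 2 × 250 validation individuals, 10,000
  variants. All stages derive deterministic sub-streams from one seed.

## Evaluation

Predicted genetic values are ŷ_v = W_val v̂ with W_val standardized by the
*training* scales and the polygenic term deliberately excluded, so
validation sets need not be pedigree-linked to training. Accuracy is the
Pearson correlation of ŷ_v with the reference (true genetic values in
simulation, phenotypes otherwise) and bias the regression of reference on
prediction (1 = unbiased), each computed per chain then averaged.
Calibration bins PIPs into five equal-width bins over (0.01, 1] (the bin
edges are a convention, configurable) and compares each bin's observed
true-QTL fraction to its median PIP. The random-gene null rebuilds
per-class prediction equations from a baseline single-class fit's effects
using randomly drawn gene sets, giving the null distribution against which
informed-class accuracies are judged.

Comparators: single-SNP GWAS (weighted least squares with covariates
projected out and a t test; optionally a pedigree polygenic background with
fixed-h² or REML variance components and Wald tests) and SNP-BLUP with a
common effect variance σ²_g/m, solved in primal or dual (individual-level
GBLUP) form, which agree to numerical precision. REML uses bounded scalar
optimisation of the eigen-rotated profile restricted likelihood (tolerance
1e-6); the GBLUP comparator defaults to fixed user h², since its role is
architectural contrast.

## Problem sizes used in the bundled analyses

The package's own analyses (test suite and `scripts/acceptance.py`) run the
generator defaults — n = 2000 training individuals, m = 10,000 variants,
3 chains × 5,000 iterations (2,500 burn-in), five replicate seeds for the
enriched-class study; one chain × 3,000 iterations and three seeds for the
uniform-QTL study — as the package's desk-scale study conditions.

## Limitations

- **Small-tier identifiability.** The smallest non-null component
  (0.0001 σ²_g) is likelihood-indistinguishable from the null spike unless
  n τ²/σ²ₑ is appreciable: the expected Bayes factor for a truly null
  variant is exactly 1, so at n = 2000 the per-class proportions P_c remain
  close to their diffuse Dirichlet prior rather than concentrating on the
  null, and null variants inherit PIPs around 1 − P_c,1 ≈ 0.2–0.3. Two
  consequences at the desk scale, both measured and reported honestly by the
  test suite: the observed true-QTL fraction among PIP > 0.25 selections
  falls short of the nominal 25% (prior-driven nulls crowd in just above the
  threshold; because the proportions are weakly identified, the selection
  count varies by an order of magnitude across replicate seeds and pooled
  values in our runs ranged from ~11% to ~24%), and the posterior mean
  component counts overstate the number of small effects severalfold. Both
  properties recover as n and m grow (at n ≈ 10⁴ and m ≈ 10⁶ the per-variant
  evidence is ~5× stronger and the variance budget forbids a diffuse P_c),
  so passing accuracy tests here does not certify calibrated PIPs for small
  reference populations — and conversely the miscalibration seen here does
  not indict the full-scale setting.
- The simulator's AR(1)-block LD and multinomial annotation are stylised;
  results on real genotypes with long-range LD, MAF-dependent annotation and
  selection may differ.
- One phenotype record per individual (Z = I); repeated records should be
  pre-aggregated with an appropriate weight.
- The polygenic update factorises an n × n precision matrix per iteration,
  so pedigree mode is intended for moderate n.
- Non-Gaussian traits, dominance/epistasis and segment-variance priors are
  out of scope.
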