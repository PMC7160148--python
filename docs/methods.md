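# Methods

## The problem

In tropical beef-cattle populations the same heifer genotype can express
very different age at first calving (AFC) depending on the environment she
is raised in — nutrition, management, climate. When genotype-by-environment
(GxE) interaction re-ranks animals across environments, a single
genome-wide scan pooled over environments hides loci whose effects are
environment-dependent. This package implements a two-stage single-step
genomic reaction-norm GWAS that estimates SNP effects *as functions of the
environment* and locates the genomic regions whose effects are shared
across, or specific to, environmental levels.

## Stage 1 — the environmental gradient

No external environment descriptor (weather, feed) is assumed. Instead the
environment experienced by a contemporary group (CG: herd x birth
year/season x management group) is summarized by that CG's effect on a
descriptor trait — yearling body weight — estimated as a fixed effect in a
single-step animal model

    y = X b + Z a + e,    a ~ N(0, H sigma2_a),  e ~ N(0, I sigma2_e)

with CG and age at recording (linear) as fixed effects. H blends pedigree
and genomic information (below). The CG BLUEs are standardized over CGs to
mean 0, sd 1 (population-sd convention; the descriptor is a property of the
CG, so standardization is unweighted over CGs, not records) and winsorized
to [-3, +3]. This standardized value EC_j is the reaction-norm covariate.
Five residual-variance classes partition the gradient at the fixed
boundaries -1.5, -0.5, 0.0, 1.5 (the value 1.5 is assigned upward); a 1-D
k-means alternative is provided but the fixed map is the default because it
is exactly reproducible.

## Stage 2 — the reaction-norm model

The target trait is modelled with a first-order random regression on
normalized Legendre polynomials of the gradient:

    y_ij = F_cg + sum_f w_f Phi_f(EC_j) + sum_f a_fi Phi_f(EC_j) + e_ij

with f = 0, 1: each animal has a genetic intercept and slope,
(a_0i, a_1i) ~ N(0, H (x) K), K the 2x2 intercept/slope covariance, and
e_ij heteroskedastic over the five gradient classes. Phi_f(x) =
sqrt((2f+1)/2) P_f(x) on x = EC/3 in [-1, 1]; at order 1 any other affine
mapping of EC only reparameterizes K, leaving fits, correlations and tests
unchanged. The fixed regression w_f is retained alongside the CG effects
even though EC is a deterministic function of CG; the resulting exact
collinearity is handled by the solver's aliasing detection (below).

Derived parameters: genetic variance at level e is phi(e) K phi(e)';
genetic correlation between levels e1, e2 is the normalized bilinear form;
heritability at e uses the residual variance of e's class. A diagonal K
with zero slope variance gives genetic correlation 1 between any two
levels (no GxE); a negative intercept-slope covariance lowers the
correlation between gradient extremes — the re-ranking signature.

## The single-step relationship matrix

A is built by the tabular method (with inbreeding); A^-1 by Henderson's
rules using inbreeding coefficients from A's diagonal. G is VanRaden's
first method, G = Mc Mc' / (2 sum p_k q_k), with dosages centered by twice
the observed allele frequency of the genotyped set (base-population
frequencies are not estimable without extra data) and missing calls
mean-imputed only at construction. The single-step inverse is

    H^-1 = A^-1 + [0 0; 0 Gb^-1 - A22^-1]

with Gb = w G + (1-w) A22, default w = 0.95. Blending is required in
practice: unblended G is singular whenever the genotyped animals outnumber
the markers (and frequently ill-conditioned otherwise). With no genotyped
animals, or Gb = A22, H^-1 is exactly A^-1. All algebra is dense; the
intended scale is up to roughly 10,000 animals.

## The mixed-model engine

Henderson's equations are assembled with the random-regression structure
held implicitly (each record points at one animal and carries its Phi row),
solved by dense Cholesky; prediction-error (co)variance blocks per animal
come from the coefficient-matrix inverse (LAPACK `dpotri` on the factor).
Fixed-effect identifiability is resolved by pivoted QR: a maximal
independent column set is kept and aliased columns are constrained to zero
with a warning naming them. Estimable functions are invariant to this
choice; it generalizes drop-one-level constraints and is what the exact
CG/EC collinearity of the reaction-norm model requires.

Variance components are estimated by REML. EM updates (guaranteed ascent)
are used for warm-up and as a fallback; average-information (AI) updates
drive convergence. AI candidates are accepted whenever they stay inside the
parameter space; a likelihood decrease — visible at the next iteration's
solve — triggers a retreat to the previous iterate's EM update. This avoids
an extra Cholesky per trial step, which matters at the ~4,000-equation
scale where one factorization costs about two seconds. Convergence is the
largest relative parameter change below `tol` (default 1e-8; the replicated
recovery experiments use 1e-3, far below the resolution of their
cross-replicate standard errors). Variance components whose update falls
below 1e-5 of the problem scale (mean residual variance plus mean K
diagonal) are snapped to an effective-zero boundary value: EM decay toward
a boundary is geometric and would otherwise stall above any finite
tolerance. Reported log-likelihoods omit the constant -q/2 log|H| term, so
only differences are meaningful.

Per-coefficient accuracy is sqrt(1 - PEV_qq / K_qq), clamped to [0, 1];
animals must reach the threshold (default 0.40) on *both* intercept and
slope to enter SNP back-solving.

## SNP effects, tests, and inflation

Back-solving uses the genomic-BLUP identity over the retained genotyped
animals: alpha_q = Mc' Gb^-1 a_hat_q / (2 sum p_k q_k) for each coefficient
q. With unblended G this reconstructs the coefficient BLUPs exactly
(Mc alpha = a_hat), which is the package's central algebraic self-check.
The effect of SNP k at gradient level e is u_k(e) = alpha_k . phi(e); its
variance share is 100 * 2 p_k q_k u_k(e)^2 / sigma2_a(e) (the squared
effect: the unsquared form has wrong units and can be negative).

Testing standardizes effects genome-wide within each level. Effects are
first scaled by sqrt(2 p_k q_k): the sampling variance of a back-solved
effect is proportional to its marker's heterozygosity, and pooling
unscaled effects across allele frequencies yields a heavy-tailed scale
mixture — in the null experiments it deflated the inflation factor to
about 0.87 while inflating type-I error to about 0.014. With the scaling,
z = (s_k - mean s) / sd s for s_k = u_k / sqrt(2 p_k q_k), two-sided
normal p-values are calibrated (lambda in [0.93, 1.07], type-I error at
nominal). The per-SNP "self-standardization" u / sqrt(2 p q u^2), whose
magnitude is constant by construction, is kept behind `literal_z` for
inspection only. Significance is -log10(p) > 6 (configurable);
Benjamini-Hochberg q-values and the ratio-form estimate
n_markers * 0.01 / n_(p<0.01) are reported alongside. The genomic
inflation factor is median(z^2)/0.456 (the 1-df chi-square median
convention; the median-p variant, which equals ~1.096 for any null set, is
also computed for comparison).

Significant sets at the three levels are partitioned into the 7-cell Venn
layout (level-specific, pairwise-only, shared by all).

## Annotation

Entirely offline against user-supplied files: gene intervals from BED
(converted to 1-based inclusive on read) or GFF3, QTL intervals from BED
with trait labels, gene sets from GMT. Window mapping intersects the
closed interval [pos - w, pos + w] (default w = 200 kb; the "200 kb
region" reading is +/-200 kb flanks, configurable). LD is composite r^2 —
squared dosage correlation over animals with both calls observed — which
needs no phase information. Enrichment is the upper-tail hypergeometric
test against the annotation's full gene list as universe, BH-corrected at
5% FDR.

## The synthetic-data generator

The generator emulates the structure of a commercial tropical beef
population, which is what the analysis assumes and what its tests must
exercise:

- **Pedigree**: discrete generations; n_founders/2 matings per generation;
  dams drawn from the previous generation, sires from a small panel
  (default n_founders/25) sampled from the males of *all* earlier
  generations — artificial-insemination-style usage, the defining feature
  of the emulated populations. Consecutive offspring cycle the
  generation's CGs, so each sire's large half-sib family spans many CGs
  and therefore many gradient levels. This matters statistically: genetic
  slope variance is identified by relatives recorded in different
  environments, and with small families confined to few environments the
  REML likelihood can genuinely prefer a degenerate K (zero slope
  variance, |correlation| = 1) — an identification failure of the design,
  not an estimator artifact.
- **Genotypes**: founder dosages Binomial(2, p), p ~ Uniform(maf_range);
  descendants by gene dropping (one transmitted allele per parent); SNPs
  laid evenly over 29 autosomes. SNPs are unlinked — LD arises only from
  relatedness — which is the simplest null for the calibration
  experiments. QTLs are genotyped SNPs themselves, so back-solving is
  exactly recoverable.
- **Traits**: CG effects on the descriptor are Normal(230 kg,
  cg_mean_spread = 30 kg), giving standardized gradients spanning about
  +/-3 sd as in the source population (CG solutions 148-327 kg); the true
  gradient is the standardized true CG effect, and the estimated gradient
  from stage 1 can be compared against it. The target trait is built from
  per-animal (intercept, slope) coefficients = pedigree polygenic part
  (founders N(0, (1-f) K), Mendelian sampling at half that covariance) +
  centered QTL dosages times bivariate-normal effects scaled so QTLs carry
  fraction f (default 0.4) of K. Defaults: K = [[800, -200], [-200, 200]]
  days^2 (genetic correlation about 0.16 between gradient extremes, i.e.
  strong re-ranking), residual class variances 2500...1600 days^2
  declining with the environment, trait mean 1050 days — AFC-like scales
  with h^2 about 0.17 at the gradient center. An oracle mode
  (`qtl_fixed_effects`) fixes every QTL's magnitude at its exact variance
  share (random sign) for detection and asymmetry tests where effect-size
  sampling noise would otherwise dominate.

What the generator does **not** emulate: linkage maps and recombination
(no within-chromosome LD beyond relatedness), selection across
generations, genotyping-platform error, imputation error, parentage
errors, overlapping generations and seasonal culling. Tests passing on
these simulations therefore validate the estimator and its calibration
under the assumed model, not robustness to those real-data features.

## Replicated validation experiments

- **Parameter recovery**: 10 studies of 2,000 pedigree animals (500
  founders, 4 generations), 5,000 SNPs, 200 QTLs, ~40% genotyped, ~54 CGs
  (the source population's ~28 records per CG); AI-REML (tol 1e-3, max 25
  iterations) on the true gradient. Checks every K entry against truth
  within 2 empirical SEs and the extreme-level genetic correlation within
  0.15.
- **Null calibration**: 10 polygenic-only studies (1,200 animals, 3,000
  SNPs); solves at the generating variance components; checks lambda in
  [0.9, 1.1] per replicate and level, and pooled type-I error at 0.01
  within 3 binomial SEs.
- **GxE asymmetry**: slope-only QTLs must test stronger at EC +/-3 than at
  0 for >= 90% of loci; intercept-only QTLs must test evenly (mean |z|
  within 10% across levels). Ten fixed-magnitude QTLs at 5% of genetic
  variance each.

Problem sizes throughout are desk-scale choices: dense algebra on a few
thousand animals, which one CPU handles in minutes.

## Known limitations

- Dense O(n^3) algebra bounds the practical scale well below national
  evaluations (no sparse A^-1 exploitation, no APY).
- First-order (linear) reaction norms only by default; higher orders are a
  parameter but untested beyond the basis itself.
- Base-population allele frequencies, metafounders, and tuned tau/omega
  scalings of the H^-1 correction are not implemented.
- The accuracy filter is applied at back-solving only, not before REML.
- Single records per animal; no permanent-environment effect is separated
  from the residual.
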