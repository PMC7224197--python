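# Methods

`rootpheno` implements a two-step phenotyping-to-genomics pipeline for
clonally propagated crops whose storage roots are photographed on a
reference board at harvest: image-derived size/shape traits, plot-level
mixed models, genomic prediction, and association mapping. This note
documents the models, the numerical choices, and what the synthetic data
do and do not emulate.

## Image measurement chain

A board photograph is reduced to its hue channel (HSV hue scaled to 0-255;
grey pixels take hue 0 by convention). Two threshold passes binarise the
image: a circles pass keeping hue 125-255 selects the painted reference
circles, and a roots pass keeping the full hue range *minus* a
background-exclusion band (default hue 70-100, centred on the board's
green) selects everything that is not board. A literal full-range
threshold would select every pixel; the exclusion band reproduces the
intent — "everything non-green" — while the circle band is kept as stated
in the original protocol. Because the roots pass also captures the
reference circles, particles matching the detected circle signature
(circularity ≥ 0.85 and area within 25% of the mean detected circle area)
are removed from root tables.

Particles are 8-connected components; components below `min_area_px`
(default 500 px) are discarded as specks, and components touching the
image border are flagged and excluded (the field protocol requires roots
not to touch the board edge, and a clipped root would be mismeasured
anyway).

Per-particle descriptors:

- **area** — pixel count; converted to cm² by dividing by the squared
  scaling coefficient.
- **perimeter** — Crofton 4-direction estimate by default. The Freeman
  chain-code length (1 per axial step, √2 per diagonal) is available via
  `PhenotypingConfig(perimeter_method="chain")`, but it overestimates the
  length of smooth outlines by ~5% on average (the classic digitisation
  bias), which pushes the circularity of a digital disk down to ≈0.91.
  Crofton is near-unbiased on smooth convex outlines (disk r=50 px:
  circularity 0.992), so it is the default; the choice matters only for
  perimeter and circularity, not for the moment or hull descriptors.
- **Feret diameter** — the maximum caliper, computed as the largest
  pairwise distance among convex-hull vertices of the boundary pixels
  (pixels with a background 4-neighbour). This equals the brute-force
  maximum over *all* boundary-pixel pairs exactly, which the tests verify.
- **ellipse axes** — from the eigenvalues of the second central moment
  matrix, semi-axis = 2√eigenvalue, so a filled ellipse recovers its true
  semi-axes. Aspect ratio is major/minor; for near-1-D particles the minor
  semi-axis is floored at 0.5 px and the particle flagged.
- **circularity** = min(1, 4π·area/perimeter²), capped because
  digitisation can push the raw ratio slightly above 1 on small particles.
- **roundness** = 4·area/(π·major²); **solidity** = area / convex-hull
  pixel area (hull from the filled convex-hull image, so solidity ≤ 1 by
  construction).

**Scaling.** Painted circles of known diameter d (default 7.5 cm) are
detected in the circles pass, filtered by circularity ≥ 0.85 and mutual
area consistency (each within 25% of the median candidate); at least three
accepted circles are required, otherwise the image is skipped with an
error. The pixels-per-cm coefficient is `sqrt(mean circle area px² /
(π(d/2)²))`; lengths are divided by it and areas by its square. On
synthetic boards the true coefficient is recovered within 0.2%.

## Plot traits and stage-1 mixed models

Per-plot traits are the mean and the sample standard deviation (n−1) of
each descriptor over the plot's imaged roots; the SD — a uniformity trait —
is defined only for plots with ≥ 2 measured roots. An optional natural-log
transform is applied to the plot-level value before model fitting
(non-positive values are dropped with a logged count); log10 would only
rescale the variance components. Grand means for the
coefficient-of-variation statistics are always taken on the original
measurement scale.

Four model variants are fitted by REML:

    y = X m + Z_clone c + Z_range r + e,        c ~ N(0, I σ²_c), r ~ N(0, I σ²_r)

Models 1/2 group plots by range; models 3/4 by range nested in location
(for multi-location trials). Models 1 and 3 include the plot CMD severity
score (1-5) as a fixed covariate next to NOHAV (number of harvested
plants); models 2 and 4 fit NOHAV only. Constant covariates are dropped
with a warning. Checks are ordinary replicated clones; no separate check
effect is fitted.

**REML engine.** The residual variance is profiled out and the two log
variance ratios γ_i = σ²_i/σ²_e are optimised by Nelder-Mead (two starts,
likelihood tolerance 1e-6, ratio floor 1e-8 treated as a boundary zero).
All linear algebra runs in the q-dimensional random-effect space through
the Woodbury identity (H⁻¹ = I − Z(Γ⁻¹+Z'Z)⁻¹Z'), so the per-iteration
cost is O(q³) rather than O(n³); a 1,000-plot, 500-clone fit takes well
under a second. The optimum is validated in the tests against an
exhaustive dense-matrix profile-likelihood grid on a 30-plot toy.

Clone BLUPs (EGVs) and their prediction-error variances come from the
mixed-model equations at the REML estimates; reliability is
r² = 1 − PEV/σ²_c, and the de-regressed EGV is EGV/r², with clones below
a reliability floor (default 0.1) set missing. De-regression follows the
plain reliability division — no parent-average decomposition and no
weighting of records downstream.

**Variability statistics.** H² = σ²_c/(σ²_c+σ²_e) on the plot basis by
default (the range variance can be added to the phenotypic variance via a
flag; both conventions are computable because published tables do not pin
the convention down). GCV = 100·√σ²_c/μ and PCV = 100·√σ²_p/μ with μ the
raw-scale grand mean.

## Genomic prediction

Marker QC applies, in order: clones with > 80% missing calls, markers with
> 60% missing, markers with Hardy-Weinberg χ² > 20 (1 df, observed
genotype counts vs expectation at the sample allele frequency), and
markers at MAF ≤ 0.01. Remaining gaps are mean-imputed per marker — a
deliberate, documented stand-in for haplotype-based imputation of real
GBS data, adequate for the low missingness the simulations produce.

The genomic relationship matrix is VanRaden's: G = WW'/(2Σp(1−p)) with
W the column-centred dosages; a 1e-6 diagonal ridge keeps it numerically
positive semidefinite. GBLUP (y = 1μ + g + e, g ~ N(0, Gσ²_g)) is fitted
by REML through the spectral decomposition of G restricted to phenotyped
clones — a single bounded 1-D optimisation over the log variance ratio —
and unphenotyped clones are predicted via
ĝ = σ²_g·G[:,train](σ²_g·G_train + σ²_e·I)⁻¹(y − μ̂). With G = WW'/c this
reproduces ridge-regression marker predictions to machine precision,
which the tests assert.

Cross-validation partitions **clones** (never plots) into k = 5 near-equal
folds, repeated 25 times; folds with fewer than 3 clones trigger a
re-draw. Accuracy per fold is the Pearson correlation between GEBVs and
the held-out de-regressed EGVs; the summary reports the mean and the SD
over all fold values. When the fitted genetic variance hits the zero
boundary the GEBVs are constant and the correlation is undefined; such a
predictor carries no information and is scored as accuracy 0. Under null
phenotypes the mean accuracy is within ±0.1 of zero at 500 clones; note
that all folds share one phenotype draw, so at small panel sizes the mean
fold accuracy itself fluctuates with an sd of ~0.1 across draws.

## Association mapping

The GWAS statistic is the mixed-linear-model association with a
leave-one-chromosome-out (LOCO) relationship matrix: for each chromosome,
G is rebuilt from all *other* chromosomes and the null model y = μ + u + e
fitted once by REML; every marker on the chromosome (MAF > 0.05, computed
symmetrically from allele counts) is then tested by GLS under the null
covariance, with the Wald χ² on 1 df. All per-marker algebra runs in the
eigenbasis of G_loco, so a 5,000-marker scan over 18 chromosomes takes a
few seconds at 500 clones. If the null genetic variance is at the
boundary the statistic reduces smoothly to ordinary least squares (a
warning is logged). Variance components are estimated once per chromosome,
not per marker. No covariates beyond the intercept are fitted: phenotypes
entering GWAS are stage-1 de-regressed EGVs, and any CMD adjustment
belongs in stage 1.

The significance cutoff is always the Bonferroni threshold computed from
the number of markers actually tested, −log10(α/n), never a hard-coded
constant.

The CMD-confound contrast runs the whole two-step pipeline twice on one
simulated trial — stage 1 without the CMD covariate, then with it — and
compares the association strength at the designated confound QTL and at a
direct-effect QTL. With a heritable severity score (confound correlation
0.6) and a CMD effect on the trait, adjustment removes the confounded
QTL's significance (median −log10 p drops from ~25 to ~0.3 in the
acceptance runs) while the direct QTL stays significant under both — the
qualitative signature of a disease-resistance locus masquerading as a
size/shape QTL.

## Synthetic data: what it emulates, what it does not

**Boards.** Roots are rotated superellipses (|x/a|ⁿ + |y/b|ⁿ ≤ 1;
exponent 2 = ellipse, larger exponents give blockier, more cylindrical
outlines) with analytic area (4ab·Γ(1+1/n)²/Γ(1+2/n)), perimeter
(parametric quadrature) and maximum caliper (2·max radial distance, valid
for these centrally symmetric convex shapes). Default shape ranges
(semi-major 6-16 cm, aspect ratio 2-5, exponent 2-4) put root areas in
the ~25-350 cm² range reported for field-grown cassava storage roots.
Objects are placed by rejection sampling with a 5 px margin between
bounding circles and from the border; reference circles sit at fixed
positions along the left and right edges. Hues are exact constant bands,
so segmentation is easy by construction: the synthetic boards validate
the *geometry* of the measurement chain, not its robustness to shadows,
soil, specular highlights or uneven illumination, which they deliberately
omit.

**Genotypes.** Independent biallelic markers, dosage ~ Binomial(2, p)
with p ~ Uniform(maf_range), assigned to 18 chromosomes (the cassava
karyotype) in contiguous blocks. There is no linkage disequilibrium,
pedigree, or population structure; LOCO therefore protects against
proximal contamination but is not stress-tested against stratification.

**Trials.** An augmented clonal-evaluation layout: every clone gets
`plots_per_clone` plots arranged in ranges of 20 plots, with 2 check
plots (from a pool of 5 check clones) added to every range — replicated
checks are what keep σ²_c identifiable at one plot per entry. NOHAV is
discrete uniform on {2,3,4} with a small negative default slope; CMD
severity is an integer 1-5 obtained by cutting a latent Gaussian — tied
to the confound QTL's standardised dosage with the configured
correlation — at equal-probability normal quintiles (the discretisation
attenuates the realised correlation by ~4%, still inside the ±0.1 check
band). Genetic values are explicit QTL effects plus a dense polygenic
term, jointly rescaled so the plot-basis heritability
σ²_c/(σ²_c+σ²_e) hits its target exactly in the realised sample. Every
phenotype decomposes exactly into stored components (grand mean, genetic
value, range effect, covariate contributions, residual), which a test
checks to machine precision.

## Problem sizes used in the validation runs

Chosen as the package's own study conditions: stage-1 recovery at 500
clones × 2 plots with true (σ²_c, σ²_r, σ²_e) = (1, 0.5, 1) over 20
seeds; null-heritability runs at 250 clones × 10 plots (heavy replication
so the REML sampling spread of σ̂²_c, ~0.009 here, sits well inside the
2%-of-residual boundary band; at 2 plots/clone the spread is ~0.05 and no
clone count near 500 can satisfy that band); GBLUP cross-validation and
GWAS calibration at 500 clones with 1,500-5,000 markers; power runs with
a QTL explaining 20% of phenotypic variance over 10 seeds.

## Known limitations

- No spatial (row-column) modelling, multi-trait stage-1 models,
  Bayesian-alphabet predictors, multi-kernel/G×E prediction, or
  multivariate GWAS; the association CSV schema leaves room for a future
  multivariate extension.
- Mean imputation is a stand-in for haplotype imputation and would be
  inadequate at GBS-level missingness.
- Real-data prediction accuracies from the motivating field populations
  are not reproducible from synthetic data at desk scale and are not
  claimed; the simulations validate calibration, equivalences and
  parameter recovery, not field performance.
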