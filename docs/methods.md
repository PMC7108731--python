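# Methods

## Model and testing framework

All tests are score tests under a Gaussian linear model. For each trait the
null model regresses the (inverse-normalised, residualised) trait on an
intercept plus covariates by OLS; the residual variance is estimated as
RSS/(n−k). With projected, weighted mask genotypes the per-variant score
vector U and its null covariance V are sufficient statistics for every
aggregation test:

- **Burden (ρ=1)**: Q = (1'U)²/(1'V1), χ²₁ null. Used for LoF masks, where
  effects are expected to share direction.
- **SKAT (ρ=0)**: Q = U'U, null a positively weighted sum of χ²₁ with the
  eigenvalues of V. Robust to mixed effect directions.
- **SKAT-O**: Q_ρ over the grid {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1};
  the omnibus p of the minimum per-ρ p is computed by decomposing Q_ρ into a
  common burden-direction χ²₁ mixing variable plus an independent residual
  mixture, and integrating the conditional distribution over the mixing
  variable (ρ = 1 is evaluated at 0.999 inside this decomposition, as in the
  method's reference formulation). The reported p is clamped to
  [min-ρ p, grid-size × min-ρ p], the analytic bounds of a min-p statistic.
  A grid of length one collapses exactly to the corresponding single test.

Per-variant weights default to the Beta(1,25) density of the within-cohort
MAF — the conventional default of this test family, which the source design
leaves unstated — with a flat option. Missing dosages are mean-imputed
(2×MAF of the analysed samples) inside the engine only; stored genotypes are
never modified.

**Small-sample moment adjustments are not applied**: target cohorts are in
the thousands, and the synthetic defaults (800/700) are large enough that
the type-I suite verifies calibration directly. This is a documented
limitation for very small n.

## Quadratic-form tail probabilities

P(Σλᵢχ²₁ > q) is computed by numerically inverting the characteristic
function (Imhof's integral). The integrand oscillates with slowly decaying
envelope; the implementation brackets the sign changes of the phase
analytically (the phase has a single maximum, then decreases strictly),
integrates each sign-constant segment with a fixed Gauss rule, and sums the
alternating series, Euler-accelerating it when it has not converged within
48 descent segments. Absolute accuracy is ~1e−9 in the regimes where the
inversion is used; agreement with 10⁶–10⁷-draw Monte-Carlo oracles is within
3 standard errors across eigenvalue spectra including near-degenerate and
two-scale cases. Deep tails (p below ~10⁻¹⁰) and loose-accuracy calls use
the Kuonen saddlepoint approximation (relative error ~10⁻³); the
Liu–Tang–Zhang moment-matching approximation is the final fallback and also
supplies the quantile guesses used inside SKAT-O. The method actually used
is recorded in each result's notes.

## Meta-analysis

Cohorts are combined homogeneously (shared effect sizes): per-cohort (U, V)
are embedded on the union variant list — absent variants contribute zero
score and zero variance — and summed, after which any single-cohort test
applies unchanged. This makes the meta-analysis exact in the score domain
and lets masks with zero overlapping variants combine, as required when the
discovery and validation platforms capture different sites. Heterogeneous
(random-effect) combination is out of scope. Permutation p-values are
combined with unweighted one-sided Stouffer; the tails arithmetic of the
reported results is consistent with the unweighted form.

## Phenotype preparation

Samples with more than 30% trait missingness are removed (strictly more:
exactly 30% is retained). Traits are rank-inverse-normalised with the Blom
offset, Φ⁻¹((rank−3/8)/(n+1/4)), average ranks for ties; the offset choice
affects only extreme ranks and is not stated by the source design.
Residualisation on covariates is done per cohort. Trait-specific sample
exclusions (assay artefacts) are supported as a configurable exclusion list
rather than hard-coded chemistry rules.

## Decision layer

Covariate boosting: a trait qualifies as a validation-stage covariate for an
outcome iff (i) no evidence of genetic correlation with it — external rg
p > 0.05, missing entries fail; (ii) in-sample phenotypic correlation
|r| > 0.10 (absolute value; the source states ">10%" without sign); (iii) a
different biomarker supergroup. Covariates enter only at the validation
stage, preserving an unadjusted discovery gate and limiting collider bias.

Effective numbers of tests are the smallest number of principal components
of the trait (or gene-set) correlation matrix explaining more than 95% of
variance; pairwise-complete correlations are repaired to the nearest PSD
matrix by eigenvalue clipping when missingness makes them indefinite.
Thresholds are exact Bonferroni quotients; with the published counts they
evaluate to 2.5×10⁻⁶ (gene), 1.32×10⁻⁷ (gene × 19 effective traits),
2.41×10⁻⁶ (gene-set), 3.7×10⁻⁴ (tails), 0.005 (GWAS-proximal).

Replication requires the corrected meta threshold, more than two variants
tested, and nominal validation significance in the unadjusted test.
Leave-one-out declares an association single-variant-driven when some
removal lifts p above 0.05 (driver = removal with the largest p; ties go to
the lower variant index); the conditional-test route (absorbing a chosen
variant into the null design) is also provided, since the source describes
both conventions without reconciling them, and reports state which was used.

Analytic power uses the two-sided 1-df chi-square approximation with
non-centrality n·2·MAF·(1−MAF)·β².

## Tails enrichment

Tails are the k = 10 most extreme participants per side (0.5%/1% percentile
modes for sensitivity); boundary ties break deterministically by sample id.
Traits sharing ≥ 8 tail participants with a previously retained trait are
greedily pruned in input order. The counting statistic is the dosage sum
(heterozygote 1, homozygote 2) over combined-mask variants with cohort
allele count strictly below 10 — "allele count" read literally. The
empirical p over 10,000 random k-subsets of the trait's non-missing samples
uses the add-one convention (r+1)/(n+1), which keeps p strictly positive as
Stouffer requires; one RNG stream per (trait, side, gene-set) is derived
from the master seed and a stable hash, so results are reproducible and
independent of evaluation order. Enrichment requires discovery p < 0.05
(gate), meta p at or below the corrected threshold, and validation p < 0.05.

Because the count statistic is integer-valued, permutation p-values are
discrete and slightly conservative; the calibration test bounds the
Kolmogorov–Smirnov distance to U(0,1) by a threshold that accommodates the
maximal point mass of the count distribution and separately checks that
rejection at the 5% level never exceeds it materially.

## Synthetic data

The generator emulates the two-cohort design at reduced size (defaults
800/700 against the original 3,741/3,401): per-site binomial(2, MAF)
genotypes with a log-uniform MAF spectrum on [1/(2n), 0.05]; a configurable
fraction of sites shared between cohorts at equal MAF, the rest private
(reproducing the partial-overlap regime of real platform pairs);
LoF/missense annotations with Beta-distributed M-CAP-like scores; and traits
from a supergroup-structured latent factor model (optionally plus one global
factor for cross-supergroup correlation) with small covariate effects and
Gaussian noise. Genetic effects are placed on mask-qualifying variants only,
with uniform-burden, single-driver or heterogeneous architectures; an effect
can be specified by per-allele β or calibrated to a target non-centrality
(summed over cohorts at unit residual variance). The genetic-correlation
table is derived from the generator's known sharing structure — pairs of
traits with a common causal gene are marked correlated — rather than
estimated, so covariate selection is exercised deterministically.

What the generator does **not** emulate: linkage disequilibrium (sites are
independent — rare variants are near-independent and the tests operate at
the mask level), population structure, relatedness, genotype-calling error,
and the heavy-tailed measurement distributions of real NMR data (the
inverse-normal transform makes the tests insensitive to the latter).
Passing suites therefore demonstrate the statistical machinery, calibration
and recovery behaviour — not robustness to upstream data-quality issues,
which the source design handles in QC stages that are out of scope here.

Study conditions used by the verification suites (chosen once as the
synthetic study design): type-I calibration uses 2,000 null replicates of
n=400 with 10-variant masks, checked against the exact binomial 99%
interval at α=0.05 for all three tests and their two-cohort meta versions.
Architecture recovery uses 50 replicates of the 800/700 design with flat
weights (matching the per-allele-uniform injected architecture); the
uniform-burden effect is calibrated to total NCP 50, giving ~96% analytic
detection at 1.32×10⁻⁷, and the single-driver effect to NCP 50 on the
driver, with leave-one-out run on the omnibus test. Covariate boosting uses
100 replicates of a 450/400 design whose eligible covariate absorbs roughly
half the outcome's non-genetic variance. Tails checks use a 400-sample null
cohort with ~240 qualifying variants (so the count statistic is nearly
continuous) and 20 planted-signal seeds at 1,000 samples.

## Numerical and degenerate-input conventions

Monomorphic or fully design-collinear masks are flagged untestable rather
than raising; single-variant masks make burden, SKAT and SKAT-O coincide
exactly; conditioning columns collinear with the design are dropped with a
warning; constant trait vectors and rank-deficient covariate matrices are
errors naming the offending columns. Duplicate gene-set names are renamed
deterministically. VCF reading rejects multiallelic records by variant id;
variant identity is the chrom:pos:ref:alt string, and a variant annotated
against several genes may enter each gene's mask but is counted once per
gene.
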