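# Methods

## The model

`kinherit` decomposes the variance of a prepared quantitative trait in
related individuals into an additive-genetic and a residual component:

    y ~ Normal(Xβ, σ²g·K + σ²e·I),    h² = σ²g / (σ²g + σ²e)

where K is a relatedness matrix on the 2Φ scale (Φ the kinship
coefficient: the probability two alleles sampled from a pair at one
autosomal locus are identical by descent). A parent–offspring or
full-sib pair has K = 0.5; a non-inbred individual has K(i,i) = 1. K can
come from two sources that the package treats as interchangeable:

- the genealogy, through the standard recursion (parents evaluated
  before children; founders mutually unrelated and non-inbred), giving
  the expectation of relatedness — exactly block-diagonal across
  families and positive semidefinite by construction;
- genome-wide markers, through the allelic-correlation GRM, giving the
  realized relatedness, nonzero for every pair and noisy with finite
  marker panels.

### Fitting

The likelihood is maximized by rotating the model through a single
symmetric eigendecomposition K = U Λ Uᵀ. In the rotated basis the
covariance is diagonal, σ²t·(h²λᵢ + 1 − h²) with σ²t = σ²g + σ²e, so for
any fixed h² both β (by GLS) and σ²t (by ML) are closed-form, and the
profile log-likelihood is a smooth scalar function of h² maximized by
bounded Brent search on [0, 1] (xatol 1e−8; the endpoints are evaluated
explicitly since a bounded search never lands exactly on them).
Estimates within 1e−6 of an endpoint are reported as exactly 0 or 1
with a boundary flag.

The likelihood-ratio statistic Λ = 2(ℓ_full − ℓ_null), with the null a
pure-noise Gaussian fit (σ²g = 0), is referred to the ½χ²₀ + ½χ²₁
mixture appropriate for a variance component on its boundary;
Λ = 0 reports p = 1. The SE of ĥ² is the delta-method value from the
numerical curvature (central differences, step 1e−4) of the profile
log-likelihood at the optimum, and is reported missing at a boundary,
where the quadratic approximation is invalid. ML rather than REML is
the default because the inference is LRT-based; at the target scale
(hundreds of individuals, ~12 fixed effects absorbed beforehand) the
ML/REML difference in ĥ² is well under 0.01.

### Kinship scale

K is internally normalised by its mean diagonal before fitting. This
makes ĥ², Λ and p exactly invariant to a global rescaling of K — the
perennial Φ-versus-2Φ ambiguity — while σ̂²g is reported on the scale of
the K actually supplied (so halving K doubles σ̂²g). When the mean
diagonal is 1 (any non-inbred pedigree matrix, any postprocessed GRM)
the identity h² = σ²g/(σ²g+σ²e) holds exactly in the reported numbers.

### Indefinite matrices

Postprocessing an empirical matrix (below) can break positive
semidefiniteness. Rather than refuse such input, eigenvalues are
clipped below at 1e−8 and the clip count is carried on the fit; the
likelihood is then that of the nearest usable model. A kinship that is
numerically an identity matrix carries no relatedness signal, so
`fit_polygenic` raises an "unidentifiable" error for it (the
association scan instead fixes h² = 0 there, since its per-SNP test is
well-defined and reduces exactly to ordinary regression).

## Empirical kinship

The built-in estimator is the allelic-correlation GRM

    K(i,j) = (1/m) Σ_s (g_is − 2p_s)(g_js − 2p_s) / (2 p_s (1 − p_s))

with allele frequencies computed from the analyzed samples, a MAF floor
(default 0.01) to keep the per-SNP scaling stable, and missing dosages
mean-imputed to 2p (i.e. contributing nothing after centering). Its
off-diagonal expectation under Mendelian transmission is 2Φ, which the
tests verify against gene-dropped pedigrees for parent–offspring,
full-sib, second-degree and unrelated pairs. LD-weighted or
HMM-smoothed estimators are deliberately not reimplemented; externally
computed matrices enter through `import_kinship` (square or long CSV)
and flow through the same postprocessing, comparison, and model code.

Raw GRM diagonals spread around their expectation of 1 and small
negative off-diagonals are ubiquitous. `postprocess_kinship` first sets
every strictly negative entry to zero, then rescales per pair,
K(i,j)/√(K(i,i)K(j,j)), which fixes the diagonal at exactly 1 no matter
how spread it was (a single global divisor could not). Zeroing-first
matters: the operation in this order is idempotent and sign-preserving.
"Removing" a negative value is interpreted as setting it to zero, since
deleting a matrix entry has no meaning. A non-positive diagonal entry
is treated as a data error, not something to patch.

## Relationship screening

The method-of-moments IBD estimator counts identity-by-state (IBS)
outcomes per pair and solves sequentially for the IBD-0/1/2 proportions
using their expected IBS distribution given allele frequencies (the
`--genome`-style moment chain), then projects onto the simplex by
truncation and renormalization. The estimated kinship coefficient is
φ̂ = ¼·IBD1 + ½·IBD2. It assumes near-independent markers, hence it is
run on the LD/HWE-pruned panel, and warns below 200 informative SNPs.

Classification uses the standard power-of-two kinship bands
(0.354, 0.177, 0.0884, 0.0442 bounding duplicate/1st/2nd/3rd-degree/
unrelated), with IBD0 < 0.1 splitting parent–offspring from full
siblings inside the 1st-degree band.

The discordance report compares each within-family pair's inferred
class with the class expected from the genealogy. Because adjacent
bands share a boundary and the true 3rd-degree coefficient (0.0625)
sits mid-band, occasional one-band flips are expected sampling noise in
a clean data set; the exclusion proposal therefore keys on *strong*
discordances — two or more degrees apart, e.g. a recorded 1st-degree
pair measured unrelated. A swapped sample breaks every one of its
genotyped relationships at once, so individuals in ≥ 2 strong
discordances are proposed; a strong discordant pair attributable to
neither member alone proposes both. All class mismatches, including
one-band flips, remain in the report table with a severity column.

## Trait preparation

Phase values average the available visit measurements (two pre, two
post; a single observed visit stands alone). Residualization is OLS on
intercept, age, sex, age×sex, age², age²×sex, dummy-coded center,
smoking, and ancestry PCs where present — always all of them, with no
significance-based covariate selection, for determinism. Ancestry PCs
are fit on pedigree founders only (standardized by founder allele
frequencies, SVD) and all samples are scored by projection, so the PCs
reflect population structure rather than family structure. The
inverse-normal transform maps average ranks (Blom offset 0.375) through
the normal quantile function and then re-standardizes exactly, giving
mean 0 and SD 1 to machine precision; it is monotone and invariant to
affine transforms of its input. Order follows the conventional
pipeline: residualize first, transform second.

## Association (measured genotype analysis)

Each SNP's alternate-allele dosage (missing values mean-imputed per
SNP) enters as a fixed covariate; the 1-df LRT against the no-SNP model
gives the p-value, and β̂ with its GLS standard error is reported with
the allele labels so the effect direction is unambiguous. Two modes
share one eigendecomposition of K: **exact** (default) re-estimates the
variance components under every SNP model; **fast** holds them at the
null fit, reducing each SNP to a vectorised weighted regression. At
study scale (n ≈ 800) the two agree within 0.1 on −log₁₀p across a null
scan — the fast path is intended for replicate-heavy power studies.
Scan inclusion requires MAF ≥ 0.01 and missingness ≤ 0.1 (configurable);
skipped SNPs are recorded with reasons. Flags: suggestive at the fixed
convention P ≤ 1×10⁻⁵, genome-wide significant at Bonferroni α/m.
Genomic inflation λ is the median statistic over the χ²₁ median.

## LD pruning

Pruning slides per variant: each SNP, in map order, is compared against
the retained SNPs within the trailing window (SNP-count units, the
convention when no kb suffix is given), and the lower-MAF member of any
pair with r² above threshold is dropped (input order breaks ties,
pairwise-complete observations for r²). Sliding per variant is the
step = 1 limit of advancing the window in steps and is at least as
strict, so the guarantee — no retained within-window pair above the
threshold — holds uniformly. Note that re-pruning an already-pruned
panel can remove a few more SNPs when previously distant,
chance-correlated pairs compact to within a window, exactly as with
the common index-windowed tools; with the window spanning the panel the
operation is idempotent.

## The synthetic study generator

The generator emulates the structure the pipeline assumes, at the scale
of a GOLDN-like cohort. Defaults:

| parameter | default | meaning |
| --- | --- | --- |
| n_families | 60 | three-generation template: founding couple, 3 offspring each married to a founder, 2 grandchildren per couple → 14/family, 840 total |
| n_snps | 10,000 | independent biallelic markers; optional block LD via haplotype copying (`ld_rho`) |
| maf | U(0.05, 0.5) | founder allele frequencies |
| true_h2 | 0.4 | σ²g/(σ²g+σ²e) of the non-QTL variance |
| qtl | none | (snp index, variance fraction) of a single additive variant |
| visit_noise_sd | 0.2 | iid measurement noise per visit; averaging 2 visits leaves σ²/2 = 0.02 extra variance (h² dilution < 1%) |
| age_slope, sex_difference, center_offsets, smoking_effect | 0.01, 0.25, (0, ±0.1), 0.2 | fixed covariate effects on the latent trait |
| post_shift | −0.5 | intervention effect on the post-phase mean |

Genotypes are gene-dropped: founders drawn from Hardy–Weinberg,
children inheriting one uniformly chosen allele per parent per SNP.
The polygenic value is sampled through a symmetric square root of K
(eigen-based) rather than by recursive within-pedigree Mendelian
sampling, because it works for any PSD matrix including empirical ones.
Ages are drawn per generation band, centers assigned per family, and
smoking independently — covariates are confounder-free by construction,
so residualization is exercised without being load-bearing for
unbiasedness. The `planted_swap` option exchanges two individuals'
genotype rows (not phenotypes), reproducing the classic sample-handling
error a relationship screen must catch. Dropping unique founder allele
labels instead of alleles (`gene_drop_ibd`) turns the same machinery
into a Monte-Carlo oracle for expected relatedness.

What the generator does **not** emulate: realistic LD and recombination
maps, ascertainment, genotyping error, pharmacodynamics of the
intervention, household/shared-environment components, and
cross-pedigree cryptic relatedness. Passing tests therefore demonstrate
correctness of the estimators under their own model assumptions, not
robustness to the full messiness of real cohort data.

## Evaluation runs and problem sizes

`kinherit.evaluation` (used by both the acceptance test suite and
`scripts/acceptance.py`) fixes the study conditions:

- kinship oracle: 10 random ≤20-member pedigrees, 20,000 label drops;
  recursion must sit within 3 Monte-Carlo SE entrywise (entries with
  zero MC variance — founders, parent–offspring — must match exactly).
- heritability recovery: h² ∈ {0.2, 0.42, 0.55, 0.8}, 60 families, 100
  replicates each through the full preparation pipeline; the small
  systematic dilution from visit noise plus residualization (~0.02) is
  part of the measured bias.
- LRT calibration: 1,000 null replicates at α = 0.05. The ½χ²₀+½χ²₁
  reference is known to be mildly conservative in finite family
  samples: at the 60-family scale the measured size is ≈ 0.034 (pooled
  7,500 replicates) with P(Λ = 0) ≈ 0.58, moving toward the nominal
  0.05 and P(Λ = 0) = ½ as the number of independent families grows
  (≈ 0.048 at 150 families, P(Λ = 0) ≈ 0.52 at 400). This is a
  property of the mixture approximation at moderate effective
  information, not of the implementation, which is pinned by the dense
  likelihood oracle.
- pedigree-vs-GRM concordance: 50 replicates, fresh 10,000-SNP panels,
  paired fits on identical prepared traits.
- association: one 5,000-SNP exact-mode null scan for λ; 150 fast-mode
  replicates for planted-QTL power (genotypes redrawn per replicate so
  the detection and coverage rates are marginal over the generative
  process, not conditional on one genotype draw).
- relationship screen: 60 families, 10,000 independent markers, one
  random cross-family swap, plus 500 random cross-family pairs for the
  unrelated class.

All randomness in these runs descends from one integer seed via
`numpy.random.SeedSequence`.

## Known limitations

- Single-component model: no dominance, household, or bivariate
  extensions; no linkage analysis or genomic prediction.
- The moment IBD screen is a screen, not a likelihood method: its class
  boundaries are heuristic and third-degree inference is intrinsically
  noisy.
- HWE uses the χ² test (an exact test is not provided); binary PLINK
  BED files are not parsed (text PED/MAP, dosage tables, and VCF are).
- Coordinates are taken as given; no liftover, strand-flipping, or
  imputation.
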