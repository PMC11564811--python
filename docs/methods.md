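# Methods

This note records the models, conventions and numerical choices behind
`cardioatlas`, the defaults of its synthetic-data generator, and what the
validation experiments do and do not demonstrate.

## Shape model and atlas

A subject's observation is a surface mesh of P corresponded 3-D points in
mm, flattened to a 3P shape vector. The generator produces subject i as

x_i = template + Σ_k z_ik · sd_k · √P · U_k + ε_i,

followed by an independent random rotation and translation. The U_k are
fixed orthonormal 3P displacement fields, drawn once per field seed and
orthogonalized against the template's six-dimensional rigid-motion subspace
(three translations, three infinitesimal rotations) so that alignment
cannot absorb shape variation. The √P factor makes sd_k the per-point RMS
displacement in mm at one latent SD, the same scale as the template
geometry and the noise. Latent scores z_ik are empirically standardized to
zero mean and unit variance per cohort; ε is iid N(0, noise_sd²) per
coordinate. The template is two ellipsoidal shells (LV-like and RV-like)
sampled deterministically by a Fibonacci spiral; only point correspondence
and scale matter downstream, not anatomical fidelity.

Generalized Procrustes analysis aligns with translation and rotation only
(Kabsch/SVD with determinant sign correction; scale and reflection never
applied), iterating mesh-to-consensus alignment and re-averaging until the
RMS consensus change is below 1e-9 mm or 100 iterations, starting from the
first mesh. The consensus frame is arbitrary up to a global rotation;
`align_atlas_frame` re-expresses an atlas in a reference frame when modes
must be compared across atlases or to generator truth.

PCA uses thin SVD of the centered data matrix (stable when 3P ≫ n),
eigenvalues with the n−1 divisor, and a deterministic sign convention
(largest-|loading| coordinate of each mode made positive). Z-scores divide
the projection by √λ_k so training scores have unit variance — the
convention under which logistic effect sizes read "per SD". Scoring
refuses modes whose eigenvalue is below 1e-12 of the leading one.

Subgroup variance explained: subgroup meshes are rigid-aligned to the atlas
mean, deviations are taken about the subgroup's own mean vector, and the
statistic is 100 × Σ‖projection onto the selected modes‖² / Σ‖deviation‖².
With all nonzero modes and the training set this is exactly 100%, which
pins the convention; whether deviations should instead be taken about the
atlas mean is genuinely open, and the chosen form is the one that makes the
training-set identity hold.

## Quality control

Four scores per subject: (1) contour fit error — mean distance from each
contour point to the nearest model point (nearest-vertex approximation via
a k-d tree; adequate for dense meshes, a documented simplification versus
point-to-triangle projection); (2) the first 10 PC z-scores, fenced per
component; (3) Mahalanobis distance √Σ₁⁰ z² (a true Mahalanobis distance
because scores are unit-variance and uncorrelated); (4) projection residual
— RMS per-point distance between the aligned mesh and its reconstruction
from the first 10 modes.

Fences: a score is flagged when it lies more than 5 IQRs above the lower
quartile or below the upper quartile, i.e. outside [Q3 − 5·IQR, Q1 + 5·IQR].
This band contains the interquartile range whenever the multiplier exceeds
1 and is slightly tighter than Tukey's [Q1 − 5·IQR, Q3 + 5·IQR], which is
available via `fence="tukey"`. The tighter rule is the default because it
is the coherent reading of the stated exclusion rule and because it is the
variant under which 8-SD shape outliers are reliably caught: for clean
10-mode scores the Mahalanobis distance follows a chi distribution whose
Q1 + 5·IQR fence sits near 7.3, safely below the ≥ 8 distance of an 8-SD
outlier, whereas the Tukey fence sits near 8.3 and misses a nontrivial
fraction. Quartiles use linear interpolation between order statistics
(numpy's default); fence placement depends on this, so it is fixed here.
Degenerate input (IQR = 0) flags values away from the median beyond an
absolute tolerance; constant data yields no flags. A subject is excluded
when any score is flagged.

## Genotypes and phenotype coupling

Dosages are built from two haplotypes per subject. Within an LD block of
`ld_block_size` variants, haplotype-level latent Gaussians share a factor
with loading √ld_rho (equicorrelation `ld_rho`); the allele is the
indicator that the latent value falls below the MAF quantile, so marginal
genotype frequencies are Hardy–Weinberg by construction. Blocks are
independent. Thresholding attenuates the realized dosage correlation below
the latent value (tetrachoric attenuation, e.g. latent 0.9 → dosage r² ≈
0.5 at MAF 0.5), which the tests account for by measuring emitted LD
directly. Variants sit at 10 kb spacing, 2000 per synthetic chromosome,
1-based positions; windows are closed intervals.

With genotypes present, latent score k is √h2 · (standardized weighted sum
of `causal_per_mode` standardized causal dosages) + √(1−h2) · standardized
noise; causal sets are disjoint across modes; both parts are empirically
standardized so the realized genetic variance share matches `per_mode_h2`.

Covariates use documented defaults (age ~ N(55, 8²) yr, height ~
N(170, 9²) cm, BMI ~ N(27, 4.5²) kg/m², SBP ~ N(138, 18²) mmHg, heart rate
~ N(69, 11²) bpm, sex ~ Bernoulli(0.5)); real covariates co-vary with shape
in ways the generator does not attempt to emulate, so covariate-adjustment
behavior on real data is not demonstrated by these tests. Binary outcomes
follow logit = intercept + Σ_k logOR_k · z_ik (+ optional standardized
covariate terms), with the intercept solved by Brent root-finding so the
expected prevalence hits the target.

## Association, loci and conditional signals

The scan is per-variant OLS of phenotype on dosage plus covariates.
Covariates (plus intercept) are residualized out of the phenotype and all
dosages once; by Frisch–Waugh–Lovell the per-variant slope, SE (df = n −
covariates − 2) and t-test are identical to the joint fit. Missing dosages
are mean-imputed (post-QC missingness < 1.5%); constant dosages are skipped
with a warning. Variant QC keeps MAF > 1%, Hardy–Weinberg exact p ≥ 1e-6
(hand-coded enumeration of heterozygote counts conditional on allele
counts, on hard calls rounded to the nearest genotype) and missing rate <
1.5%.

Genomic inflation is the median-χ² definition, λ = median(χ²₁ quantile of
1−p)/0.4549 — the reproducible standard; a mixed-model package's internally
averaged lambda is not restated here. The large-scale mixed-model machinery
itself is out of scope: the scan is OLS and heritability is Haseman–Elston,
which is appropriate because the generator contains no relatedness or
stratification; no claim of equivalence under confounding is made.

Loci/signals: greedily take the smallest-p genome-wide-significant variant
(p < 5e-8; ties by chromosome then position) as a lead, open a closed
±500 kb window, record signal members (r² > 0.1 with the lead, same
chromosome, in-window) and proxies (r² ≥ 0.8), remove the window's variants
from candidacy, repeat. Conditional analysis refits each locus member with
the lead dosage as an extra covariate and declares a secondary when all
three hold: original p < 1e-6; −log₁₀(P_lead)/−log₁₀(P_sec) < 1.5; and
−log₁₀(P_sec)/−log₁₀(P_cond) < 1.5. The source text joins these conditions
ambiguously ("or if"); the conservative conjunction is the default and the
disjunctive reading is available via `rule="any"`. Candidates nearly
collinear with the lead (r² > 0.99) are skipped; p-values are floored at
1e-300 before taking logs.

Haseman–Elston: with standardized phenotype y and GRM G_ij = (1/m) Σ_v
x_iv x_jv over standardized dosages, the slope of y_i y_j on G_ij over
pairs i < j estimates h²; the symmetrized cross-product slope estimates
genetic covariance, and r_g = gcov/√(h²_a h²_b). Standard errors are
leave-one-block-out jackknife over 20 subject blocks (pairs touching the
held-out block removed). Percent variance explained is incremental R²:
100 × (R² of covariates + significant dosages − R² of covariates alone).

## PRS

A PRS model is a list of (variant, effect allele, weight = scan beta) for
lead variants only — no clumping-and-thresholding grid, matching a
lead-variant score. Scoring counts dosage on the model's effect allele
(flipping 2−g when the cohort table lists the opposite allele) and
z-standardizes on the scoring cohort. A model variant missing from the
cohort may be substituted by its highest-r² proxy (r² > 0.8) computed in a
supplied reference panel, oriented by the sign of the LD correlation;
otherwise scoring errors with the missing ids. Weights are the marginal
scan betas (whether joint betas should be used for conditionally
independent secondaries is open; marginal is the default). Disease
association reuses the logistic machinery (OR per SD of PRS, Wald CI);
transferability reports per-group incremental R² of the PC score on the
PRS and per-variant effect-allele frequencies with a < 1% flag.

## Mendelian randomization

Harmonization aligns outcome rows to the exposure's effect allele (sign
flip + EAF mirror on swap), drops allele pairs that neither match nor swap,
and drops strand-ambiguous palindromic variants (A/T, C/G) when the
exposure EAF is in (0.42, 0.58) — a conventional guard band, configurable.
Instruments require F = (β_x/se_x)² strictly > 10. Clumping is greedy by
ascending exposure p within 10 Mb at r² > 0.001 against a reference panel.

IVW: estimate Σ(b_x b_y/s_y²)/Σ(b_x²/s_y²), fixed-effect SE
√(1/Σ(b_x²/s_y²)) inflated by √(Q/df) when Cochran heterogeneity exceeds
its degrees of freedom (multiplicative random effects); one instrument
reduces to the Wald ratio. Weighted median: inverse-variance weights of the
first-order delta-method ratio SEs, median by linear interpolation of the
weighted CDF at 0.5, SE by parametric bootstrap (1000 replicates, seeded).
MR-Egger: exposure betas oriented positive (paired outcome betas flipped),
weighted regression of b_y on b_x with intercept and weights 1/s_y²;
residual variance floored at 1 (the usual Egger convention of never
deflating below the fixed-effect variance); t-based p-values on k−2 df.
The intercept estimates average directional pleiotropy. A bidirectional
harness runs both causal directions with roles swapped.

The MR generator orients instruments to the exposure-raising allele — the
convention of published instrument lists, and the orientation in which a
constant pleiotropy term is "directional" in the Egger sense. Exposure and
outcome SEs both default to 0.005, emulating two large independent GWAS.

## Validation experiments and sizes

The `validation` module runs each study design end to end; the test suite
and `scripts/acceptance.py` call the same functions. Sizes, chosen to make
each recovery property sharp while keeping the full run under a minute on
one CPU: atlas recovery n=500 meshes, P=300 points, 5 modes with SDs
10/6/4/2/1 mm and 0.5 mm noise under random rigid transforms; QC with a
500-subject clean training atlas and a 1010-subject scored cohort (1%
outliers at 8 SD along mode 1); null scan calibration and Haseman–Elston
recovery (truth h²=0.30, mean over 10 seeds) at n=2000 subjects and m=5000
variants; conditional logic at n=2000 with 20-variant loci (10 two-causal
replicates with equal effects, so the lead/secondary −log₁₀ p ratio
concentrates near 1, and 100 single-causal replicates); PRS recovery with
100 logistic replicates at OR 1.5/SD plus a 2000/2000 train/test pipeline;
MR with 30 instruments at causal effect 0.2, 50 replicates for Egger
intercept coverage and the pleiotropy bias comparison.

What passing shows: the pipeline recovers what this generator puts in, the
estimators are calibrated under their own assumptions, and the discrete
procedures (loci, clumping, fences, filters) match independent brute-force
oracles exactly. What it does not show: behavior under relatedness,
population stratification, covariate–shape confounding, genotyping error,
non-Gaussian shape variation, or segmentation artifacts beyond the simple
corruption model — none of which the generator emulates.

## Known limitations

- Nearest-vertex contour error underestimates true point-to-surface
  distance on sparse meshes.
- Haseman–Elston is less efficient than REML and assumes homoscedastic
  environmental noise; its jackknife SE is approximate at small n.
- The weighted-median bootstrap SE is itself stochastic; it is seeded for
  reproducibility.
- The LD model is block-equicorrelation; long-range LD and recombination
  structure are not represented, so clumping behavior on real panels may
  differ.
- Strand-flip (complement) harmonization is not attempted; non-matching
  allele pairs are dropped rather than complemented.
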