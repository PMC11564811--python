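# cardioatlas

Statistical shape analysis of the biventricular heart coupled to genetic
analysis, at desk scale. The package is for researchers who want a tested,
fully synthetic-data-driven reimplementation of the cardiac
shape-atlas-to-genetics pipeline: build a point-distribution model from
corresponded 3-D surface meshes, use the per-subject principal-component
Z-scores as quantitative phenotypes, and take those phenotypes through
variant-level association, heritability, polygenic risk scores and
two-sample Mendelian randomization. Every input is simulated by the
package's own generator with recorded ground truth, so each stage's
parameter recovery is verifiable.

## The model

Each subject contributes a mesh of P corresponded points, stacked as a
shape vector **x** ∈ ℝ³ᴾ (mm). Meshes are aligned by generalized Procrustes
analysis using translation and rotation only — scale is deliberately kept,
so heart size remains part of the shape signal. PCA of the aligned vectors
gives the atlas: mean shape **μ**, orthonormal modes **v**ₖ and eigenvalues
λₖ. A subject's phenotype for mode k is the Z-score

    z_k = v_kᵀ (x − μ) / √λ_k ,

unit-variance and uncorrelated across modes on the training set, so
downstream effect sizes read "per SD of shape mode". Quality control
computes four scores (contour fit error, per-mode z, Mahalanobis distance
D = √Σ₁⁰ z², projection residual) and excludes subjects beyond 5
interquartile ranges above the lower quartile or below the upper quartile.

Genetics: per-variant ordinary least squares of z on additive dosage with
covariate adjustment; loci as ±500 kb windows around genome-wide-significant
(p < 5×10⁻⁸) leads, signals as LD r² > 0.1 members, conditional secondary
signals by the 1.5-fold −log₁₀ p rules; SNV heritability by Haseman–Elston
regression of phenotype cross-products on genomic-relationship entries;
lead-variant PRS tested per SD against binary outcomes; and two-sample MR
(harmonization, F > 10 instrument filter, LD clumping, IVW / weighted
median / MR-Egger).

## Worked example

`examples/04_gwas.py` simulates 2000 subjects with a 30%-heritable shape
mode driven by 10 causal variants among 2000, then runs the genetic
pipeline end to end:

```
variant QC kept 2000/2000 (MAF fails 0, HWE fails 0)
genomic inflation lambda = 1.068 (1.0 = well calibrated)
4 genome-wide significant loci (p < 5e-8, +/-500 kb windows)
signals overlap 4/10 true causal variants
conditional analysis declares 0 secondary signal(s)
Haseman-Elston h2 = 0.28 +/- 0.04 (generator: 0.30)
lead variants explain 20.2% of PC1 variance (73% of its heritability)
```

Reading: the scan is calibrated (λ near 1), discovers the strongest 4 of
the 10 causal loci at this sample size, declares no spurious secondary
signals, and the heritability estimate brackets the generating value. The
other scripts in `examples/` cover atlas construction (`01`), quality
control (`02`), observational disease associations (`03`), polygenic
scores (`05`) and Mendelian randomization (`06`); each prints the numbers
it computes along with the ground truth it should recover.

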