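"""Synthetic cohort generator: meshes, genotypes, covariates, outcomes, MR tables.

Everything downstream of image segmentation is emulated here with stated,
seedable parameters so the whole pipeline — atlas, QC, association scan,
heritability, PRS, MR — can be exercised and its parameter recovery tested
against recorded ground truth at desk scale.

Shape model
-----------
Subject ``i``'s shape vector is

    x_i = template + sum_k z_ik * sd_k * sqrt(P) * U_k + eps_i,

where the ``U_k`` are fixed orthonormal 3P displacement fields (orthogonal
to the template's rigid-motion subspace, so alignment cannot absorb them),
``z_ik`` are unit-variance latent scores, and ``eps_i`` iid
N(0, noise_sd^2) per coordinate. The sqrt(P) factor makes ``sd_k`` the
per-point RMS displacement in mm at one latent SD — a 10 mm mode moves
points about 10 mm RMS — so mode amplitudes read on the same mm scale as
the template and the noise. Each
mesh is then given an independent random rotation and translation, which
generalized Procrustes alignment must undo.

When genotypes are supplied, each latent score is split into a genetic part
(a weighted sum of standardized causal dosages) and an environmental part
with variance ratio ``per_mode_h2[k] : 1 - per_mode_h2[k]``.

Determinism: every operation draws from ``numpy.random.default_rng`` seeded
with ``(cfg.seed, op-tag)``, so identical configs give bitwise-identical
output and the ops are mutually independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import ContourSet, GenotypeMatrix, SurfaceMesh, variant_table

# op tags for independent per-operation random streams
_TAG_FIELDS = 1
_TAG_POP = 2
_TAG_CONTOUR = 3
_TAG_GENO = 4
_TAG_COHORT = 5
_TAG_MR = 6


@dataclass
class SimulationConfig:
    """All knobs for one simulated study, with validation.

    Defaults emulate a mid-sized imaging-genetics cohort: a few dominant
    shape modes with geometrically decaying spread, mm-scale measurement
    noise, common variants in LD blocks, and moderate per-mode
    heritability.
    """

    n_subjects: int = 500
    n_points: int = 300
    n_latent_modes: int = 5
    mode_sds: tuple = (10.0, 6.0, 4.0, 2.0, 1.0)  # mm
    noise_sd: float = 0.5  # mm, per coordinate
    n_variants: int = 1000
    maf_range: tuple = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.5
    per_mode_h2: tuple = (0.3, 0.3, 0.3, 0.3, 0.3)
    causal_per_mode: int = 10
    outcome_log_odds: dict = field(default_factory=dict)  # outcome -> per-mode log-OR list
    target_prevalence: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.mode_sds = tuple(float(s) for s in self.mode_sds)
        self.per_mode_h2 = tuple(float(h) for h in self.per_mode_h2)
        if len(self.mode_sds) != self.n_latent_modes:
            raise ValueError("mode_sds length must equal n_latent_modes")
        if any(a <= b for a, b in zip(self.mode_sds, self.mode_sds[1:])):
            raise ValueError("mode_sds must be strictly decreasing")
        if len(self.per_mode_h2) != self.n_latent_modes:
            raise ValueError("per_mode_h2 length must equal n_latent_modes")
        if any(not (0.0 <= h < 1.0) for h in self.per_mode_h2):
            raise ValueError("each per_mode_h2 must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class TruthRecord:
    """Generator ground truth for parameter-recovery tests."""

    true_latent_scores: np.ndarray          # (n, K)
    causal_variant_ids: list                # per-mode lists of variant ids
    true_betas: np.ndarray | None           # (m, K) effects on standardized dosage scale
    true_h2: np.ndarray                     # (K,)
    injected_outlier_ids: list = field(default_factory=list)
    displacement_fields: np.ndarray | None = None  # (3P, K) orthonormal U_k


# ---------------------------------------------------------------------------
# template

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere sampling."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + 5.0**0.5) / 2.0
    theta = 2.0 * np.pi * i / golden
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def make_template(n_points: int, geometry_params: dict | None = None) -> SurfaceMesh:
    """Deterministic two-shell template standing in for a biventricular mesh.

    Points are split half/half between an LV-like and an RV-like ellipsoidal
    shell whose semi-axes and centers are configurable via
    ``geometry_params`` keys ``lv_axes``, ``rv_axes`` (mm triples) and
    ``rv_offset`` (mm triple). Only point correspondence and scale matter
    downstream, not anatomical fidelity.
    """
    if n_points < 12:
        raise ValueError("n_points must be >= 12 to cover both shells")
    params = {
        "lv_axes": (30.0, 30.0, 45.0),
        "rv_axes": (25.0, 35.0, 45.0),
        "rv_offset": (45.0, 0.0, 0.0),
    }
    if geometry_params:
        params.update(geometry_params)
    n_lv = n_points // 2
    n_rv = n_points - n_lv
    lv = _fibonacci_sphere(n_lv) * np.asarray(params["lv_axes"], dtype=float)
    rv = _fibonacci_sphere(n_rv) * np.asarray(params["rv_axes"], dtype=float)
    rv = rv + np.asarray(params["rv_offset"], dtype=float)
    return SurfaceMesh("template", np.vstack([lv, rv]))


# ---------------------------------------------------------------------------
# shape population

def _rigid_subspace(points: np.ndarray) -> np.ndarray:
    """Orthonormal basis of infinitesimal rigid motions at a point set.

    3 translations plus 3 rotation generators (cross products with the
    centered coordinates); modes are orthogonalized against this subspace
    so rigid alignment cannot absorb shape variation.
    """
    p = points - points.mean(axis=0)
    n = p.shape[0]
    basis = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        basis.append(t.reshape(-1))
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        basis.append(np.cross(np.broadcast_to(e, p.shape), p).reshape(-1))
    q, _ = np.linalg.qr(np.column_stack(basis))
    return q


def _displacement_fields(template: SurfaceMesh, k: int, seed: int) -> np.ndarray:
    """K orthonormal 3P fields, orthogonal to the rigid subspace."""
    d = 3 * template.n_points
    if k > d - 6:
        raise ValueError("cannot build K orthonormal fields: K too large for P")
    rng = np.random.default_rng([seed, _TAG_FIELDS])
    raw = rng.standard_normal((d, k))
    rigid = _rigid_subspace(template.points)
    raw -= rigid @ (rigid.T @ raw)
    q, r = np.linalg.qr(raw)
    # fix signs so the factorization is unique
    q *= np.sign(np.diag(r))
    return q


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _standardize_dosages(dosages: np.ndarray) -> np.ndarray:
    mu = dosages.mean(axis=0)
    sd = dosages.std(axis=0)
    sd[sd == 0] = 1.0
    return (dosages - mu) / sd


def sample_shape_population(
    cfg: SimulationConfig,
    template: SurfaceMesh,
    genotypes: GenotypeMatrix | None = None,
    variants: pd.DataFrame | None = None,
    field_seed: int | None = None,
) -> tuple[list[SurfaceMesh], TruthRecord]:
    """Simulate a cohort of meshes from the latent-mode shape model.

    With genotypes, latent score k is sqrt(h2_k) * (standardized genetic
    score from ``causal_per_mode`` causal variants) + sqrt(1-h2_k) *
    (standardized environmental noise); causal sets are disjoint across
    modes. Both parts are empirically standardized so realized variances
    match the requested split.

    ``field_seed`` pins the displacement fields independently of the
    subject draws (default: cfg.seed), so two cohorts can share one
    generative shape model.
    """
    n, k = cfg.n_subjects, cfg.n_latent_modes
    if 3 * template.n_points < k:
        raise ValueError("K exceeds 3P: cannot build orthonormal fields")
    fields = _displacement_fields(
        template, k, cfg.seed if field_seed is None else field_seed
    )
    rng = np.random.default_rng([cfg.seed, _TAG_POP])

    causal_ids: list[list[str]] = [[] for _ in range(k)]
    true_betas = None
    if genotypes is not None:
        m = genotypes.n_variants
        if variants is None:
            raise ValueError("variants table required with genotypes")
        if cfg.causal_per_mode * k > m:
            raise ValueError("not enough variants for disjoint causal sets")
        xs = _standardize_dosages(np.nan_to_num(genotypes.dosages))
        perm = rng.permutation(m)
        true_betas = np.zeros((m, k))
        z = np.empty((n, k))
        for j in range(k):
            idx = np.sort(perm[j * cfg.causal_per_mode : (j + 1) * cfg.causal_per_mode])
            causal_ids[j] = [variants["variant_id"].iloc[i] for i in idx]
            b = rng.standard_normal(cfg.causal_per_mode)
            g = xs[:, idx] @ b
            g_sd = g.std()
            g = g / g_sd if g_sd > 0 else g
            e = rng.standard_normal(n)
            e = (e - e.mean()) / e.std()
            h2 = cfg.per_mode_h2[j]
            z[:, j] = np.sqrt(h2) * g + np.sqrt(1.0 - h2) * e
            true_betas[idx, j] = np.sqrt(h2) * b / (g_sd if g_sd > 0 else 1.0)
    else:
        z = rng.standard_normal((n, k))
    # latent scores are unit-variance by construction (empirical
    # standardization, so realized eigenvalues track the stated mode SDs)
    z = (z - z.mean(axis=0)) / z.std(axis=0)

    base = template.as_vector()
    sds = np.asarray(cfg.mode_sds) * np.sqrt(template.n_points)
    meshes = []
    for i in range(n):
        x = base + fields @ (z[i] * sds)
        if cfg.noise_sd > 0:
            x = x + rng.normal(0.0, cfg.noise_sd, size=x.size)
        pts = x.reshape(-1, 3)
        rot = _random_rotation(rng)
        trans = rng.uniform(-20.0, 20.0, size=3)
        meshes.append(SurfaceMesh(f"S{i:06d}", pts @ rot.T + trans))

    truth = TruthRecord(
        true_latent_scores=z,
        causal_variant_ids=causal_ids,
        true_betas=true_betas,
        true_h2=np.asarray(cfg.per_mode_h2) if genotypes is not None else np.zeros(k),
        displacement_fields=fields,
    )
    return meshes, truth


def degrade_to_contours(
    mesh: SurfaceMesh,
    keep_fraction: float = 0.5,
    jitter_sd: float = 1.0,
    corrupt: bool = False,
    corrupt_fraction: float = 0.1,
    corrupt_shift_mm: float = 25.0,
    seed: int = 0,
) -> ContourSet:
    """Subsample mesh points with isotropic jitter; optionally corrupt some.

    Corruption displaces ``corrupt_fraction`` of kept points by
    ``corrupt_shift_mm`` (>= 20 mm) along random directions, emulating
    erroneous auto-segmentation contours.
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must be in (0, 1]")
    rng = np.random.default_rng([seed, _TAG_CONTOUR])
    n_keep = int(round(mesh.n_points * keep_fraction))
    if n_keep == 0:
        raise ValueError("keep_fraction leaves no contour points")
    idx = np.sort(rng.choice(mesh.n_points, size=n_keep, replace=False))
    pts = mesh.points[idx].copy()
    if jitter_sd > 0:
        pts += rng.normal(0.0, jitter_sd, size=pts.shape)
    if corrupt:
        if corrupt_shift_mm < 20.0:
            raise ValueError("corrupt shift must be >= 20 mm")
        n_bad = max(1, int(round(corrupt_fraction * n_keep)))
        bad = rng.choice(n_keep, size=n_bad, replace=False)
        dirs = rng.standard_normal((n_bad, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts[bad] += corrupt_shift_mm * dirs
    return ContourSet(mesh.subject_id, pts, source_index=idx)


# ---------------------------------------------------------------------------
# genotypes

_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]


def sample_genotypes(cfg: SimulationConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Biallelic dosages with block LD via a thresholded Gaussian copula.

    Haplotypes within an LD block share a latent factor with loading
    sqrt(ld_rho); each haplotype allele is the indicator that its latent
    Gaussian falls below the MAF quantile, giving Hardy-Weinberg genotype
    frequencies marginally. Blocks are independent. Positions are 1-based
    at 10 kb spacing on one synthetic chromosome per ~2000 variants.
    """
    m, n = cfg.n_variants, cfg.n_subjects
    if m < cfg.ld_block_size:
        raise ValueError("n_variants must be >= ld_block_size")
    rng = np.random.default_rng([cfg.seed, _TAG_GENO])
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    thresholds = stats.norm.ppf(mafs)

    n_hap = 2 * n
    dosage = np.empty((n, m))
    for start in range(0, m, cfg.ld_block_size):
        stop = min(start + cfg.ld_block_size, m)
        width = stop - start
        f = rng.standard_normal((n_hap, 1))
        e = rng.standard_normal((n_hap, width))
        latent = np.sqrt(cfg.ld_rho) * f + np.sqrt(1.0 - cfg.ld_rho) * e
        alleles = (latent < thresholds[start:stop]).astype(float)
        dosage[:, start:stop] = alleles[0::2] + alleles[1::2]

    per_chrom = 2000
    chrom = 1 + np.arange(m) // per_chrom
    pos = 1 + 10_000 * (np.arange(m) % per_chrom)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    ea = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    nea = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    eaf = dosage.mean(axis=0) / 2.0
    vt = variant_table(
        [f"rs{i + 1}" for i in range(m)], chrom, pos, ea, nea, eaf,
        missing_rate=np.zeros(m),
    )
    return GenotypeMatrix(dosage), vt


# ---------------------------------------------------------------------------
# covariates and outcomes

_COVARIATE_MODEL = {
    # name: (mean, sd) for normals; sex is Bernoulli(0.5)
    "age": (55.0, 8.0),        # years
    "height": (170.0, 9.0),    # cm
    "bmi": (27.0, 4.5),        # kg/m^2
    "sbp": (138.0, 18.0),      # mmHg (medication-adjusted scale)
    "heart_rate": (69.0, 11.0),  # bpm
}


def sample_covariates_outcomes(
    cfg: SimulationConfig,
    truth: TruthRecord,
    covariate_log_odds: dict | None = None,
) -> pd.DataFrame:
    """Cohort table: covariates plus binary outcomes from a logistic model.

    Each outcome named in ``cfg.outcome_log_odds`` gets
    logit = intercept + sum_k logOR_k * z_ik (+ optional standardized
    covariate terms); the intercept is tuned by root-finding so realized
    expected prevalence matches ``cfg.target_prevalence``.
    """
    if truth is None:
        raise ValueError("truth record required")
    z = truth.true_latent_scores
    n = z.shape[0]
    rng = np.random.default_rng([cfg.seed, _TAG_COHORT])
    df = pd.DataFrame({"subject_id": [f"S{i:06d}" for i in range(n)]})
    for name, (mu, sd) in _COVARIATE_MODEL.items():
        df[name] = rng.normal(mu, sd, size=n)
    df["sex"] = rng.integers(0, 2, size=n).astype(float)

    for outcome, log_ors in cfg.outcome_log_odds.items():
        log_ors = np.asarray(log_ors, dtype=float)
        lin = z[:, : log_ors.size] @ log_ors
        if covariate_log_odds:
            for cov, lo in covariate_log_odds.get(outcome, {}).items():
                col = df[cov].to_numpy()
                lin = lin + lo * (col - col.mean()) / col.std()

        def expected_prev(intercept: float) -> float:
            return float(np.mean(1.0 / (1.0 + np.exp(-(intercept + lin)))))

        target = cfg.target_prevalence
        lo_b, hi_b = -30.0, 30.0
        if not (expected_prev(lo_b) < target < expected_prev(hi_b)):
            raise ValueError(f"target prevalence {target} unattainable for {outcome}")
        icept = optimize.brentq(lambda b: expected_prev(b) - target, lo_b, hi_b)
        prob = 1.0 / (1.0 + np.exp(-(icept + lin)))
        df[outcome] = (rng.uniform(size=n) < prob).astype(int)
        realized = df[outcome].mean()
        if target > 0 and abs(realized - target) > 0.2 * target + 3 * np.sqrt(target / n):
            raise ValueError(
                f"realized prevalence {realized:.4f} misses target {target} for {outcome}"
            )
    return df


# ---------------------------------------------------------------------------
# MR summary statistics

def make_mr_summary_stats(
    n_instruments: int = 30,
    causal_effect: float = 0.2,
    pleiotropy: float = 0.0,
    se_exposure: float = 0.005,
    se_outcome: float = 0.005,
    beta_exposure_range: tuple = (0.05, 0.15),
    allele_scramble: bool = False,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Two-sample GWAS summary-statistic pair with known causal effect.

    Exposure effects are drawn uniform in ``beta_exposure_range``, positive:
    instruments are reported for the exposure-raising allele, the usual
    orientation of published instrument lists (and the one under which a
    constant pleiotropy term is "directional"). Observed betas add
    independent N(0, se^2) noise in each sample. The outcome beta is
    causal_effect * true_beta + pleiotropy + noise. With
    ``allele_scramble`` the outcome rows for every second variant are
    emitted with EA/NEA swapped and beta/EAF flipped, which harmonization
    must undo.
    """
    if n_instruments < 3:
        raise ValueError("need at least 3 instruments")
    rng = np.random.default_rng([seed, _TAG_MR])
    k = n_instruments
    bx_true = rng.uniform(*beta_exposure_range, size=k)
    bx_obs = bx_true + rng.normal(0.0, se_exposure, size=k)
    by_true = causal_effect * bx_true + pleiotropy
    by_obs = by_true + rng.normal(0.0, se_outcome, size=k)
    eaf = rng.uniform(0.1, 0.9, size=k)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=k)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    nea = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    ids = [f"rs{i + 1}" for i in range(k)]
    pos = 1 + 1_000_000 * np.arange(k)

    def table(beta, se, ea_c, nea_c, eaf_c):
        with np.errstate(divide="ignore"):
            z = np.where(se > 0, np.abs(beta) / np.where(se > 0, se, 1.0), np.inf)
        return pd.DataFrame(
            {
                "SNP": ids, "CHR": 1, "POS": pos,
                "EA": ea_c, "NEA": nea_c, "EAF": eaf_c,
                "BETA": beta, "SE": se, "P": 2 * stats.norm.sf(z),
            }
        )

    exposure = table(bx_obs, np.full(k, se_exposure), ea, nea, eaf)
    ea_o, nea_o, eaf_o, by_emit = ea.copy(), nea.copy(), eaf.copy(), by_obs.copy()
    scrambled = np.zeros(k, dtype=bool)
    if allele_scramble:
        scrambled[::2] = True
        ea_o[scrambled], nea_o[scrambled] = nea[scrambled], ea[scrambled]
        by_emit[scrambled] = -by_emit[scrambled]
        eaf_o[scrambled] = 1.0 - eaf_o[scrambled]
    outcome = table(by_emit, np.full(k, se_outcome), ea_o, nea_o, eaf_o)
    truth = {
        "causal_effect": causal_effect,
        "beta_exposure_true": bx_true,
        "beta_exposure_obs": bx_obs,
        "beta_outcome_obs": by_obs,
        "scrambled": scrambled,
    }
    return exposure, outcome, truth
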