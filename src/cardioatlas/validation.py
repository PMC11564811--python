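"""End-to-end validation experiments on synthetic cohorts.

Each function runs one study design — atlas mode recovery, QC outlier
detection, scan calibration, heritability recovery, conditional-signal
logic, PRS recovery, MR recovery — at a stated size and returns the
measured quantities. They are the package's own evidence that the pipeline
recovers what the generator put in; the test suite and the reproduction
script both call them.

All randomness flows from a single integer ``seed``; derived sub-seeds stay
below 2**31.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import mr as mr_mod
from .atlas import (
    align_atlas_frame,
    build_atlas,
    generalized_procrustes,
    principal_angles_deg,
    reconstruct_shape,
    rigid_align_pair,
    score_shapes,
    scores_matrix,
)
from .gwas import (
    association_scan,
    conditional_secondary_scan,
    define_loci_and_signals,
    genomic_inflation,
    he_heritability,
)
from .pheno_assoc import logistic_odds_ratio, pearson_correlation
from .prs import prs_from_scan, score_prs
from .shape_qc import qc_report
from .synthdata import (
    SimulationConfig,
    make_mr_summary_stats,
    make_template,
    sample_genotypes,
    sample_shape_population,
)
from .types import GenotypeMatrix, SurfaceMesh


def _sub(seed: int, tag: int) -> int:
    return int((seed * 1000 + tag) % (2**31 - 1))


def _std(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _genetic_phenotype(geno: GenotypeMatrix, h2: float, n_causal: int, rng) -> np.ndarray:
    """Latent-score model without the mesh layer: standardized genetic part
    with variance h2 plus environmental noise."""
    x = geno.dosages
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    idx = rng.choice(x.shape[1], n_causal, replace=False)
    g = x[:, idx] @ rng.standard_normal(n_causal)
    return np.sqrt(h2) * _std(g) + np.sqrt(1 - h2) * _std(rng.standard_normal(x.shape[0]))


# ---------------------------------------------------------------------------
# atlas

ATLAS_MODE_SDS = (10.0, 6.0, 4.0, 2.0, 1.0)


def atlas_recovery(seed: int, n: int = 500, p: int = 300, noise_sd: float = 0.5) -> dict:
    """Recover 5 latent modes from a rigidly perturbed mesh population.

    Returns the worst relative error of the top-5 variance fractions
    against their theoretical values and the largest principal angle
    (degrees) between the true and estimated 5-mode subspaces.
    """
    cfg = SimulationConfig(
        n_subjects=n, n_points=p, n_latent_modes=5, mode_sds=ATLAS_MODE_SDS,
        noise_sd=noise_sd, per_mode_h2=(0.0,) * 5, seed=_sub(seed, 1),
    )
    template = make_template(p)
    meshes, truth = sample_shape_population(cfg, template)
    aligned, _, _ = generalized_procrustes(meshes)
    atlas = align_atlas_frame(build_atlas(aligned), template)
    sds = np.asarray(ATLAS_MODE_SDS)
    total = p * np.sum(sds**2) + 3 * p * noise_sd**2
    theory = (p * sds**2 + noise_sd**2) / total
    rel_err = np.abs(atlas.variance_fractions[:5] / theory - 1.0)
    angles = principal_angles_deg(truth.displacement_fields, atlas.modes[:, :5])
    return {
        "max_rel_frac_err": float(rel_err.max()),
        "max_principal_angle_deg": float(angles.max()),
        "variance_fraction_top5_pct": float(100 * atlas.variance_fractions[:5].sum()),
        "n": n,
    }


def rigid_invariance(seed: int, n: int = 150, p: int = 120) -> dict:
    """Apply one random rigid transform to every input mesh and compare
    atlas eigenvalues and |z| before/after."""
    cfg = SimulationConfig(
        n_subjects=n, n_points=p, n_latent_modes=3, mode_sds=(8.0, 4.0, 2.0),
        noise_sd=0.3, per_mode_h2=(0.0,) * 3, seed=_sub(seed, 2),
    )
    template = make_template(p)
    meshes, _ = sample_shape_population(cfg, template)
    rng = np.random.default_rng(_sub(seed, 3))
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    shift = rng.uniform(-25, 25, 3)
    moved = [SurfaceMesh(m.subject_id, m.points @ q.T + shift) for m in meshes]
    k = 5
    a1 = build_atlas(generalized_procrustes(meshes)[0])
    a2 = build_atlas(generalized_procrustes(moved)[0])
    rel = np.abs(a2.eigenvalues[:k] / a1.eigenvalues[:k] - 1.0)
    z1 = np.abs(scores_matrix(score_shapes(a1, meshes, n_modes=k)))
    z2 = np.abs(scores_matrix(score_shapes(a2, moved, n_modes=k)))
    return {
        "max_rel_eigenvalue_change": float(rel.max()),
        "max_abs_z_change": float(np.max(np.abs(z1 - z2))),
        "n": n,
    }


def score_orthogonality(seed: int, n: int = 300, p: int = 150) -> dict:
    """Max absolute cross-PC correlation of training-set scores."""
    cfg = SimulationConfig(
        n_subjects=n, n_points=p, n_latent_modes=3, mode_sds=(8.0, 4.0, 2.0),
        noise_sd=0.3, per_mode_h2=(0.0,) * 3, seed=_sub(seed, 4),
    )
    meshes, _ = sample_shape_population(cfg, make_template(p))
    aligned, _, _ = generalized_procrustes(meshes)
    atlas = build_atlas(aligned)
    z = scores_matrix(score_shapes(atlas, aligned, align=False, n_modes=10))
    c = np.corrcoef(z.T) - np.eye(10)
    return {"max_cross_pc_corr": float(np.max(np.abs(c))), "n": n}


# ---------------------------------------------------------------------------
# QC

def qc_outlier_detection(seed: int, n_train: int = 500, n_score: int = 1000,
                         p: int = 120, outlier_frac: float = 0.01) -> dict:
    """Train a clean atlas, score a cohort with 1% 8-SD mode-1 outliers.

    Returns the fraction of injected outliers excluded by the Mahalanobis
    fence and the exclusion rate on the clean remainder.
    """
    base = dict(n_points=p, n_latent_modes=3, mode_sds=(8.0, 4.0, 2.0),
                noise_sd=0.3, per_mode_h2=(0.0,) * 3)
    template = make_template(p)
    train, _ = sample_shape_population(
        SimulationConfig(n_subjects=n_train, seed=_sub(seed, 5), **base), template
    )
    atlas = build_atlas(generalized_procrustes(train)[0])
    clean, _ = sample_shape_population(
        SimulationConfig(n_subjects=n_score, seed=_sub(seed, 6), **base),
        template, field_seed=_sub(seed, 5),
    )
    n_out = max(1, int(round(outlier_frac * n_score)))
    rng = np.random.default_rng(_sub(seed, 7))
    meshes = list(clean)
    outlier_ids = []
    for i in range(n_out):
        z = rng.standard_normal(10)
        z[0] = 8.0
        m = reconstruct_shape(atlas, z, modes=list(range(10)), subject_id=f"OUT{i}")
        meshes.append(m)
        outlier_ids.append(f"OUT{i}")
    report = qc_report(atlas, meshes).set_index("subject_id")
    recall = float(report.loc[outlier_ids, "flag_mahalanobis"].mean())
    clean_ids = [m.subject_id for m in clean]
    false_rate = float(report.loc[clean_ids, "excluded"].mean())
    return {
        "outlier_recall": recall,
        "false_exclusion_rate": false_rate,
        "n": n_score + n_out,
    }


# ---------------------------------------------------------------------------
# GWAS

def gwas_null_calibration(seed: int, n: int = 2000, m: int = 5000) -> dict:
    """Fully null scan: genomic inflation and empirical type-I at 1e-3."""
    cfg = SimulationConfig(n_subjects=n, n_variants=m, ld_rho=0.0,
                           ld_block_size=10, maf_range=(0.05, 0.5),
                           seed=_sub(seed, 8))
    geno, vt = sample_genotypes(cfg)
    rng = np.random.default_rng(_sub(seed, 9))
    y = rng.standard_normal(n)
    covars = rng.standard_normal((n, 3))
    res = association_scan(geno, y, covars=covars, variants=vt)
    lam = genomic_inflation(res["P"].to_numpy())
    alpha = 1e-3
    frac = float((res["P"] < alpha).mean())
    half_width = 1.96 * np.sqrt(alpha * (1 - alpha) / m)
    return {
        "lambda_gc": float(lam),
        "type1_at_1e3": frac,
        "type1_within_binomial_bounds": float(abs(frac - alpha) <= half_width),
        "n": m,
    }


def he_recovery(seed: int, n: int = 2000, m: int = 5000, h2: float = 0.30,
                n_seeds: int = 10) -> dict:
    """Mean Haseman-Elston h2 estimate over seeded replicates, truth 0.30."""
    ests = []
    for rep in range(n_seeds):
        cfg = SimulationConfig(n_subjects=n, n_variants=m, ld_rho=0.0,
                               ld_block_size=10, maf_range=(0.05, 0.5),
                               seed=_sub(seed, 10 + rep))
        geno, _ = sample_genotypes(cfg)
        rng = np.random.default_rng(_sub(seed, 40 + rep))
        y = _genetic_phenotype(geno, h2, 50, rng)
        ests.append(he_heritability(geno, y).h2)
    return {
        "h2_mean": float(np.mean(ests)),
        "h2_abs_err": float(abs(np.mean(ests) - h2)),
        "n": n_seeds,
    }


def conditional_logic(seed: int, n: int = 2000, n_null_reps: int = 100,
                      n_two_causal_reps: int = 10) -> dict:
    """Secondary-signal logic at a locus.

    A two-causal-variant locus (weak LD between the causals, both strongly
    and equally powered so the lead/secondary -log10 p ratio concentrates
    near 1) must declare a secondary; a single-causal locus must declare
    none in at least 95% of replicates.
    """

    def locus_run(s, two_causal):
        cfg = SimulationConfig(n_subjects=n, n_variants=20, ld_rho=0.35,
                               ld_block_size=20, maf_range=(0.2, 0.5), seed=s)
        geno, vt = sample_genotypes(cfg)
        rng = np.random.default_rng(s + 1)
        y = 0.40 * _std(geno.dosages[:, 2])
        var = 0.40**2
        if two_causal:
            y = y + 0.40 * _std(geno.dosages[:, 15])
            var += 0.40**2
        y = y + np.sqrt(1 - var) * rng.standard_normal(n)
        res = association_scan(geno, y, variants=vt)
        ls = define_loci_and_signals(res, geno, vt)
        if ls.n_loci == 0:
            return None
        return conditional_secondary_scan(ls.loci[0], geno, vt, y, None, res)

    declared = 0
    for rep in range(n_two_causal_reps):
        sec = locus_run(_sub(seed, 60 + rep), two_causal=True)
        declared += sec is not None and len(sec) >= 1
    null_declared = 0
    n_eval = 0
    for rep in range(n_null_reps):
        sec = locus_run(_sub(seed, 100 + rep), two_causal=False)
        if sec is None:
            continue
        n_eval += 1
        null_declared += len(sec) > 0
    return {
        "two_causal_secondary_declared": declared / n_two_causal_reps,
        "single_causal_no_secondary_rate": float(1 - null_declared / max(n_eval, 1)),
        "n": n_eval,
    }


def greedy_oracle_match(seed: int, n_instances: int = 5) -> dict:
    """Loci/signals and LD clumping vs brute-force greedy enumeration on
    50-variant instances; returns the fraction of instances matching."""
    matches = 0
    for rep in range(n_instances):
        cfg = SimulationConfig(n_subjects=300, n_variants=50, ld_rho=0.6,
                               ld_block_size=5, maf_range=(0.2, 0.5),
                               seed=_sub(seed, 200 + rep))
        geno, vt = sample_genotypes(cfg)
        rng = np.random.default_rng(_sub(seed, 300 + rep))
        p = 10.0 ** rng.uniform(-12, 0, size=50)
        res = vt.rename(columns={"variant_id": "SNP", "chr": "CHR", "pos": "POS"}).copy()
        res["PC"], res["BETA"], res["SE"], res["P"] = "PC1", 0.1, 0.01, p
        ls = define_loci_and_signals(res, geno, vt)
        ok = True
        # oracle: plain re-walk of the greedy definition
        alive = set(range(50))
        pos = vt["pos"].to_numpy()
        chrom = vt["chr"].to_numpy()
        oracle = []
        while True:
            sig = [i for i in alive if p[i] < 5e-8]
            if not sig:
                break
            lead = min(sig, key=lambda i: (p[i], chrom[i], pos[i]))
            members = [i for i in alive
                       if chrom[i] == chrom[lead] and abs(pos[i] - pos[lead]) <= 500_000]
            oracle.append((lead, sorted(members)))
            alive -= set(members)
        ok &= ls.n_loci == len(oracle)
        if ok:
            for locus, (lead, members) in zip(ls.loci, oracle):
                ok &= locus.lead == vt["variant_id"].iloc[lead]
                ok &= sorted(locus.members) == sorted(vt["variant_id"].iloc[members])
        matches += bool(ok)
    return {"fraction_matching_oracle": matches / n_instances, "n": n_instances}


# ---------------------------------------------------------------------------
# PRS

def prs_recovery(seed: int, n: int = 2000, n_reps: int = 100) -> dict:
    """Odds-ratio recovery and PRS-phenotype correlation.

    (a) Outcomes generated at OR 1.5 per SD of the true genetic score; the
    fitted Wald CI should cover 1.5 in ~95% of replicates. (b) A full
    train/test pipeline: scan the training half, build a lead-variant PRS,
    score the held-out half, and correlate with its PC phenotype.
    """
    covered = 0
    target = np.log(1.5)
    for rep in range(n_reps):
        rng = np.random.default_rng(_sub(seed, 400 + rep))
        score = rng.standard_normal(n)
        logit = target * score - 2.0
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(float)
        rec = logistic_odds_ratio(score, y)
        covered += rec.ci95[0] <= 1.5 <= rec.ci95[1]

    # held-out PRS-PC correlation
    cfg = SimulationConfig(n_subjects=4000, n_variants=1000, ld_rho=0.0,
                           ld_block_size=10, maf_range=(0.1, 0.5),
                           seed=_sub(seed, 500))
    geno, vt = sample_genotypes(cfg)
    rng = np.random.default_rng(_sub(seed, 501))
    pc = _genetic_phenotype(geno, 0.3, 10, np.random.default_rng(_sub(seed, 502)))
    train = slice(0, 2000)
    test = slice(2000, 4000)
    g_train = GenotypeMatrix(geno.dosages[train])
    res = association_scan(g_train, pc[train], variants=vt, pc="PC1")
    ls = define_loci_and_signals(res, g_train, vt)
    model = prs_from_scan(res, ls.lead_ids, pc="PC1")
    g_test = GenotypeMatrix(geno.dosages[test])
    scores = score_prs(model, g_test, vt)
    r, p_corr = pearson_correlation(scores, pc[test])
    return {
        "or_coverage_rate": covered / n_reps,
        "prs_pc_corr": float(r),
        "prs_pc_corr_p": float(p_corr),
        "n_loci_for_prs": ls.n_loci,
        "n": n_reps,
    }


# ---------------------------------------------------------------------------
# MR

def mr_recovery(seed: int, n_instruments: int = 30, causal: float = 0.2,
                n_pleio_seeds: int = 50) -> dict:
    """IVW point recovery, Egger intercept coverage under no pleiotropy,
    and Egger-vs-IVW bias under +0.05 directional pleiotropy."""
    exp, out, _ = make_mr_summary_stats(
        n_instruments=n_instruments, causal_effect=causal, seed=_sub(seed, 600)
    )
    inst = mr_mod.strength_filter(mr_mod.harmonize(exp, out))
    est_ivw = mr_mod.ivw(inst)

    # Egger intercept 95% CI coverage of zero over no-pleiotropy replicates
    covered = 0
    for rep in range(n_pleio_seeds):
        e1, o1, _ = make_mr_summary_stats(
            n_instruments=n_instruments, causal_effect=causal, seed=_sub(seed, 650 + rep)
        )
        i1 = mr_mod.strength_filter(mr_mod.harmonize(e1, o1))
        eg = mr_mod.egger(i1)
        t_crit = stats.t.ppf(0.975, df=len(i1) - 2)
        covered += abs(eg.intercept) <= t_crit * eg.intercept_se

    wins = 0
    for rep in range(n_pleio_seeds):
        e2, o2, _ = make_mr_summary_stats(
            n_instruments=n_instruments, causal_effect=causal, pleiotropy=0.05,
            seed=_sub(seed, 700 + rep),
        )
        i2 = mr_mod.strength_filter(mr_mod.harmonize(e2, o2))
        wins += abs(mr_mod.egger(i2).estimate - causal) < abs(mr_mod.ivw(i2).estimate - causal)
    return {
        "ivw_estimate": float(est_ivw.estimate),
        "ivw_abs_err": float(abs(est_ivw.estimate - causal)),
        "egger_intercept_zero_coverage_rate": covered / n_pleio_seeds,
        "egger_beats_ivw_rate": wins / n_pleio_seeds,
        "n": n_pleio_seeds,
    }
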