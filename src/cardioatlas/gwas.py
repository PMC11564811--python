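"""Variant QC, association scan, loci/signals, conditional analysis,
Haseman-Elston heritability and percent variance explained.

The scan is ordinary least squares of the PC phenotype on additive dosage
plus covariates, per variant. Covariates are residualized out once, which
by the Frisch-Waugh-Lovell theorem gives coefficients and standard errors
identical to the joint fit while making the scan a single matrix product.

Heritability uses Haseman-Elston regression: with standardized phenotype y
and genomic relationship G_ij = (1/m) sum_v x_iv x_jv over standardized
dosages, E[y_i y_j] = h2 * G_ij for i != j, so the slope of the
cross-products on the relationship entries estimates h2. Genetic covariance
between two phenotypes replaces y_i y_j with the symmetrized cross product;
r_g = gcov / sqrt(h2_a * h2_b). Standard errors are block jackknife over
subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .types import GenotypeMatrix, HeritabilityEstimate

GW_SIG_P = 5e-8
SUGGESTIVE_P = 1e-6
_CHI2_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.4549...


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test

def hwe_exact_test(n_aa_hom: int, n_het: int, n_bb_hom: int) -> float:
    """Exact two-sided Hardy-Weinberg test.

    Enumerates the conditional distribution of the heterozygote count given
    the allele counts and sums the probabilities of all outcomes no more
    likely than the observed one (the standard exact construction).
    """
    if min(n_aa_hom, n_het, n_bb_hom) < 0:
        raise ValueError("counts must be non-negative")
    n = n_aa_hom + n_het + n_bb_hom
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa_hom + n_het  # rarer allele not required; symmetric
    n_b = 2 * n_bb_hom + n_het
    n_minor = min(n_a, n_b)
    if n_minor == 0:
        return 1.0
    # heterozygote count must match the parity of the minor allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)

    def log_prob(h):
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        return (
            gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(hom_minor + 1)
            - gammaln(hom_major + 1)
            + h * np.log(2.0)
            + gammaln(n_a + 1)
            + gammaln(n_b + 1)
            - gammaln(2 * n + 1)
        )

    lp = log_prob(hets.astype(float))
    lp -= lp.max()
    probs = np.exp(lp)
    probs /= probs.sum()
    obs = probs[hets == n_het]
    if obs.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    p = probs[probs <= obs[0] * (1 + 1e-12)].sum()
    return float(min(1.0, p))


# ---------------------------------------------------------------------------
# variant QC

def variant_qc(
    geno: GenotypeMatrix,
    variants: pd.DataFrame,
    maf_min: float = 0.01,
    hwe_min: float = 1e-6,
    missing_max: float = 0.015,
) -> tuple[GenotypeMatrix, pd.DataFrame, dict]:
    """Filter variants on MAF, Hardy-Weinberg and missingness.

    Keeps variants with maf > maf_min, HWE exact p >= hwe_min and missing
    rate < missing_max. HWE is tested on hard calls (dosages rounded to the
    nearest integer genotype) over non-missing subjects. Returns the
    filtered genotype/variant pair plus per-filter exclusion counts.
    """
    d = geno.dosages
    n = d.shape[0]
    missing = np.isnan(d)
    missing_rate = missing.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        eaf = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(eaf, 1.0 - eaf)
    hard = np.rint(np.where(missing, np.nan, d))
    hwe_p = np.empty(d.shape[1])
    for j in range(d.shape[1]):
        col = hard[:, j]
        col = col[~np.isnan(col)]
        n_bb = int(np.sum(col == 0))
        n_ab = int(np.sum(col == 1))
        n_aa = int(np.sum(col == 2))
        hwe_p[j] = hwe_exact_test(n_aa, n_ab, n_bb)

    keep = (maf > maf_min) & (hwe_p >= hwe_min) & (missing_rate < missing_max)
    counts = {
        "n_input": d.shape[1],
        "fail_maf": int(np.sum(maf <= maf_min)),
        "fail_hwe": int(np.sum(hwe_p < hwe_min)),
        "fail_missing": int(np.sum(missing_rate >= missing_max)),
        "n_kept": int(keep.sum()),
    }
    if counts["n_kept"] == 0:
        raise ValueError("no variants survive QC")
    vt = variants.loc[keep].reset_index(drop=True).copy()
    vt["maf"] = maf[keep]
    vt["hwe_p"] = hwe_p[keep]
    vt["missing_rate"] = missing_rate[keep]
    filtered = GenotypeMatrix(d[:, keep], subject_ids=list(geno.subject_ids))
    return filtered, vt, counts


# ---------------------------------------------------------------------------
# association scan

def _residualize(y: np.ndarray, covars: np.ndarray | None) -> tuple[np.ndarray, int]:
    """Residualize on covariates plus intercept; returns (residual, dof used)."""
    n = y.shape[0]
    if covars is None or covars.size == 0:
        x = np.ones((n, 1))
    else:
        x = np.column_stack([np.ones(n), covars])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta, x.shape[1]


def association_scan(
    geno: GenotypeMatrix,
    phenotype: np.ndarray,
    covars: pd.DataFrame | np.ndarray | None = None,
    variants: pd.DataFrame | None = None,
    pc: str = "PC1",
) -> pd.DataFrame:
    """Per-variant OLS of phenotype on dosage with covariate adjustment.

    Missing dosages are mean-imputed (post-QC missingness is < 1.5%).
    Constant dosages are skipped with a warning (NaN results). Returns a
    frame with columns PC, SNP, BETA, SE, P (plus CHR/POS/EA/NEA/EAF when a
    variant table is supplied), mirroring a GWAS summary-statistics table.
    """
    y = np.asarray(phenotype, dtype=float)
    d = geno.dosages.copy()
    if np.isnan(d).any():
        mu = np.nanmean(d, axis=0)
        nan_r, nan_c = np.where(np.isnan(d))
        d[nan_r, nan_c] = mu[nan_c]
    c = np.asarray(covars, dtype=float) if covars is not None else None
    if c is not None and c.ndim == 1:
        c = c[:, None]
    n = y.shape[0]
    y_r, k = _residualize(y, c)
    g_r = np.empty_like(d)
    if c is None:
        g_r = d - d.mean(axis=0)
    else:
        x = np.column_stack([np.ones(n), c])
        coef, *_ = np.linalg.lstsq(x, d, rcond=None)
        g_r = d - x @ coef
    gg = np.sum(g_r**2, axis=0)
    const = gg < 1e-12
    if const.any():
        warnings.warn(f"{const.sum()} constant dosage column(s) skipped", stacklevel=2)
    gg_safe = np.where(const, 1.0, gg)
    beta = (g_r.T @ y_r) / gg_safe
    dof = n - k - 1
    rss = np.sum(y_r**2) - beta**2 * gg_safe
    sigma2 = np.maximum(rss, 0.0) / dof
    se = np.sqrt(sigma2 / gg_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df=dof)
    beta[const] = np.nan
    se[const] = np.nan
    p[const] = np.nan
    out = pd.DataFrame({"PC": pc, "BETA": beta, "SE": se, "P": p})
    if variants is not None:
        out.insert(1, "SNP", variants["variant_id"].to_numpy())
        out.insert(2, "CHR", variants["chr"].to_numpy())
        out.insert(3, "POS", variants["pos"].to_numpy())
        out.insert(4, "EA", variants["EA"].to_numpy())
        out.insert(5, "NEA", variants["NEA"].to_numpy())
        out.insert(6, "EAF", variants["EAF"].to_numpy())
    else:
        out.insert(1, "SNP", [f"v{j}" for j in range(d.shape[1])])
    return out


def genomic_inflation(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median chi-square over its null median.

    lambda_GC = median(chi2_1 quantile of 1-p) / 0.4549; 1.0 under the null,
    > 1 under confounding or polygenicity.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise ValueError("need at least 100 p-values")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_MEDIAN)


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.size != g2.size:
        raise ValueError("dosage vectors must share length")
    if g1.std() == 0 or g2.std() == 0:
        raise ValueError("zero-variance dosage")
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# loci and signals

@dataclass
class Locus:
    lead: str
    chr: int
    pos: int
    p: float
    window: tuple            # (pos - window, pos + window), closed
    members: list            # all variants in the window, same chromosome
    signal_members: list     # members with r^2 > signal_r2 within 1 Mb
    proxies: list            # members with r^2 >= proxy_r2
    secondaries: list = field(default_factory=list)


@dataclass
class LocusSet:
    loci: list
    gw_p: float
    window_kb: float
    signal_r2: float
    proxy_r2: float

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def lead_ids(self) -> list:
        return [l.lead for l in self.loci]


def define_loci_and_signals(
    results: pd.DataFrame,
    geno: GenotypeMatrix,
    variants: pd.DataFrame,
    gw_p: float = GW_SIG_P,
    window_kb: float = 500.0,
    signal_r2: float = 0.1,
    proxy_r2: float = 0.8,
) -> LocusSet:
    """Greedy locus/signal definition from a scan.

    Repeatedly takes the smallest-p genome-wide-significant variant still in
    candidacy as a lead (ties broken by chromosome then position), opens a
    closed +/- window around it, records signal members (same chromosome,
    r^2 > signal_r2 with the lead within the window) and high-LD proxies
    (r^2 >= proxy_r2), removes the window's variants from candidacy and
    repeats until no significant candidates remain.
    """
    df = results.merge(
        variants[["variant_id", "chr", "pos"]],
        left_on="SNP", right_on="variant_id", how="left",
    ) if "CHR" not in results.columns else results.rename(
        columns={"CHR": "chr", "POS": "pos"}
    )
    window = window_kb * 1000.0
    id_to_col = {v: j for j, v in enumerate(variants["variant_id"])}
    cand = df.dropna(subset=["P"]).copy()
    loci = []
    while True:
        sig = cand[cand["P"] < gw_p]
        if sig.empty:
            break
        sig = sig.sort_values(["P", "chr", "pos"], kind="mergesort")
        lead = sig.iloc[0]
        lo, hi = lead["pos"] - window, lead["pos"] + window
        in_win = (cand["chr"] == lead["chr"]) & (cand["pos"] >= lo) & (cand["pos"] <= hi)
        members = cand.loc[in_win, "SNP"].tolist()
        g_lead = geno.dosages[:, id_to_col[lead["SNP"]]]
        signal, proxies = [lead["SNP"]], [lead["SNP"]]
        for snp in members:
            if snp == lead["SNP"]:
                continue
            g = geno.dosages[:, id_to_col[snp]]
            if g.std() == 0 or g_lead.std() == 0:
                continue
            r2 = ld_r2(g_lead, g)
            if r2 > signal_r2:
                signal.append(snp)
            if r2 >= proxy_r2:
                proxies.append(snp)
        loci.append(
            Locus(
                lead=lead["SNP"], chr=int(lead["chr"]), pos=int(lead["pos"]),
                p=float(lead["P"]), window=(lo, hi), members=members,
                signal_members=signal, proxies=proxies,
            )
        )
        cand = cand[~in_win]
    return LocusSet(loci, gw_p, window_kb, signal_r2, proxy_r2)


# ---------------------------------------------------------------------------
# conditional analysis

def conditional_secondary_scan(
    locus: Locus,
    geno: GenotypeMatrix,
    variants: pd.DataFrame,
    phenotype: np.ndarray,
    covars: pd.DataFrame | np.ndarray | None,
    results: pd.DataFrame,
    suggestive_p: float = SUGGESTIVE_P,
    ratio: float = 1.5,
    rule: str = "all",
) -> list[dict]:
    """Secondary signals at one locus by conditioning on the lead dosage.

    Each locus member is refit with the lead's dosage added as a covariate.
    The three declaration conditions are: (1) original p < suggestive_p;
    (2) -log10(P_lead) / -log10(P_sec) < ratio; (3) -log10(P_sec) /
    -log10(P_cond) < ratio. ``rule='all'`` (default, conservative) requires
    all three; ``rule='any'`` declares on any one. Candidates nearly
    collinear with the lead (r^2 > 0.99) are skipped.
    """
    if rule not in ("all", "any"):
        raise ValueError("rule must be 'all' or 'any'")
    id_to_col = {v: j for j, v in enumerate(variants["variant_id"])}
    g_lead = geno.dosages[:, id_to_col[locus.lead]]
    p_by_snp = dict(zip(results["SNP"], results["P"]))
    p_lead = max(p_by_snp[locus.lead], 1e-300)
    base_cov = None if covars is None else np.asarray(covars, dtype=float)
    secondaries = []
    for snp in locus.members:
        if snp == locus.lead:
            continue
        p_orig = p_by_snp.get(snp)
        if p_orig is None or not np.isfinite(p_orig):
            continue
        g = geno.dosages[:, id_to_col[snp]]
        if g.std() == 0:
            continue
        if ld_r2(g, g_lead) > 0.99:
            continue
        cond_cov = g_lead[:, None] if base_cov is None else np.column_stack([base_cov, g_lead])
        res = association_scan(
            GenotypeMatrix(g[:, None]), phenotype, covars=cond_cov, pc="cond"
        )
        p_cond = max(float(res["P"].iloc[0]), 1e-300)
        p_orig_c = max(p_orig, 1e-300)
        c1 = p_orig < suggestive_p
        c2 = (-np.log10(p_lead)) / (-np.log10(p_orig_c)) < ratio
        c3 = (-np.log10(p_orig_c)) / (-np.log10(p_cond)) < ratio
        declared = (c1 and c2 and c3) if rule == "all" else (c1 or c2 or c3)
        if declared:
            secondaries.append(
                {
                    "variant_id": snp,
                    "p_original": float(p_orig),
                    "p_conditional": p_cond,
                    "beta_conditional": float(res["BETA"].iloc[0]),
                    "se_conditional": float(res["SE"].iloc[0]),
                }
            )
    return secondaries


# ---------------------------------------------------------------------------
# heritability (Haseman-Elston) and variance explained

def grm(geno: GenotypeMatrix) -> np.ndarray:
    """Genomic relationship matrix from standardized dosages."""
    d = geno.dosages
    if np.isnan(d).any():
        d = np.where(np.isnan(d), np.nanmean(d, axis=0), d)
    mu = d.mean(axis=0)
    sd = d.std(axis=0)
    keep = sd > 0
    x = (d[:, keep] - mu[keep]) / sd[keep]
    return x @ x.T / x.shape[1]


def he_heritability(
    geno: GenotypeMatrix,
    pheno_a: np.ndarray,
    pheno_b: np.ndarray | None = None,
    n_jackknife_blocks: int = 20,
) -> HeritabilityEstimate:
    """Haseman-Elston regression heritability or genetic correlation.

    Univariate: slope of y_i*y_j on G_ij over pairs i<j with standardized
    phenotype = h2. Bivariate: the genetic covariance slope from the
    symmetrized cross products, reported as r_g = gcov/sqrt(h2_a*h2_b).
    SE by leave-one-block-out jackknife over subjects.
    """
    if geno.n_variants < 10:
        raise ValueError("need at least 10 variants")
    g = grm(geno)
    n = g.shape[0]
    ya = np.asarray(pheno_a, dtype=float)
    ya = (ya - ya.mean()) / ya.std()
    iu = np.triu_indices(n, k=1)
    gij = g[iu]

    def slope(prod, gv):
        gc = gv - gv.mean()
        return float(np.dot(gc, prod) / np.dot(gc, gc))

    if pheno_b is None:
        prod = np.outer(ya, ya)[iu]
        est = slope(prod, gij)

        def stat(mask_pairs):
            return slope(prod[mask_pairs], gij[mask_pairs])
    else:
        yb = np.asarray(pheno_b, dtype=float)
        yb = (yb - yb.mean()) / yb.std()
        cross = 0.5 * (np.outer(ya, yb) + np.outer(yb, ya))[iu]
        prod_a = np.outer(ya, ya)[iu]
        prod_b = np.outer(yb, yb)[iu]

        def rg(mask_pairs):
            gcov = slope(cross[mask_pairs], gij[mask_pairs])
            h2a = slope(prod_a[mask_pairs], gij[mask_pairs])
            h2b = slope(prod_b[mask_pairs], gij[mask_pairs])
            denom = np.sqrt(max(h2a, 1e-12) * max(h2b, 1e-12))
            return float(gcov / denom)

        est = rg(np.ones(gij.size, dtype=bool))
        stat = rg

    # block jackknife over subjects
    blocks = np.array_split(np.arange(n), n_jackknife_blocks)
    subj_i, subj_j = iu
    reps = []
    for blk in blocks:
        inblk = np.zeros(n, dtype=bool)
        inblk[blk] = True
        mask = ~(inblk[subj_i] | inblk[subj_j])
        reps.append(stat(mask))
    reps = np.asarray(reps)
    b = len(blocks)
    se = float(np.sqrt((b - 1) / b * np.sum((reps - reps.mean()) ** 2)))
    tag = "haseman-elston" if pheno_b is None else "haseman-elston-rg"
    return HeritabilityEstimate(pc="", h2=est, se=se, method=tag)


def pct_variance_explained(
    phenotype: np.ndarray,
    sig_dosages: np.ndarray,
    covars: pd.DataFrame | np.ndarray | None = None,
) -> float:
    """Percent phenotype variance attributable to significant variants.

    Incremental R^2: 100 * (R^2 of covariates + dosages - R^2 of covariates
    alone). With no covariates this is the plain regression R^2.
    """
    y = np.asarray(phenotype, dtype=float)
    g = np.asarray(sig_dosages, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    if g.shape[1] < 1:
        raise ValueError("need at least one significant variant")
    n = y.shape[0]

    def r2(x):
        x = np.column_stack([np.ones(n), x]) if x is not None else np.ones((n, 1))
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        tss = np.sum((y - y.mean()) ** 2)
        return 1.0 - np.sum(resid**2) / tss

    c = np.asarray(covars, dtype=float) if covars is not None else None
    base = r2(c) if c is not None else 0.0
    full = r2(np.column_stack([c, g]) if c is not None else g)
    return 100.0 * (full - base)
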