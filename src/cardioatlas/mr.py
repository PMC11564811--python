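"""Two-sample Mendelian randomization from GWAS summary statistics.

Pipeline: harmonize effect alleles between the exposure and outcome tables,
keep instruments with F = (beta/se)^2 > 10, LD-clump to independent
variants, then estimate the causal effect with inverse-variance weighting
(IVW), the weighted median, and MR-Egger regression. The three estimators
make complementary pleiotropy assumptions: IVW assumes none (or balanced),
the weighted median tolerates up to half invalid instruments by weight, and
Egger's intercept absorbs (and tests) directional pleiotropy.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeMatrix, MREstimate

PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# instrument construction

def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_eaf_window: tuple = (0.42, 0.58),
    drop_palindromic_in_window: bool = True,
) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect allele.

    Rows with swapped EA/NEA get their outcome beta sign-flipped and EAF
    mirrored. Strand-ambiguous palindromic variants (A/T or C/G) whose EAF
    falls in ``palindrome_eaf_window`` are dropped, since allele frequency
    cannot disambiguate the strand there. Variants whose allele pairs
    neither match nor swap are dropped with a warning. Adds the instrument
    F statistic (beta_x / se_x)^2.
    """
    merged = exposure.merge(outcome, on="SNP", suffixes=("_x", "_y"))
    rows = []
    dropped = []
    for _, r in merged.iterrows():
        ea_x, nea_x, ea_y, nea_y = r["EA_x"], r["NEA_x"], r["EA_y"], r["NEA_y"]
        if frozenset((ea_x, nea_x)) in PALINDROMIC and drop_palindromic_in_window:
            lo, hi = palindrome_eaf_window
            if lo < r["EAF_x"] < hi:
                dropped.append((r["SNP"], "palindromic, ambiguous EAF"))
                continue
        if (ea_y, nea_y) == (ea_x, nea_x):
            b_y, eaf_y = r["BETA_y"], r["EAF_y"]
        elif (ea_y, nea_y) == (nea_x, ea_x):
            b_y, eaf_y = -r["BETA_y"], 1.0 - r["EAF_y"]
        else:
            dropped.append((r["SNP"], "incompatible alleles"))
            continue
        rows.append(
            {
                "SNP": r["SNP"],
                "CHR": r.get("CHR_x", r.get("CHR", np.nan)),
                "POS": r.get("POS_x", r.get("POS", np.nan)),
                "EA": ea_x, "NEA": nea_x, "EAF": r["EAF_x"],
                "beta_exposure": r["BETA_x"], "se_exposure": r["SE_x"],
                "beta_outcome": b_y, "se_outcome": r["SE_y"],
                "eaf_outcome": eaf_y,
                "p_exposure": r.get("P_x", np.nan),
            }
        )
    if dropped:
        warnings.warn(f"harmonization dropped {len(dropped)} variant(s): {dropped}", stacklevel=2)
    out = pd.DataFrame(rows)
    if not out.empty:
        out["F"] = (out["beta_exposure"] / out["se_exposure"]) ** 2
    return out


def strength_filter(instruments: pd.DataFrame, f_min: float = 10.0) -> pd.DataFrame:
    """Keep instruments with F strictly greater than ``f_min``."""
    if "F" not in instruments.columns:
        raise ValueError("instrument table lacks F statistics (run harmonize)")
    kept = instruments[instruments["F"] > f_min].reset_index(drop=True)
    if kept.empty:
        raise ValueError(f"no instruments with F > {f_min}")
    return kept


def ld_clump(
    instruments: pd.DataFrame,
    geno_ref: GenotypeMatrix,
    ref_variants: pd.DataFrame,
    r2_max: float = 0.001,
    window_kb: float = 10_000.0,
) -> pd.DataFrame:
    """Greedy LD clumping: keep the lowest-p variant, drop correlated ones.

    Walks instruments by ascending exposure p-value; a variant is dropped
    when it lies within ``window_kb`` of an already-kept variant on the same
    chromosome with reference-panel r^2 > ``r2_max``. Instruments absent
    from the reference are dropped with a warning.
    """
    ref_cols = {v: j for j, v in enumerate(ref_variants["variant_id"])}
    df = instruments.sort_values(["p_exposure", "CHR", "POS"], kind="mergesort")
    window = window_kb * 1000.0
    kept_rows = []
    for _, r in df.iterrows():
        j = ref_cols.get(r["SNP"])
        if j is None:
            warnings.warn(f"{r['SNP']} absent from LD reference; dropped", stacklevel=2)
            continue
        g = geno_ref.dosages[:, j]
        clumped = False
        for k in kept_rows:
            if r["CHR"] != k["CHR"] or abs(r["POS"] - k["POS"]) > window:
                continue
            gk = geno_ref.dosages[:, ref_cols[k["SNP"]]]
            if g.std() == 0 or gk.std() == 0:
                continue
            r2 = float(np.corrcoef(g, gk)[0, 1]) ** 2
            if r2 > r2_max:
                clumped = True
                break
        if not clumped:
            kept_rows.append(r)
    return pd.DataFrame(kept_rows).reset_index(drop=True)


# ---------------------------------------------------------------------------
# estimators

def _wald_ratios(inst: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    bx = inst["beta_exposure"].to_numpy(dtype=float)
    by = inst["beta_outcome"].to_numpy(dtype=float)
    sy = inst["se_outcome"].to_numpy(dtype=float)
    ratios = by / bx
    se = sy / np.abs(bx)  # first-order delta method
    return ratios, se


def ivw(instruments: pd.DataFrame) -> MREstimate:
    """Inverse-variance-weighted estimate.

    beta_IVW = sum(bx*by/sy^2) / sum(bx^2/sy^2); fixed-effect SE
    1/sqrt(sum(bx^2/sy^2)), inflated multiplicatively by sqrt(Q/df) when
    Cochran heterogeneity exceeds its degrees of freedom. With a single
    instrument this reduces to the Wald ratio.
    """
    k = len(instruments)
    if k < 1:
        raise ValueError("need at least 1 instrument")
    bx = instruments["beta_exposure"].to_numpy(dtype=float)
    by = instruments["beta_outcome"].to_numpy(dtype=float)
    sy = instruments["se_outcome"].to_numpy(dtype=float)
    w = bx**2 / sy**2
    est = float(np.sum(bx * by / sy**2) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    if k > 1:
        ratios = by / bx
        q = float(np.sum(w * (ratios - est) ** 2))
        scale = q / (k - 1)
        if scale > 1.0:
            se *= np.sqrt(scale)  # multiplicative random effects
    p = float(2 * stats.norm.sf(abs(est) / se))
    return MREstimate("ivw", est, se, p, n_instruments=k)


def weighted_median(
    instruments: pd.DataFrame,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted median of Wald ratios; robust to <50% invalid weight.

    Weights are inverse variances of the ratios (delta method); the median
    interpolates the weighted empirical CDF at 0.5. SE comes from a
    parametric bootstrap (instrument betas resampled from their normals,
    ``n_bootstrap`` replicates, seeded).
    """
    k = len(instruments)
    if k < 3:
        raise ValueError("weighted median needs at least 3 instruments")
    ratios, se_r = _wald_ratios(instruments)
    w = 1.0 / se_r**2

    def wmedian(r, wt):
        order = np.argsort(r)
        r_s, w_s = r[order], wt[order]
        cum = np.cumsum(w_s) - 0.5 * w_s
        cum /= w_s.sum()
        return float(np.interp(0.5, cum, r_s))

    est = wmedian(ratios, w)
    rng = np.random.default_rng(seed)
    bx = instruments["beta_exposure"].to_numpy(dtype=float)
    by = instruments["beta_outcome"].to_numpy(dtype=float)
    sx = instruments["se_exposure"].to_numpy(dtype=float)
    sy = instruments["se_outcome"].to_numpy(dtype=float)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        bxb = bx + rng.normal(0.0, sx)
        byb = by + rng.normal(0.0, sy)
        rb = byb / bxb
        wb = (np.abs(bxb) / sy) ** 2
        boots[b] = wmedian(rb, wb)
    se = float(boots.std(ddof=1))
    p = float(2 * stats.norm.sf(abs(est) / se)) if se > 0 else 0.0
    return MREstimate("weighted-median", est, se, p, n_instruments=k)


def egger(instruments: pd.DataFrame) -> MREstimate:
    """MR-Egger: weighted regression of outcome on exposure betas with
    intercept.

    Exposure effects are first oriented positive (flipping the paired
    outcome betas), the standard Egger orientation. Weights are 1/se_y^2;
    the slope estimates the causal effect and the intercept the average
    directional pleiotropy, with t-based p-values on k-2 df.
    """
    k = len(instruments)
    if k < 3:
        raise ValueError("Egger needs at least 3 instruments")
    bx = instruments["beta_exposure"].to_numpy(dtype=float)
    by = instruments["beta_outcome"].to_numpy(dtype=float)
    sy = instruments["se_outcome"].to_numpy(dtype=float)
    sign = np.sign(bx)
    sign[sign == 0] = 1.0
    bx, by = bx * sign, by * sign
    if np.ptp(bx) == 0:
        raise ValueError("no variation in exposure betas")
    w = 1.0 / sy**2
    x = np.column_stack([np.ones(k), bx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - x @ coef
    dof = k - 2
    sigma2 = float(np.sum(w * resid**2) / dof)
    # MR-Egger convention: never deflate below the fixed-effect variance
    sigma2 = max(sigma2, 1.0)
    cov = sigma2 * np.linalg.inv(xtwx)
    se_i, se_s = np.sqrt(np.diag(cov))
    p_slope = float(2 * stats.t.sf(abs(coef[1]) / se_s, df=dof))
    p_int = float(2 * stats.t.sf(abs(coef[0]) / se_i, df=dof))
    return MREstimate(
        "egger", float(coef[1]), float(se_s), p_slope, n_instruments=k,
        intercept=float(coef[0]), intercept_se=float(se_i), intercept_p=p_int,
    )


# ---------------------------------------------------------------------------
# harness

def run_mr(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    geno_ref: GenotypeMatrix | None = None,
    ref_variants: pd.DataFrame | None = None,
    f_min: float = 10.0,
    clump_r2: float = 0.001,
    clump_window_kb: float = 10_000.0,
    seed: int = 0,
) -> dict:
    """Full one-direction MR: harmonize, filter, clump, estimate.

    Returns a dict with the instrument table and the three MREstimates
    (keys 'ivw', 'weighted_median', 'egger'; the latter two are None when
    fewer than 3 instruments survive).
    """
    inst = harmonize(exposure, outcome)
    inst = strength_filter(inst, f_min=f_min)
    if geno_ref is not None and ref_variants is not None:
        inst = ld_clump(inst, geno_ref, ref_variants, r2_max=clump_r2,
                        window_kb=clump_window_kb)
    out = {"instruments": inst, "ivw": ivw(inst)}
    out["weighted_median"] = weighted_median(inst, seed=seed) if len(inst) >= 3 else None
    out["egger"] = egger(inst) if len(inst) >= 3 else None
    return out


def bidirectional_mr(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    **kwargs,
) -> dict:
    """Run MR in both directions (A->B and B->A) and report both."""
    return {
        "forward": run_mr(stats_a, stats_b, **kwargs),
        "reverse": run_mr(stats_b, stats_a, **kwargs),
    }
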