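"""Polygenic risk scores from GWAS lead variants.

A PRS is the sum of effect-allele dosages weighted by the GWAS betas,
z-standardized on the scoring cohort so disease associations read as odds
ratio per SD of PRS. Only lead variants are scored (no clumping +
thresholding grid), matching a lead-variant score construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas import ld_r2, pct_variance_explained
from .pheno_assoc import AssociationRecord, logistic_odds_ratio
from .types import GenotypeMatrix


@dataclass
class PRSModel:
    """Lead-variant score: per variant, the effect allele and its weight."""

    pc: str
    entries: pd.DataFrame  # columns: variant_id, EA, weight
    standardization: tuple | None = None  # (mean, sd) on the scoring cohort

    def __post_init__(self) -> None:
        req = {"variant_id", "EA", "weight"}
        if not req.issubset(self.entries.columns):
            raise ValueError(f"entries must have columns {sorted(req)}")
        if self.entries["variant_id"].duplicated().any():
            raise ValueError("duplicate variant ids in PRS model")
        if not np.all(np.isfinite(self.entries["weight"])):
            raise ValueError("weights must be finite")


def prs_from_scan(results: pd.DataFrame, lead_ids: list[str], pc: str = "PC") -> PRSModel:
    """Build a PRS model from scan results restricted to lead variants."""
    sub = results[results["SNP"].isin(lead_ids)]
    entries = pd.DataFrame(
        {"variant_id": sub["SNP"], "EA": sub["EA"], "weight": sub["BETA"]}
    ).reset_index(drop=True)
    return PRSModel(pc=pc, entries=entries)


def score_prs(
    model: PRSModel,
    geno: GenotypeMatrix,
    variants: pd.DataFrame,
    proxy_ref: tuple | None = None,
    proxy_r2_min: float = 0.8,
    standardize: bool = True,
) -> np.ndarray:
    """Score a cohort: sum of weight * effect-allele dosage, standardized.

    Dosages are counted on the model's effect allele: when the cohort table
    lists the opposite allele as EA, the dosage is flipped to 2 - g. Model
    variants absent from the cohort are substituted by their highest-r^2 LD
    proxy (r^2 > ``proxy_r2_min``) found in ``proxy_ref``, a
    (GenotypeMatrix, variant table) reference panel carrying both the
    missing variant and the cohort's variants; the proxy dosage is oriented
    to the allele positively correlated with the missing variant's effect
    allele. Variants with no admissible proxy raise an error listing the
    ids.
    """
    id_to_col = {v: j for j, v in enumerate(variants["variant_id"])}
    alleles = variants.set_index("variant_id")[["EA", "NEA"]]
    raw = np.zeros(geno.n_subjects)
    missing = []
    for _, row in model.entries.iterrows():
        vid, ea, w = row["variant_id"], row["EA"], float(row["weight"])
        flip_for_proxy = False
        if vid not in id_to_col:
            sub = _best_proxy(vid, ea, set(id_to_col), proxy_ref, proxy_r2_min)
            if sub is None:
                missing.append(vid)
                continue
            vid, flip_for_proxy = sub
            ea = alleles.loc[vid, "EA"]
        g = geno.dosages[:, id_to_col[vid]]
        cohort_ea = alleles.loc[vid, "EA"]
        cohort_nea = alleles.loc[vid, "NEA"]
        if ea == cohort_ea:
            dose = g
        elif ea == cohort_nea:
            dose = 2.0 - g
        else:
            raise ValueError(f"allele mismatch for {vid}: model EA {ea}")
        if flip_for_proxy:
            dose = 2.0 - dose
        raw += w * dose
    if missing:
        raise ValueError(f"model variants missing from cohort, no proxy: {missing}")
    if not standardize:
        return raw
    sd = raw.std()
    if sd == 0:
        warnings.warn("constant PRS; returning zeros", stacklevel=2)
        return raw - raw.mean()
    return (raw - raw.mean()) / sd


def _best_proxy(vid, model_ea, cohort_ids, proxy_ref, r2_min):
    """Highest-r^2 stand-in for a missing variant from a reference panel.

    Returns (proxy_id, flip) where flip means the proxy's EA dosage is
    negatively correlated with the missing variant's model-EA dosage, or
    None when no candidate clears ``r2_min``.
    """
    if proxy_ref is None:
        return None
    ref_geno, ref_variants = proxy_ref
    ref_cols = {v: j for j, v in enumerate(ref_variants["variant_id"])}
    if vid not in ref_cols:
        return None
    ref_alleles = ref_variants.set_index("variant_id")[["EA", "NEA"]]
    target = ref_geno.dosages[:, ref_cols[vid]]
    if ref_alleles.loc[vid, "EA"] != model_ea:
        target = 2.0 - target  # orient to the model's effect allele
    best = None
    for cand in cohort_ids:
        j = ref_cols.get(cand)
        if j is None:
            continue
        g = ref_geno.dosages[:, j]
        if g.std() == 0 or target.std() == 0:
            continue
        r = float(np.corrcoef(target, g)[0, 1])
        if r * r > r2_min and (best is None or r * r > best[2]):
            best = (cand, r < 0, r * r)
    if best is None:
        return None
    return best[0], best[1]


def prs_disease_association(
    scores: np.ndarray,
    outcome: np.ndarray,
    covars: pd.DataFrame | None = None,
    pc: str = "PRS",
    outcome_name: str = "outcome",
) -> AssociationRecord:
    """Logistic OR per SD of PRS with Wald CI and two-sided p."""
    return logistic_odds_ratio(scores, outcome, covars, pc=pc, outcome_name=outcome_name)


def prs_transferability(
    model: PRSModel,
    cohorts: dict,
    low_freq_threshold: float = 0.01,
) -> dict:
    """Per-group PRS performance and allele-frequency audit.

    ``cohorts`` maps group name to a dict with keys ``geno``
    (GenotypeMatrix), ``variants`` (table), ``pc_scores`` (vector) and
    optional ``covars``. Returns per group the percent variance of the PC
    score explained by the PRS (incremental R^2 after covariates) and a
    per-variant effect-allele frequency table flagging EAF below
    ``low_freq_threshold``.
    """
    if not cohorts:
        raise ValueError("need at least one group")
    out = {}
    for group, data in cohorts.items():
        geno, variants = data["geno"], data["variants"]
        if geno.n_subjects < 50:
            warnings.warn(f"group {group} has n < 50; results unstable", stacklevel=2)
        scores = score_prs(model, geno, variants)
        covars = data.get("covars")
        r2_pct = pct_variance_explained(data["pc_scores"], scores, covars=covars)
        vt = variants.set_index("variant_id")
        rows = []
        for vid in model.entries["variant_id"]:
            if vid in vt.index:
                eaf = float(vt.loc[vid, "EAF"])
                rows.append(
                    {"variant_id": vid, "EAF": eaf,
                     "low_freq": min(eaf, 1 - eaf) < low_freq_threshold}
                )
            else:
                rows.append({"variant_id": vid, "EAF": np.nan, "low_freq": True})
        out[group] = {"r2_pct": r2_pct, "freq_table": pd.DataFrame(rows), "n": geno.n_subjects}
    return out
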