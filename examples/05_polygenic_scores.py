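"""Lead-variant polygenic risk score: construction, association, transfer.

Scans a training cohort, builds a PRS from the lead variants, scores a
held-out cohort, and tests the PRS against the PC phenotype and a disease
outcome, plus a transferability check in a second group.
"""

import numpy as np

from cardioatlas import SimulationConfig
from cardioatlas.gwas import association_scan, define_loci_and_signals
from cardioatlas.pheno_assoc import pearson_correlation
from cardioatlas.prs import prs_disease_association, prs_from_scan, prs_transferability, score_prs
from cardioatlas.synthdata import sample_genotypes
from cardioatlas.types import GenotypeMatrix

cfg = SimulationConfig(n_subjects=4000, n_variants=1000, ld_rho=0.0,
                       ld_block_size=10, maf_range=(0.1, 0.5), seed=6)
geno, variants = sample_genotypes(cfg)

# 30%-heritable PC phenotype from 10 causal variants
rng = np.random.default_rng(7)
x = (geno.dosages - geno.dosages.mean(0)) / geno.dosages.std(0)
idx = rng.choice(1000, 10, replace=False)
g = x[:, idx] @ rng.standard_normal(10)
pc = np.sqrt(0.3) * (g - g.mean()) / g.std() + np.sqrt(0.7) * rng.standard_normal(4000)

train, test = slice(0, 2000), slice(2000, 4000)
g_train = GenotypeMatrix(geno.dosages[train])
res = association_scan(g_train, pc[train], variants=variants, pc="PC1")
loci = define_loci_and_signals(res, g_train, variants)
model = prs_from_scan(res, loci.lead_ids, pc="PC1")
print(f"PRS built from {len(model.entries)} lead variants")

g_test = GenotypeMatrix(geno.dosages[test])
scores = score_prs(model, g_test, variants)
r, p = pearson_correlation(scores, pc[test])
print(f"held-out PRS vs PC1: r = {r:+.3f}, p = {p:.2g}")

# disease risk rises with the PC; the PRS should pick that up per SD
logit = 0.4 * pc[test] - 2.5
y = (rng.uniform(size=2000) < 1 / (1 + np.exp(-logit))).astype(float)
rec = prs_disease_association(scores, y, outcome_name="disease")
print(f"disease ~ PRS: OR {rec.odds_ratio:.2f} per SD "
      f"(95% CI {rec.ci95[0]:.2f}-{rec.ci95[1]:.2f}), p = {rec.p_value:.2g}")

# transferability: two held-out halves behave exchangeably
halves = {
    "group_a": {"geno": GenotypeMatrix(geno.dosages[2000:3000]), "variants": variants,
                "pc_scores": pc[2000:3000]},
    "group_b": {"geno": GenotypeMatrix(geno.dosages[3000:4000]), "variants": variants,
                "pc_scores": pc[3000:4000]},
}
out = prs_transferability(model, halves)
for gname, d in out.items():
    n_low = int(d["freq_table"]["low_freq"].sum())
    print(f"{gname}: PRS explains {d['r2_pct']:.1f}% of PC variance; "
          f"{n_low} lead variant(s) below 1% frequency")
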