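"""Bidirectional two-sample Mendelian randomization from summary statistics.

Generates exposure/outcome GWAS tables with a known causal effect of 0.2
(with scrambled alleles to exercise harmonization), then estimates the
effect with IVW, weighted median and MR-Egger — once without and once with
directional pleiotropy, where only Egger stays unbiased.
"""

import numpy as np

from cardioatlas.mr import run_mr
from cardioatlas.synthdata import make_mr_summary_stats


def report(tag, res):
    ivw, wm, eg = res["ivw"], res["weighted_median"], res["egger"]
    print(f"{tag} ({ivw.n_instruments} instruments after F>10 filter)")
    print(f"  IVW             {ivw.estimate:+.3f} (95% CI {ivw.ci95[0]:+.3f} "
          f"to {ivw.ci95[1]:+.3f})")
    print(f"  weighted median {wm.estimate:+.3f} +/- {wm.se:.3f}")
    print(f"  MR-Egger slope  {eg.estimate:+.3f}, intercept {eg.intercept:+.4f} "
          f"(p = {eg.intercept_p:.2f})")


exposure, outcome, truth = make_mr_summary_stats(
    n_instruments=30, causal_effect=0.2, allele_scramble=True, seed=8
)
res = run_mr(exposure, outcome, seed=1)
report("no pleiotropy, truth 0.200", res)

exp_p, out_p, _ = make_mr_summary_stats(
    n_instruments=30, causal_effect=0.2, pleiotropy=0.05, seed=9
)
res_p = run_mr(exp_p, out_p, seed=1)
report("\ndirectional pleiotropy +0.05, truth 0.200", res_p)
print("  -> IVW absorbs the pleiotropy into its slope; the Egger intercept")
print("     estimates it (+0.05) and the Egger slope stays near the truth.")
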