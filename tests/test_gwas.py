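"""Variant QC, scan calibration, loci/signals, conditional logic, heritability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from cardioatlas import SimulationConfig
from cardioatlas.gwas import (
    association_scan,
    conditional_secondary_scan,
    define_loci_and_signals,
    genomic_inflation,
    he_heritability,
    hwe_exact_test,
    ld_r2,
    pct_variance_explained,
    variant_qc,
)
from cardioatlas.synthdata import sample_genotypes
from cardioatlas.types import GenotypeMatrix, variant_table


def hwe_brute_force(n_aa, n_ab, n_bb):
    """Independent enumeration oracle using binomial coefficients."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    n_minor = min(na, nb)

    def prob(h):
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        num = comb(n, h, exact=True) * comb(n - h, hom_min, exact=True) * 2**h
        den = comb(2 * n, n_minor, exact=True)
        return num / den

    hets = range(n_minor % 2, n_minor + 1, 2)
    probs = {h: prob(h) for h in hets}
    p_obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestHWE:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(0, 0, 100) == 1.0

    def test_perfect_hwe_proportions(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_total_het_deficit(self):
        assert hwe_exact_test(50, 0, 50) < 1e-6

    @pytest.mark.parametrize("counts", [(25, 50, 25), (10, 40, 50), (3, 7, 90), (0, 5, 95)])
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(hwe_brute_force(*counts), rel=1e-10)


class TestVariantQC:
    def _toy(self):
        rng = np.random.default_rng(4)
        n = 1000
        cols = []
        # v0 rare (maf ~0.005), v1/v2 clean, v3 HWE violation, v4 missing 2%
        for maf in (0.005, 0.02, 0.3):
            p = maf
            cols.append(rng.binomial(1, p, n) + rng.binomial(1, p, n))
        v4 = np.repeat([0.0, 2.0], n // 2)  # no heterozygotes at 50% frequency
        cols.append(v4)
        v5 = rng.binomial(1, 0.3, n) + rng.binomial(1, 0.3, n).astype(float)
        v5[: int(0.02 * n)] = np.nan
        cols.append(v5)
        d = np.column_stack(cols).astype(float)
        vt = variant_table([f"v{i}" for i in range(5)], [1] * 5, range(1, 6),
                           ["A"] * 5, ["G"] * 5, [0.1] * 5)
        return GenotypeMatrix(d), vt

    def test_constructed_filters(self):
        geno, vt = self._toy()
        filt, kept, counts = variant_qc(geno, vt)
        assert list(kept["variant_id"]) == ["v1", "v2"]  # v1 is maf .02, v2 .3
        assert counts["fail_maf"] == 1
        assert counts["fail_hwe"] == 1
        assert counts["fail_missing"] == 1

    def test_clean_variants_identity(self, geno_cohort):
        geno, vt = geno_cohort
        filt, kept, counts = variant_qc(geno, vt)
        assert counts["fail_missing"] == 0

    def test_hwe_consistent_simulation_survives(self):
        cfg = SimulationConfig(n_subjects=1000, n_variants=1000, ld_rho=0.0,
                               ld_block_size=10, maf_range=(0.05, 0.5), seed=6)
        geno, vt = sample_genotypes(cfg)
        _, kept, counts = variant_qc(geno, vt)
        assert counts["n_kept"] >= 0.99 * cfg.n_variants


class TestScan:
    def test_exact_linear_phenotype(self, geno_cohort):
        geno, vt = geno_cohort
        y = 0.1 * geno.dosages[:, 7]
        res = association_scan(geno, y, variants=vt)
        assert res["BETA"].iloc[7] == pytest.approx(0.1, abs=1e-10)
        assert res["P"].iloc[7] < 1e-200

    def test_covariate_rescaling_invariance(self, geno_cohort, rng):
        geno, vt = geno_cohort
        n = geno.n_subjects
        y = rng.standard_normal(n)
        c = rng.standard_normal((n, 2))
        r1 = association_scan(geno, y, covars=c)
        r2 = association_scan(geno, y, covars=c * 100.0 + 3.0)
        assert np.allclose(r1["BETA"], r2["BETA"], atol=1e-8)
        assert np.allclose(r1["SE"], r2["SE"], atol=1e-8)

    def test_beta_coverage(self, rng):
        cfg = SimulationConfig(n_subjects=2000, n_variants=20, ld_rho=0.0,
                               ld_block_size=10, maf_range=(0.2, 0.5), seed=8)
        geno, vt = sample_genotypes(cfg)
        g = geno.dosages[:, 0]
        gs = (g - g.mean()) / g.std()
        covered = 0
        n_reps = 50
        true_beta = np.sqrt(0.02) / g.std()  # per-variant R^2 of 2%
        for rep in range(n_reps):
            r = np.random.default_rng(500 + rep)
            y = true_beta * g + np.sqrt(1 - 0.02) * r.standard_normal(2000)
            res = association_scan(geno, y)
            b, se = res["BETA"].iloc[0], res["SE"].iloc[0]
            covered += (b - 1.96 * se) <= true_beta <= (b + 1.96 * se)
        assert covered >= 42  # binomial 95% band around 0.95*50


class TestInflation:
    def test_uniform_null(self, rng):
        p = rng.uniform(size=100_000)
        assert genomic_inflation(p) == pytest.approx(1.0, abs=0.02)

    def test_definitional_half(self):
        assert genomic_inflation(np.full(200, 0.5)) == pytest.approx(1.0, abs=1e-12)

    def test_inflated_chisq(self, rng):
        chi2 = 1.2 * rng.chisquare(1, size=100_000)
        p = stats.chi2.sf(chi2, df=1)
        assert genomic_inflation(p) == pytest.approx(1.2, abs=0.03)


class TestLD:
    def test_self_and_flip(self, geno_cohort):
        geno, _ = geno_cohort
        g = geno.dosages[:, 0]
        assert ld_r2(g, g) == pytest.approx(1.0)
        assert ld_r2(g, 2.0 - g) == pytest.approx(1.0)

    def test_matches_direct_recomputation(self, geno_cohort):
        geno, _ = geno_cohort
        g1, g2 = geno.dosages[:, 0], geno.dosages[:, 1]
        direct = np.corrcoef(g1, g2)[0, 1] ** 2
        assert ld_r2(g1, g2) == pytest.approx(direct, rel=1e-12)


def greedy_loci_oracle(pvals, positions, chroms, dosages, gw_p, window, signal_r2):
    """Straight-line reimplementation of the greedy locus rule."""
    alive = set(range(len(pvals)))
    loci = []
    while True:
        sig = [i for i in alive if pvals[i] < gw_p]
        if not sig:
            break
        lead = min(sig, key=lambda i: (pvals[i], chroms[i], positions[i]))
        members = [
            i for i in alive
            if chroms[i] == chroms[lead] and abs(positions[i] - positions[lead]) <= window
        ]
        signal = [lead] + [
            i for i in members
            if i != lead and np.corrcoef(dosages[:, lead], dosages[:, i])[0, 1] ** 2 > signal_r2
        ]
        loci.append((lead, sorted(members), sorted(signal)))
        alive -= set(members)
    return loci


class TestLoci:
    def _scan_frame(self, vt, pvals):
        return pd.DataFrame(
            {"PC": "PC1", "SNP": vt["variant_id"], "CHR": vt["chr"], "POS": vt["pos"],
             "EA": vt["EA"], "NEA": vt["NEA"], "EAF": vt["EAF"],
             "BETA": 0.1, "SE": 0.01, "P": pvals}
        )

    def test_no_significant_hits(self, geno_cohort):
        geno, vt = geno_cohort
        res = self._scan_frame(vt, np.full(geno.n_variants, 0.5))
        assert define_loci_and_signals(res, geno, vt).n_loci == 0

    def test_window_merges_nearby_hits(self):
        cfg = SimulationConfig(n_subjects=500, n_variants=100, ld_rho=0.9,
                               ld_block_size=100, maf_range=(0.3, 0.5), seed=10)
        geno, vt = sample_genotypes(cfg)  # one 100-variant block, 10 kb spacing
        p = np.full(100, 0.5)
        p[10], p[40] = 1e-12, 1e-10  # 300 kb apart, high LD
        res = self._scan_frame(vt, p)
        ls = define_loci_and_signals(res, geno, vt)
        assert ls.n_loci == 1
        assert len(ls.loci[0].signal_members) >= 2

    def test_distant_independent_hits_two_loci(self):
        cfg = SimulationConfig(n_subjects=500, n_variants=500, ld_rho=0.0,
                               ld_block_size=10, maf_range=(0.3, 0.5), seed=12)
        geno, vt = sample_genotypes(cfg)
        p = np.full(500, 0.5)
        p[10], p[400] = 1e-12, 1e-10  # ~3.9 Mb apart, no LD
        res = self._scan_frame(vt, p)
        ls = define_loci_and_signals(res, geno, vt)
        assert ls.n_loci == 2

    def test_matches_brute_force_oracle(self):
        cfg = SimulationConfig(n_subjects=300, n_variants=50, ld_rho=0.6,
                               ld_block_size=5, maf_range=(0.2, 0.5), seed=14)
        geno, vt = sample_genotypes(cfg)
        rng = np.random.default_rng(15)
        p = 10.0 ** rng.uniform(-12, 0, size=50)
        res = self._scan_frame(vt, p)
        ls = define_loci_and_signals(res, geno, vt)
        oracle = greedy_loci_oracle(
            p, vt["pos"].to_numpy(), vt["chr"].to_numpy(), geno.dosages,
            5e-8, 500_000, 0.1,
        )
        assert ls.n_loci == len(oracle)
        for locus, (lead, members, signal) in zip(ls.loci, oracle):
            assert locus.lead == vt["variant_id"].iloc[lead]
            assert sorted(locus.members) == sorted(vt["variant_id"].iloc[members])
            assert sorted(locus.signal_members) == sorted(vt["variant_id"].iloc[signal])


class TestConditional:
    def _locus_setup(self, seed, two_causal):
        cfg = SimulationConfig(n_subjects=2000, n_variants=20, ld_rho=0.3,
                               ld_block_size=20, maf_range=(0.2, 0.5), seed=seed)
        geno, vt = sample_genotypes(cfg)
        rng = np.random.default_rng(seed + 10_000)
        g1 = geno.dosages[:, 2]
        y = 0.35 * (g1 - g1.mean()) / g1.std()
        if two_causal:
            g2 = geno.dosages[:, 15]
            y = y + 0.30 * (g2 - g2.mean()) / g2.std()
        y = y + np.sqrt(1 - (0.35**2 + (0.30**2 if two_causal else 0))) * rng.standard_normal(2000)
        res = association_scan(geno, y, variants=vt)
        ls = define_loci_and_signals(res, geno, vt)
        return geno, vt, y, res, ls

    def test_two_causal_variants_declare_secondary(self):
        geno, vt, y, res, ls = self._locus_setup(16, two_causal=True)
        assert ls.n_loci >= 1
        sec = conditional_secondary_scan(ls.loci[0], geno, vt, y, None, res)
        assert len(sec) >= 1

    def test_single_causal_no_secondary(self):
        hits = 0
        for rep in range(20):
            geno, vt, y, res, ls = self._locus_setup(30 + rep, two_causal=False)
            if ls.n_loci == 0:
                continue
            sec = conditional_secondary_scan(ls.loci[0], geno, vt, y, None, res)
            hits += len(sec) > 0
        assert hits <= 1

    def test_suggestive_gate(self, geno_cohort):
        geno, vt = geno_cohort
        rng = np.random.default_rng(17)
        y = rng.standard_normal(geno.n_subjects)
        res = association_scan(geno, y, variants=vt)
        # force a lead and give a neighbor p just above the suggestive gate
        res.loc[0, "P"] = 1e-12
        res.loc[1, "P"] = 1e-5
        ls = define_loci_and_signals(res, geno, vt)
        sec = conditional_secondary_scan(ls.loci[0], geno, vt, y, None, res)
        assert all(s["p_original"] < 1e-6 for s in sec)
        assert not any(s["variant_id"] == res["SNP"].iloc[1] for s in sec)


class TestHeritability:
    def test_null_phenotype(self, rng):
        cfg = SimulationConfig(n_subjects=800, n_variants=500, ld_rho=0.0,
                               ld_block_size=10, seed=18)
        geno, _ = sample_genotypes(cfg)
        est = he_heritability(geno, rng.standard_normal(800))
        assert abs(est.h2) <= 2 * est.se + 0.02

    def test_self_genetic_correlation_is_one(self, rng):
        cfg = SimulationConfig(n_subjects=400, n_variants=200, ld_rho=0.0,
                               ld_block_size=10, seed=20)
        geno, _ = sample_genotypes(cfg)
        y = rng.standard_normal(400)
        est = he_heritability(geno, y, y)
        assert est.h2 == pytest.approx(1.0, abs=1e-6)

    def test_shared_architecture_genetic_correlation(self):
        # two phenotypes with the same causal set and effect correlation 0.75
        cfg = SimulationConfig(n_subjects=2000, n_variants=2000, ld_rho=0.0,
                               ld_block_size=10, maf_range=(0.1, 0.5), seed=22)
        geno, _ = sample_genotypes(cfg)
        rng = np.random.default_rng(23)
        m = 100
        idx = rng.choice(2000, m, replace=False)
        x = geno.dosages[:, idx]
        x = (x - x.mean(axis=0)) / x.std(axis=0)
        rho = 0.75
        b1 = rng.standard_normal(m)
        b2 = rho * b1 + np.sqrt(1 - rho**2) * rng.standard_normal(m)
        h2 = 0.5
        g1, g2 = x @ b1, x @ b2
        y1 = np.sqrt(h2) * g1 / g1.std() + np.sqrt(1 - h2) * rng.standard_normal(2000)
        y2 = np.sqrt(h2) * g2 / g2.std() + np.sqrt(1 - h2) * rng.standard_normal(2000)
        est = he_heritability(geno, y1, y2)
        assert est.h2 == pytest.approx(rho, abs=0.1)


class TestPctVariance:
    def test_exact_linear(self, geno_cohort):
        geno, _ = geno_cohort
        y = 0.3 * geno.dosages[:, 5]
        assert pct_variance_explained(y, geno.dosages[:, 5]) == pytest.approx(100.0)

    def test_null_inflation_magnitude(self, rng):
        n, k = 2000, 10
        y = rng.standard_normal(n)
        g = rng.binomial(2, 0.3, size=(n, k)).astype(float)
        pct = pct_variance_explained(y, g)
        assert pct < 2 * 100 * k / n  # ~ E[R^2] = k/n under the null

    def test_many_small_effects(self, rng):
        n, k = 2000, 20
        g = rng.binomial(2, 0.3, size=(n, k)).astype(float)
        gs = (g - g.mean(axis=0)) / g.std(axis=0)
        per = 0.001
        y = gs @ (np.full(k, np.sqrt(per))) + np.sqrt(1 - k * per) * rng.standard_normal(n)
        pct = pct_variance_explained(y, g)
        assert pct == pytest.approx(2.0, abs=0.7 * 2)
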