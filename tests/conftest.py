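"""Shared fixtures: a small simulated cohort and its trained atlas."""

import numpy as np
import pytest

from cardioatlas import SimulationConfig, build_atlas, generalized_procrustes, make_template
from cardioatlas.synthdata import sample_genotypes, sample_shape_population


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        n_subjects=200,
        n_points=120,
        n_latent_modes=3,
        mode_sds=(8.0, 4.0, 2.0),
        noise_sd=0.3,
        n_variants=200,
        ld_block_size=10,
        ld_rho=0.4,
        per_mode_h2=(0.3, 0.3, 0.3),
        causal_per_mode=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_template(small_cfg):
    return make_template(small_cfg.n_points)


@pytest.fixture(scope="session")
def small_population(small_cfg, small_template):
    meshes, truth = sample_shape_population(small_cfg, small_template)
    return meshes, truth


@pytest.fixture(scope="session")
def small_atlas(small_population):
    meshes, _ = small_population
    aligned, consensus, _ = generalized_procrustes(meshes)
    atlas = build_atlas(aligned)
    return atlas, aligned


@pytest.fixture(scope="session")
def geno_cohort():
    """Genotypes with LD blocks for GWAS/PRS/MR reference tests."""
    cfg = SimulationConfig(
        n_subjects=1000, n_variants=300, ld_block_size=10, ld_rho=0.5,
        maf_range=(0.1, 0.5), seed=7,
    )
    geno, variants = sample_genotypes(cfg)
    return geno, variants


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
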