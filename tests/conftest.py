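import numpy as np
import pytest

from meiorec.config import SimConfig
from meiorec.pipeline import call_cohort
from meiorec.simulate import simulate_genotype_calls, simulate_pedigree


@pytest.fixture(scope="session")
def noise_free_f2():
    """A small noise-free F2 cross with events called — shared by the
    recovery and classification tests."""
    cfg = SimConfig(
        chrom_lengths=(8_000_000, 6_000_000),
        n_hotspots=600,
        exact_genotypes=True,
        base_error_rate=0.0,
        false_het_rate=0.0,
        false_hom_rate=0.0,
    )
    rng = np.random.default_rng(1)
    ped = simulate_pedigree(cfg, rng, through="F2")
    geno = simulate_genotype_calls(ped, cfg, rng)
    calls = call_cohort(geno, ped.snp_map, sample_ids=ped.samples("F2"))
    return cfg, ped, geno, calls


@pytest.fixture(scope="session")
def small_cross():
    """A tiny noisy cross (default rates) for filter/pipeline tests."""
    cfg = SimConfig(chrom_lengths=(4_000_000,), n_hotspots=300)
    rng = np.random.default_rng(7)
    ped = simulate_pedigree(cfg, rng, through="F2")
    geno = simulate_genotype_calls(ped, cfg, rng)
    return cfg, ped, geno
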