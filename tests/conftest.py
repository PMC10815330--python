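import numpy as np
import pytest

from haplopair.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def pair_cohort():
    """Cohort with one planted two-locus effect (per-allele OR 2), an
    r2=1 LD block, X-chromosome decoys and 1% missingness — the standard
    end-to-end fixture."""
    cfg = SimConfig(
        n_case=144, n_control=163, n_variants=120, maf_range=(0.1, 0.5),
        missing_rate=0.01, ld_blocks=((4, 1.0),),
        planted_pair_effects=((20, 30, 2.0),), n_x_decoys=4, seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def snp_cohort():
    """Large cohort with one planted single-SNP allelic effect (OR 2.5)."""
    cfg = SimConfig(
        n_case=2000, n_control=2000, n_variants=40, maf_range=(0.1, 0.5),
        missing_rate=0.0, planted_snp_effects=((5, 2.5),), seed=23,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effects, no missingness: pure sampling noise."""
    cfg = SimConfig(n_case=144, n_control=163, n_variants=200,
                    missing_rate=0.0, seed=5)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
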