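"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pytest

from bioage.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def null_sim():
    """2,000 samples, 300 independent SNPs, no causal effects, no APOE."""
    cfg = SimConfig(n_samples=2000, n_snps=300, causal_effects=(), apoe=None,
                    ld_block_size=1, seed=101)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def ld_sim():
    """1,500 samples, 120 SNPs in correlated LD blocks, APOE locus present."""
    cfg = SimConfig(n_samples=1500, n_snps=120, ld_block_size=6, ld_rho=0.7,
                    seed=202)
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
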