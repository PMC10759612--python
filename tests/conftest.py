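import numpy as np
import pytest

from larchgp.simulate import SimulationConfig, simulate_dataset


def tiny_config(**overrides) -> SimulationConfig:
    """A small but structurally complete trial (~90 trees, 120 SNPs)."""
    kwargs = dict(
        n_families=8,
        progeny_per_family=(9, 12),
        n_maternal_parents=8,
        n_pollen_parents=12,
        n_snps=120,
        n_blocks=3,
        missing_rate=0.0,
        seed=11,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_sim():
    return simulate_dataset(tiny_config())


@pytest.fixture(scope="session")
def mid_sim():
    """Medium trial used for model fits: ~200 trees, 600 SNPs, additive-rich."""
    cfg = SimulationConfig(
        n_families=20,
        progeny_per_family=(9, 12),
        n_maternal_parents=20,
        n_pollen_parents=30,
        n_snps=600,
        n_blocks=5,
        missing_rate=0.0,
        seed=7,
        variance_shares={
            "additive": 0.45,
            "dominance": 0.05,
            "imprinting": 0.05,
            "epistasis": 0.05,
            "plot": 0.05,
            "residual": 0.35,
        },
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
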