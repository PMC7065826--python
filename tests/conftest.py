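import numpy as np
import pytest

from mfqtl import (
    ChainConfig,
    IntervalGrid,
    QTLSpec,
    SimulationConfig,
    adjust_for_environment,
    impute_interval_genotypes,
    run_mcmc,
    simulate_dataset,
)


def three_family_config(**overrides):
    """Scaled-down study conditions: 3 families x 188 DH lines, a compact
    3-chromosome genome, 5-cM markers, one strong QTL at 50 cM of chr '2'."""
    defaults = dict(
        chromosomes=[("1", 100.0), ("2", 100.0), ("3", 100.0)],
        marker_spacing_cm=5.0,
        qtls=[QTLSpec("2", 50.0, 1.0, (1, 1, 1))],
        resid_sd=0.5,
        missing_rate=0.02,
        seed=7,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def single_qtl_data():
    cfg = three_family_config()
    observed, plots, truth = simulate_dataset(cfg)
    adjusted = adjust_for_environment(plots, cfg.trait)
    grid = IntervalGrid.from_map(truth["map"])
    ivgen = impute_interval_genotypes(observed, grid)
    return {
        "config": cfg,
        "observed": observed,
        "plots": plots,
        "truth": truth,
        "adjusted": adjusted,
        "grid": grid,
        "ivgen": ivgen,
    }


@pytest.fixture(scope="session")
def single_qtl_field(single_qtl_data):
    return run_mcmc(
        single_qtl_data["adjusted"],
        single_qtl_data["ivgen"],
        chain=ChainConfig(iterations=4000, burn_in=1000, thin=5, seed=3),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
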