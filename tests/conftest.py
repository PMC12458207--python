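import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from invgwa import (
    ArmSpec,
    InversionSpec,
    PanelConfig,
    TraitConfig,
    simulate_covariates,
    simulate_panel,
    simulate_traits,
)


@pytest.fixture(scope="session")
def inv_panel():
    """A 150-line panel with one diverged inversion on 2L and a clean arm 2R."""
    cfg = PanelConfig(
        n_lines=150,
        arms=[ArmSpec("2L", 30_000_000, 1500), ArmSpec("2R", 25_000_000, 1200)],
        inversions=[InversionSpec("2L", 5_000_000, 15_000_000, 0.30, 0.80, name="In(2L)t")],
        residual_het_rate=0.01,
        genotype_missing_rate=0.01,
        seed=11,
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def covariates(inv_panel):
    gm, _, _ = inv_panel
    return simulate_covariates(gm.line_ids, seed=12)


@pytest.fixture(scope="session")
def trait_panel(inv_panel, covariates):
    """Six traits: three with inversion + polygenic signal, three pure noise."""
    gm, inv, spans = inv_panel
    cfg = TraitConfig(
        n_traits=6,
        n_null_traits=3,
        inversion_effect_r2=0.15,
        n_causal_background=4,
        polygenic_h2=0.15,
        covariate_effect=0.25,
        phenotype_missing_rate=0.08,
        seed=13,
    )
    return simulate_traits(gm, inv, covariates.symbiont(gm.line_ids), cfg, spans=spans)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2029)
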