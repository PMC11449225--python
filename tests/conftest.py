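import numpy as np
import pytest

from syntelink.synthetic_data import (
    FamilyParams,
    SimulationConfig,
    simulate_dataset,
)


def quiet_family(**kw) -> FamilyParams:
    """Family with all stochastic rates zeroed unless overridden."""
    base = dict(
        n_orthogroups=2,
        root_copies_per_og=1,
        origin="root",
        tandem_dup_rate=0.0,
        dispersed_dup_rate=0.0,
        loss_rate=0.0,
        rearrangement_rate=0.0,
        retention_after_wgd=1.0,
    )
    base.update(kw)
    return FamilyParams(**base)


def quiet_config(**kw) -> SimulationConfig:
    """Small event-free simulation: genomes stay identical to the root."""
    base = dict(
        seed=7,
        n_species=6,
        chromosomes_per_species=2,
        background_genes_per_chromosome=40,
        family_a=quiet_family(n_orthogroups=4),
        family_b=quiet_family(n_orthogroups=3),
        background_shuffle_rate=0.0,
        background_retention_after_wgd=1.0,
        wgd_probability=0.0,
        detector_sensitivity={a: 1.0 for a in
                              ("OGxD1", "OGxD2", "MCLxD1", "MCLxD2")},
        detector_fp_rate=0.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def clean_dataset():
    """Event-free 6-species dataset with perfect detectors."""
    return simulate_dataset(quiet_config())


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default study conditions at 16 species (all event types active)."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
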