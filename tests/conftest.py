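import numpy as np
import pytest

from kmscreen import PlantedEffect, SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """Two small cohorts (GPL570 + GPL96) with one strong planted risk gene."""
    cfg = SimConfig(
        n_cohorts=2,
        samples_per_cohort=(80, 80),
        n_genes_total=40,
        n_shared_genes=30,
        planted_effects=(PlantedEffect("G0001", 0.5, 2.5, "both"),),
        seed=42,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """One cohort with no planted effects (expression independent of survival)."""
    cfg = SimConfig(
        n_cohorts=1,
        samples_per_cohort=(150,),
        n_genes_total=30,
        n_shared_genes=30,
        seed=7,
    )
    return simulate_study(cfg).cohorts[0]


@pytest.fixture
def toy_survival():
    """Six samples, all events, perfect separation at the 3/3 split."""
    time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    event = np.ones(6, dtype=int)
    group = np.array([False, False, False, True, True, True])
    return time, event, group
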