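import pytest

from phosite.digest import map_psm, MappedPsm
from phosite.io import ExperimentDesign, default_design
from phosite.simulate import SimulationConfig, simulate_psm_table


@pytest.fixture(scope="session")
def design() -> ExperimentDesign:
    return default_design()


@pytest.fixture(scope="session")
def small_run(design):
    """One modest synthetic experiment shared by read-only tests."""
    cfg = SimulationConfig(seed=11, protein_length=300, background_depth_mean=8.0)
    psms, truth = simulate_psm_table(cfg)
    mapped = [
        m for m in (map_psm(p, truth.protein) for p in psms)
        if isinstance(m, MappedPsm)
    ]
    return cfg, psms, truth, mapped
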