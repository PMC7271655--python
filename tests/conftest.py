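import pytest

from glycodiff import SimulationDesign
from glycodiff.pipeline import run_glyco_tmt
from glycodiff.simulate import simulate_dataset


@pytest.fixture(scope="session")
def small_glyco_design() -> SimulationDesign:
    return SimulationDesign(
        kind="glyco_tmt10",
        n_proteins=80,
        n_planted_per_isoform=12,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_glyco_dataset(small_glyco_design):
    return simulate_dataset(small_glyco_design)


@pytest.fixture(scope="session")
def default_glyco_run():
    """The standard study conditions: 300 proteins, 60 planted sites per
    isoform, effect ratio 0.2, noise sd 0.05 log10, seed 42."""
    return run_glyco_tmt(SimulationDesign(kind="glyco_tmt10"))
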