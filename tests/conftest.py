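import numpy as np
import pytest

from coexsim import TransmitterPanel, observed_panel, reconstruct_fixture


@pytest.fixture(scope="session")
def panel() -> TransmitterPanel:
    """The packaged observed panel (five neuropeptides + GABA, N=360)."""
    return observed_panel()


@pytest.fixture(scope="session")
def peptide_panel(panel) -> TransmitterPanel:
    return panel.subset(["TK", "FMRF", "Mas-AT", "MIP", "AST-A"])


@pytest.fixture(scope="session")
def constrained_peptide_panel(peptide_panel) -> TransmitterPanel:
    """Peptide panel restricted to the GABAergic population (~170 cells)."""
    return peptide_panel.with_population(170.0)


@pytest.fixture(scope="session")
def fixture_result():
    """The reconstructed per-cell fixture at the default pooled scale."""
    return reconstruct_fixture()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_panel() -> TransmitterPanel:
    """Two deterministic transmitters in a 10-cell population (forced overlap)."""
    return TransmitterPanel(
        transmitters=("A", "B"),
        count_mean=(10.0, 4.0),
        count_sd=(0.0, 0.0),
        population_mean=10.0,
    )
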