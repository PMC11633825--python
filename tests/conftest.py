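import pytest

from pkashift import SimulationSpec, make_temp_context, simulate


@pytest.fixture(scope="session")
def ctx():
    return make_temp_context(298.0)


@pytest.fixture(scope="session")
def noiseless_world():
    """Three-solvent synthetic world with zero noise and no systematic errors."""
    spec = SimulationSpec(
        n_species=30,
        acid_fraction=0.5,
        solvents={"acetonitrile": 10.0, "dmso": -6.0, "methanol": -0.5},
        noise_sd=0.0,
        seed=7,
    )
    return simulate(spec)


@pytest.fixture(scope="session")
def noisy_world():
    spec = SimulationSpec(
        n_species=50,
        acid_fraction=0.5,
        solvents={"acetonitrile": 10.0, "dmso": -6.0},
        noise_sd=0.5,
        seed=11,
    )
    return simulate(spec)
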