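import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_env():
    from antlobe.odor import OdorantEnvironment

    return OdorantEnvironment.from_matrices(
        b=np.array([[2.0, 0.5], [1.0, 3.0]]),
        d=np.array([[4.0, 1.0], [2.0, 6.0]]),
        receptor_labels=["Or59b", "Or7a"],
        odorant_labels=["A", "B"],
    )


@pytest.fixture(scope="session")
def planted_small():
    """Compact synthetic connectome for extraction tests (3 glomeruli, 40 LNs)."""
    from antlobe.synth import PlantedSpec, generate_connectome

    spec = PlantedSpec(
        glomeruli=("DA1", "DM4", "DL5"),
        n_ln=40,
        gloms_per_ln=(1, 3),
        n_weak_ln=4,
        seed=11,
    )
    return generate_connectome(spec)


@pytest.fixture(scope="session")
def planted_small_records(planted_small, tmp_path_factory):
    """The same connectome parsed back through the table reader."""
    from antlobe.motifs import read_tables

    d = tmp_path_factory.mktemp("tables")
    paths = planted_small.write(d)
    return read_tables(paths["synapses"], paths["neurons"])


@pytest.fixture(scope="session")
def tiny_glomerulus():
    """5 OSNs, 1 PN with high per-OSN convergence; sub-second simulations."""
    from antlobe.composer import build_glomerulus

    rng = np.random.default_rng(3)
    return build_glomerulus("DM4", 5, 1, rng.integers(70, 91, size=(5, 1)))


@pytest.fixture()
def tiny_circuit(tiny_glomerulus):
    from antlobe.composer import CircuitModel

    circuit = CircuitModel()
    circuit.add_glomerulus(tiny_glomerulus)
    return circuit


@pytest.fixture(scope="session")
def pair_circuit():
    from antlobe.composer import interconnect_pair
    from antlobe.synth import make_pair_fixture

    glom_a, glom_b, spec = make_pair_fixture()
    return interconnect_pair(glom_a, glom_b, spec)
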