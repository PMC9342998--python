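import numpy as np
import pytest

from patchkf.schemes import Edge, KineticScheme
from patchkf.simulate import NoiseParams, simulate_traceset


def two_state_scheme(k12=5.0, k21=50.0) -> KineticScheme:
    """Ligand-gated two-state toy: C1 -(k12*L)-> O2, O2 -(k21)-> C1."""
    return KineticScheme(
        n_states=2,
        edges=[Edge(1, 2, "k12", 1), Edge(2, 1, "k21", 0)],
        conducting={2: 1.0},
        bound_ligands={1: 0, 2: 1},
        default_rates={"k12": k12, "k21": k21},
        name="co_toy",
    )


@pytest.fixture(scope="session")
def toy2():
    return two_state_scheme()


@pytest.fixture(scope="session")
def toy2_traces(toy2):
    """Small cPCF dataset from the two-state toy (3 concentrations)."""
    return simulate_traceset(
        toy2,
        concentrations=[1.0, 4.0, 16.0],
        Nch=1000,
        noise=NoiseParams(lambda_b=0.375),
        seed=3,
        t_on=0.6,
        t_off=0.6,
        f_ana=250.0,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
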