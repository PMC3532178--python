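import numpy as np
import pytest

from sslna import ConservationLaw, Reaction, ReactionNetwork, Species
from sslna.models import EnzymeParams, GeneParams


@pytest.fixture(scope="session")
def birth_death():
    """0 -> S (k_in = 5), S -> 0 (k = 0.5): Poisson stationary law with
    mean concentration 10 at volume 100."""
    return ReactionNetwork(
        [Species("S", "slow", 10.0)],
        [Reaction({}, {"S": 1}, 5.0, name="in"),
         Reaction({"S": 1}, {}, 0.5, name="out")],
        volume=100.0,
    )


@pytest.fixture(scope="session")
def enzyme_params():
    """Headline enzyme parameter set: k1 = 5e-7, Theta = 1/2, volume 100."""
    return EnzymeParams()


@pytest.fixture(scope="session")
def enzyme_params_fast():
    """Cheaper simulation variant with k1 = 5e-3 (also a studied value)."""
    return EnzymeParams(k1=5e-3)


@pytest.fixture(scope="session")
def gene_params():
    """Feedback-circuit set with k3 = 1, k0 = 100, volume 100."""
    return GeneParams()


def random_enzyme_params(rng: np.random.Generator) -> EnzymeParams:
    return EnzymeParams(
        k1=10 ** rng.uniform(-7, -2),
        k2=10 ** rng.uniform(0, 4),
        km1=10 ** rng.uniform(0, 3),
        km2=10 ** rng.uniform(0, 3),
        k3=10 ** rng.uniform(-1, 1),
        k4=10 ** rng.uniform(-1, 1),
        EET=10 ** rng.uniform(-1, 1),
        omega=10 ** rng.uniform(1, 3),
    ).at_theta(rng.uniform(0.05, 0.95))


def random_gene_params(rng: np.random.Generator) -> GeneParams:
    return GeneParams(
        k0=10 ** rng.uniform(-1, 2.5),
        ks=10 ** rng.uniform(-1, 1),
        kdM=10 ** rng.uniform(-1, 1),
        k1=10 ** rng.uniform(-6, -3),
        k2=10 ** rng.uniform(1, 3),
        km1=10 ** rng.uniform(0, 2),
        km2=10 ** rng.uniform(0, 2),
        km3=10 ** rng.uniform(0, 2),
        k3=10 ** rng.uniform(-2, 1),
        k4=10 ** rng.uniform(-1, 1),
        GT=10 ** rng.uniform(-3, -1),
        ET=10 ** rng.uniform(-1, 1),
        omega=100.0,
    )
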