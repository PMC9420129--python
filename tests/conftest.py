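import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from otomap.core import Skeleton
from otomap.synthetic import (
    CircuitConfig,
    MaculaConfig,
    generate_circuit,
    generate_macula,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_tree(rng, n_nodes: int, scale: float = 5.0) -> Skeleton:
    """A random tree skeleton with distinct node positions."""
    xyz = [rng.normal(size=3) * scale]
    parent = [-1]
    for k in range(1, n_nodes):
        p = int(rng.integers(k))
        step = rng.normal(size=3)
        step *= (0.5 + rng.random() * scale) / np.linalg.norm(step)
        xyz.append(xyz[p] + step)
        parent.append(p)
    return Skeleton(np.arange(n_nodes), np.array(parent), np.asarray(xyz))


@pytest.fixture(scope="session")
def macula():
    """Default synthetic macula: 91 hair cells, von Mises noise kappa=20."""
    return generate_macula(MaculaConfig())


@pytest.fixture(scope="session")
def macula_noiseless():
    return generate_macula(MaculaConfig(noise_kappa=None))


@pytest.fixture(scope="session")
def circuit(macula):
    """Default synthetic circuit built on the default macula."""
    cells, truth = macula
    cells = {k: v for k, v in cells.items()}  # generate_circuit mutates ribbon counts
    return (cells, truth, *generate_circuit(cells, truth, CircuitConfig()))
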