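import numpy as np
import pytest

from limisim import LatticeSpec, SimulationParams


@pytest.fixture
def default_params() -> SimulationParams:
    """The source model's headline conditions (beta_N=100, beta_D=10)."""
    return SimulationParams()


@pytest.fixture
def small_params() -> SimulationParams:
    """A 6x6 field for brute-force oracle comparisons."""
    return SimulationParams(lattice=LatticeSpec(6, 6))


@pytest.fixture
def fast_params() -> SimulationParams:
    """Parameters whose pipeline converges in milliseconds.

    A small reporter capacity and half-saturation shrink the reporter
    scale so the derivative residual drops below tolerance quickly; the
    dynamics are otherwise the same model.  Used by sweep/IO/CLI tests
    where the subject is plumbing, not the equilibrium itself.
    """
    return SimulationParams(
        beta_R=1000.0, k_RS=300.0, dt=1e-3, max_steps=200_000,
        lattice=LatticeSpec(6, 6),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
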