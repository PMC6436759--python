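import numpy as np
import pytest

from gbjgsa.simulate import SimDesign, generate_study_resources


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def exchangeable(d: int, rho: float) -> np.ndarray:
    sig = np.full((d, d), rho)
    np.fill_diagonal(sig, 1.0)
    return sig


@pytest.fixture(scope="session")
def null_resources():
    """Small synthetic genome slice with no genetic effect (shared)."""
    return generate_study_resources(
        design=SimDesign(seed=7), n_genes=12, seed=7
    )


@pytest.fixture(scope="session")
def signal_resources():
    """Genome slice with three causal genes of strong effect (shared)."""
    return generate_study_resources(
        design=SimDesign(seed=11), n_genes=12, causal_genes=3, b=3,
        beta=0.25, seed=11
    )
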