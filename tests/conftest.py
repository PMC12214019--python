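import numpy as np
import pytest

from strandex.kinetics import (
    KineticScheme,
    StatePath,
    TransferRates,
    build_transfer_scheme,
)
from strandex.optics import ExcitationPattern, OpticsModel


@pytest.fixture
def two_state_scheme() -> KineticScheme:
    """A -> B at 1 s^-1, B absorbing."""
    q = np.array([[-1.0, 1.0], [0.0, 0.0]])
    return KineticScheme(
        ("A", "B"), q,
        fret_level={"A": 0.8, "B": 0.2},
        donor_count={"A": 1, "B": 1},
        acceptor_present={"A": True, "B": True},
        absorbing=frozenset({"B"}),
    )


@pytest.fixture
def transfer_rates() -> TransferRates:
    # spec-scale example: k_obs = 1e6 * 1e-7 * 1/(9+1) = 0.01 s^-1
    return TransferRates(k_on_compete=1e6, conc_compete=1e-7, k_fail=9.0, k_succ=1.0)


@pytest.fixture
def transfer_scheme(transfer_rates) -> KineticScheme:
    return build_transfer_scheme(transfer_rates, fret_bound=0.8, fret_free=0.2)


@pytest.fixture
def clean_optics() -> OpticsModel:
    """Noise-free, leak-free, background-free optics."""
    return OpticsModel(
        shot_noise=False, read_noise_sd=0.0, leakage=0.0,
        background_green=0.0, background_red=0.0, flow_background_step=0.0,
    )


@pytest.fixture
def green_pattern() -> ExcitationPattern:
    return ExcitationPattern(mode="continuous_green")


@pytest.fixture
def alex_pattern() -> ExcitationPattern:
    return ExcitationPattern(mode="alex")


def constant_path(scheme: KineticScheme, state: str, horizon: float) -> StatePath:
    return StatePath(
        np.array([0.0]), np.array([scheme.index(state)]), scheme.state_names, horizon
    )


@pytest.fixture
def make_constant_path():
    return constant_path
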