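import numpy as np
import pytest

from myostiff import ComponentSpec, PreparationState, StretchProtocol, paper_defaults
from myostiff.trace import ForceTrace


@pytest.fixture(scope="session")
def ladder():
    """The packaged disruption-ladder configuration (calibrated once)."""
    return paper_defaults()


@pytest.fixture
def single_component():
    """One component with E(0.2) = 1.0, viscous fraction 0.5, tau = 1 s."""
    return ComponentSpec(name="titin", elastic_poly=(0.0, 5.0, 0.0), viscous_fraction=0.5, tau=1.0)


@pytest.fixture
def one_step_protocol():
    return StretchProtocol(steps=((0.20, 10.0),), fs=1000.0)


@pytest.fixture
def cell_state():
    return PreparationState("cardiomyocyte", frozenset({"titin"}))


def make_relaxation_trace(f_ss, amp, tau, hold_s=10.0, fs=1000.0, strain=0.2, rng=None, sigma=0.0):
    """Closed-form exponential-relaxation window as a standalone trace."""
    n = int(hold_s * fs)
    t = np.arange(n) / fs
    force = f_ss + amp * np.exp(-t / tau)
    if sigma:
        force = force + sigma * (rng or np.random.default_rng(0)).standard_normal(n)
    return ForceTrace(t, np.full(n, strain), force)
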