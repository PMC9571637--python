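import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ehgfilt.signal import Signal
from ehgfilt.synthgen import (
    AlvAtom,
    RespirationSpec,
    SimulationScenario,
    compose_scenario,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def short_scenario():
    """A compact chirp scenario (600 s at 20 Hz) for filter-level tests."""
    atoms = [
        AlvAtom(f_atom=0.25, fract_bw=0.02 / 0.25, t_center=150),
        AlvAtom(f_atom=0.35, fract_bw=0.02 / 0.35, t_center=450),
    ]
    resp = RespirationSpec(kind="chirp", duration=600.0, seed=5)
    return SimulationScenario(
        atoms=atoms, respiration=resp, fs=20.0, duration=600.0, noise_std=0.05, seed=5,
        scenario_id="short",
    )


@pytest.fixture(scope="session")
def short_signals(short_scenario):
    return compose_scenario(short_scenario)


@pytest.fixture(scope="session")
def stationary_pair():
    """d = s + N + v with N a filtered white interference and the white
    driving process as reference; s is a slow tone orthogonal-ish to N."""
    rng = np.random.default_rng(42)
    n = 10_000
    x = rng.normal(size=n)
    h = np.array([0.9, -0.5])
    N = np.convolve(x, h)[:n]
    s = 0.5 * np.sin(2 * np.pi * 0.013 * np.arange(n))
    v = 0.02 * rng.normal(size=n)
    return {
        "desired": Signal(s + N + v, 20.0),
        "reference": Signal(x, 20.0),
        "clean": Signal(s, 20.0),
        "h": h,
    }
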