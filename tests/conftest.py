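import numpy as np
import pytest

from melophys.core import UniformSeries
from melophys.synthetic import Coupling, SimConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small uncoupled cohort shared by read-only tests."""
    cfg = SimConfig(
        n_pieces=2, piece_duration_s=120.0, n_listeners=6, playlist_length=3,
        annotation_counts={"Novel Melody": 2, "Return": 2}, seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def coupled_cohort():
    """Cohort with a sustained planted respiratory response to Novel Melody."""
    coupling = Coupling(
        "Novel Melody", "resp", amplitude=-0.15,
        latency_s=0.5, rise_s=0.3, decay_s=1000.0,
    )
    cfg = SimConfig(
        n_pieces=2, piece_duration_s=240.0, n_listeners=8, playlist_length=3,
        annotation_counts={"Novel Melody": 5}, couplings=(coupling,), seed=21,
    )
    return generate_cohort(cfg)


def step_series(n=300, at=150, height=2.0, noise_sd=0.0, rate=5.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n) * noise_sd
    x[at:] += height
    return UniformSeries("step", x, rate=rate)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
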