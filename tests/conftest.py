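import numpy as np
import pytest

from pfradiomics import synthdata
from pfradiomics.imageprep import PatellaMask, Radiograph


def make_ellipse_mask(shape=(128, 128), center=(64, 64), a=40.0, b=25.0,
                      power=2.0):
    """Binary ellipse/superellipse mask: vertical semi-axis a, horizontal b."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    return (np.abs((rr - center[0]) / a) ** power
            + np.abs((cc - center[1]) / b) ** power) <= 1.0


@pytest.fixture(scope="session")
def frozen_grid32():
    """Frozen 32x32 real-valued fixture for oracle-equivalence checks."""
    rng = np.random.default_rng(20240)
    base = rng.normal(0.0, 1.0, (32, 32))
    ramp = np.linspace(-1.0, 1.0, 32)[:, None] * np.linspace(0.5, 1.5, 32)[None, :]
    return base + 2.0 * ramp


@pytest.fixture(scope="session")
def small_cohort():
    """A small rendered cohort shared across tests (12 subjects)."""
    cfg = synthdata.SimulationConfig(n_subjects=12, seed=42)
    records, images, masks = synthdata.generate_cohort(cfg)
    return cfg, records, images, masks


@pytest.fixture()
def simple_subject():
    """One deterministic rendered subject."""
    cfg = synthdata.SimulationConfig(n_subjects=1, seed=7)
    records, images, masks = synthdata.generate_cohort(cfg)
    return images[0], masks[0]


@pytest.fixture()
def censored_fixture50():
    """n=50 censored survival fixture with a mildly informative score."""
    rng = np.random.default_rng(99)
    risk = rng.normal(0, 1, 50)
    time = rng.exponential(1.0, 50) / np.exp(0.8 * risk) * 20.0
    cens = rng.uniform(5.0, 60.0, 50)
    event = time <= cens
    obs = np.minimum(time, cens)
    score = risk + rng.normal(0, 0.5, 50)
    return score, obs, event.astype(int)
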