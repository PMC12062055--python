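import numpy as np
import pytest

from epidmd.io_panel import IncidencePanel
from epidmd.synthetic import GeneratorConfig, generate_panel


def sorted_eigs(eigs):
    """Deterministic eigenvalue ordering for multiset comparison."""
    return sorted(eigs, key=lambda z: (round(-abs(z), 9), round(np.angle(z), 9)))


def max_eig_discrepancy(a, b):
    return max(abs(x - y) for x, y in zip(sorted_eigs(a), sorted_eigs(b)))


def random_panel(rng, n, m, low=10.0, high=100.0):
    """Arbitrary positive panel with no special structure."""
    return IncidencePanel(
        counties=[f"{i + 1:05d}" for i in range(n)],
        years=list(range(2000, 2000 + m)),
        values=rng.uniform(low, high, (n, m)),
    )


def linear_trend_panel(rng, n=30, m=6):
    """Each county follows an exact linear trend a_i + d_i * t."""
    a = rng.uniform(50.0, 80.0, n)
    d = rng.uniform(-1.0, 1.0, n)
    t = np.arange(1, m + 1)
    values = a[:, None] + d[:, None] * t[None, :]
    panel = IncidencePanel(
        counties=[f"{i + 1:05d}" for i in range(n)],
        years=list(range(2000, 2000 + m)),
        values=values,
    )
    truth_next = a + d * (m + 1)
    return panel, truth_next


@pytest.fixture
def scalar_decay_panel():
    """Single county with geometric decay 100 * 0.9^(k-1)."""
    return IncidencePanel(
        counties=["21001"],
        years=[2000, 2001, 2002, 2003],
        values=np.array([[100.0, 90.0, 81.0, 72.9]]),
    )


@pytest.fixture
def noise_free_default():
    """Default synthetic conditions without observation noise, with truth."""
    cfg = GeneratorConfig(noise_sd=0.0)
    return generate_panel(cfg), cfg


@pytest.fixture
def small_noise_free():
    """Smaller noise-free panel for fast per-operation tests."""
    cfg = GeneratorConfig(n_counties=60, n_years=12, n_blocks=6,
                          high_block="02", low_block="05", noise_sd=0.0, seed=11)
    return generate_panel(cfg), cfg
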