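"""Shared fixtures; the expensive parameter-recovery runs are session-scoped."""

import numpy as np
import pytest

from permeapath.synthetic import (
    Landscape,
    LangevinConfig,
    plan_windows,
    sc_bilayer_landscape,
    simulate_window,
)

SPRING_K = 500.0


def window_seed(base: int, i: int) -> int:
    return int(np.random.SeedSequence([base, i]).generate_state(1)[0] % (2**31))


def flat_landscape(d0: float = 1e-3, z_max: float = 4.4) -> Landscape:
    return Landscape(
        g_of_z=lambda z: np.zeros_like(np.asarray(z, float)),
        d_of_z=lambda z: np.full_like(np.asarray(z, float), d0),
        z_min=0.0,
        z_max=z_max,
        name="flat",
    )


def simulate_campaign(landscape, n_samples, stride, dt, seed, equil=50_000,
                      spring_k=SPRING_K, spacing=0.2):
    windows = []
    for i, c in enumerate(plan_windows(landscape.z_min, landscape.z_max, spacing)):
        cfg = LangevinConfig(
            dt=dt,
            n_steps=n_samples * stride + equil,
            sample_stride=stride,
            equilibration_steps=equil,
            seed=window_seed(seed, i),
        )
        windows.append(simulate_window(landscape, c, spring_k, cfg))
    return windows


@pytest.fixture(scope="session")
def me5ala_recovery_windows():
    """23 umbrella windows, 1e5 samples each, on the Me-5ALA-like landscape.

    Sample spacing 8 ps so even the slow-diffusivity tail windows
    (IACT ~ 500 ps) are covered ~1500x by each window's duration.
    """
    return simulate_campaign(sc_bilayer_landscape("me5ala"),
                             n_samples=100_000, stride=80, dt=0.1, seed=7)


@pytest.fixture(scope="session")
def ala5_recovery_windows():
    """Lighter 5-ALA-like campaign (2e4 samples/window) for ordering checks."""
    return simulate_campaign(sc_bilayer_landscape("5ala"),
                             n_samples=20_000, stride=80, dt=0.1, seed=11)


@pytest.fixture(scope="session")
def ou_window():
    """A single 1e6-sample Ornstein-Uhlenbeck-like window (flat G, k=500)."""
    cfg = LangevinConfig(dt=0.01, n_steps=10_050_000, sample_stride=10,
                         equilibration_steps=50_000, seed=5)
    return simulate_window(flat_landscape(), 2.2, SPRING_K, cfg)
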