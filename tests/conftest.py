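"""Shared fixtures: whisker geometries, force profiles, and cached simulations."""

import numpy as np
import pytest

from whiskervib import (
    ContactConfig,
    ForceProfile,
    simulate_touch,
    standard_whisker,
)


@pytest.fixture(scope="session")
def geom():
    """Standard modeling whisker (5% trimmed, alpha = 430 rad/s)."""
    return standard_whisker()


@pytest.fixture(scope="session")
def geom_undamped():
    return standard_whisker(alpha=0.0)


@pytest.fixture(scope="session")
def contact06(geom):
    return ContactConfig.from_relative(geom, 0.6)


@pytest.fixture(scope="session")
def profile():
    """Standard touch force: F_max = 1 uN, t_f = 10 ms, tau = 0.1 ms, C = 0.5."""
    return ForceProfile.gaussian_smooth(1e-6)


@pytest.fixture(scope="session")
def touch06(geom, contact06, profile):
    """Full standard-touch simulation at c/L = 0.6 with 100 modes (shared)."""
    return simulate_touch(geom, contact06, profile, n_modes=100)


@pytest.fixture(scope="session")
def touch_small(geom, contact06, profile):
    """Cheap 20-mode simulation for tests that only need low modes."""
    return simulate_touch(geom, contact06, profile, n_modes=20)
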