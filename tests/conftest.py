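"""Shared fixtures: simulated spectra and the parameter-recovery grid."""

from __future__ import annotations

import numpy as np
import pytest

from cwdip.dipolar import DistanceModel, forward_model
from cwdip.fitting import FitOptions, fit_distance
from cwdip.simulate import (
    NitroxideSystem,
    default_axis,
    simulate_mobile,
    simulate_powder,
)


@pytest.fixture(scope="session")
def default_system() -> NitroxideSystem:
    return NitroxideSystem()


@pytest.fixture(scope="session")
def rigid_single(default_system) -> "FieldSpectrum":
    """Rigid-limit single-label powder spectrum on the 200 G sweep."""
    return simulate_powder(default_system, orientations=800, label="single")


@pytest.fixture(scope="session")
def rt_system() -> NitroxideSystem:
    """Room-temperature acquisition frequency (~9.65 GHz)."""
    return NitroxideSystem(mw_frequency=9.65)


@pytest.fixture(scope="session")
def rt_axis() -> np.ndarray:
    return default_axis(center=3437.0, sweep=100.0, n=1024)


@pytest.fixture(scope="session")
def mobile_reference(rt_system, rt_axis):
    """Fast-motion reference spectrum (order parameter 0.3)."""
    return simulate_mobile(rt_system, 0.3, rt_axis, orientations=800)


@pytest.fixture(scope="session")
def rigid_rt(rt_system, rt_axis):
    """Immobilized (rigid-limit) spectrum on the room-temperature axis."""
    return simulate_powder(rt_system, rt_axis, orientations=800,
                           temperature=295.0)


def _recovery_grid_models() -> list[DistanceModel]:
    """20 seeded distance models spanning the fit bounds (14 1-G + 6 2-G)."""
    rng = np.random.default_rng(42)
    models = []
    for _ in range(14):
        r = rng.uniform(0.85, 2.3)
        dr = rng.uniform(0.05, 1.5)
        f = rng.uniform(0.3, 0.9)
        models.append(DistanceModel.single(round(r, 3), round(dr, 3), round(f, 3)))
    for _ in range(6):
        r1 = rng.uniform(0.85, 1.05)
        dr1 = rng.uniform(0.05, 0.3)
        f1 = rng.uniform(0.15, 0.4)
        r2 = rng.uniform(1.35, 2.2)
        dr2 = rng.uniform(0.4, 1.5)
        f2 = rng.uniform(0.25, min(0.45, 0.9 - f1))
        models.append(
            DistanceModel.double(
                round(r1, 3), round(dr1, 3), round(f1, 3),
                round(r2, 3), round(dr2, 3), round(f2, 3),
            )
        )
    return models


@pytest.fixture(scope="session")
def recovery_grid(rigid_single):
    """Noiseless fits of the 20-model grid: list of (truth, fitted) pairs."""
    results = []
    for truth in _recovery_grid_models():
        double = forward_model(rigid_single, truth)
        n = len(truth.components)
        opts = FitOptions(n_gaussians=n, n_starts=4 if n == 1 else 8, seed=7)
        fit = fit_distance(double, rigid_single, opts)
        results.append((truth.sorted_by_r(), fit.model.sorted_by_r()))
    return results
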