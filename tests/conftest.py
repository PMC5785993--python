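"""Shared fixtures: the full-resolution study runs are expensive enough that
they are simulated once per session and shared across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from enafl.bioheat import (LaserSource, SimGrid, ThermalProperties,
                           TissueGeometry, simulate)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def props():
    return ThermalProperties()


@pytest.fixture(scope="session")
def thin_geometry():
    return TissueGeometry()


@pytest.fixture(scope="session")
def thick_geometry():
    return TissueGeometry().thick_variant()


@pytest.fixture(scope="session")
def source():
    return LaserSource()


@pytest.fixture(scope="session")
def thin_history(props, thin_geometry, source):
    """Default thin-slab (500 um) study run: 2 s heating + cooling to 10 s."""
    return simulate(props, thin_geometry, source, SimGrid.build(thin_geometry))


@pytest.fixture(scope="session")
def thick_history(props, thick_geometry, source):
    """Thick-tissue (5 mm) variant of the study run."""
    return simulate(props, thick_geometry, source,
                    SimGrid.build(thick_geometry))


@pytest.fixture(scope="session")
def thin_noperf_history(thin_geometry, source):
    """Thin slab with perfusion and metabolism off: the configuration of the
    energy-conservation and maximum-principle checks."""
    p = ThermalProperties(perfusion_rate=0.0, metabolic_heat=0.0)
    return simulate(p, thin_geometry, source, SimGrid.build(thin_geometry),
                    t_end=4.0)


@pytest.fixture(scope="session")
def thin_peak_refined(props, thin_geometry, source):
    """Peak temperature of the thin run on a mesh/time-step refined 2x,
    heated to t = 2 s only (the peak time)."""
    grid = SimGrid.build(thin_geometry).refined(2)
    hist = simulate(props, thin_geometry, source, grid, t_end=2.0)
    return float(max(s.T.max() for s in hist))


def coarse_grid(geometry, *, dt=0.02, t_end=3.0):
    """A deliberately coarse mesh for fast qualitative runs."""
    return SimGrid.build(geometry, dr_core=8.0e-6, core_radius=2.0e-4,
                         dz_surface=5.0e-6, radial_stretch=1.3,
                         axial_stretch=1.35, dt=dt, t_end=t_end)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
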