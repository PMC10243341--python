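"""Shared fixtures: small geometries and phantoms generated at test time."""

import warnings

import numpy as np
import pytest

from perfct.phantom import (
    LesionSpec,
    PhantomSpec,
    build_phantom,
    render_dynamic_hu,
)
from perfct.projector import ScanGeometry

# single-frame gradient warnings are expected in some small fixtures
warnings.filterwarnings("ignore", message="single-frame series")


@pytest.fixture(scope="session")
def small_geometry():
    """16x16 grid with enough rays to be overdetermined."""
    return ScanGeometry(n_views=48, n_detectors=32, grid_size=16)


@pytest.fixture(scope="session")
def desk_phantom():
    """Lesion-free 64x64 phantom at the full 50-frame, 1 s sampling."""
    spec = PhantomSpec(grid_size=64, n_frames=50, dt=1.0)
    labels = build_phantom(spec)
    series = render_dynamic_hu(labels, spec)
    return spec, labels, series


@pytest.fixture(scope="session")
def lesion_phantom():
    spec = PhantomSpec(grid_size=64, n_frames=50, dt=1.0, lesion=LesionSpec())
    labels = build_phantom(spec)
    series = render_dynamic_hu(labels, spec)
    return spec, labels, series


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
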