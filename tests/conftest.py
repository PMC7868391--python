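"""Shared fixtures: head models and lead fields built once per session."""

import numpy as np
import pytest

from ratesi import forward as fw
from ratesi import headmodel as hm


@pytest.fixture(scope="session")
def small_head():
    """Reduced ellipsoid model (~500 dipoles) for solver-level tests."""
    return hm.build_head_model(semi_axes=(5.0, 6.5, 4.0), voxel=1.0)


@pytest.fixture(scope="session")
def small_lf(small_head):
    return fw.compute_lead_field(small_head.mesh, small_head.montage,
                                 small_head.grid)


@pytest.fixture(scope="session")
def tiny_head():
    """Very small model (a few dozen dipoles) for oracle comparisons."""
    return hm.build_head_model(semi_axes=(4.0, 5.0, 3.5), voxel=1.0,
                               grid_spacing=2.0)


@pytest.fixture(scope="session")
def tiny_lf(tiny_head):
    return fw.compute_lead_field(tiny_head.mesh, tiny_head.montage,
                                 tiny_head.grid)


@pytest.fixture(scope="session")
def default_head():
    """Full-size rat model at 1 mm resolution (the pipeline default)."""
    return hm.build_head_model(voxel=1.0)


@pytest.fixture(scope="session")
def default_lf(default_head):
    return fw.compute_lead_field(default_head.mesh, default_head.montage,
                                 default_head.grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
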