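"""Shared fixtures: small phantoms, scans, and motion models.

Everything is generated programmatically at session scope so the expensive
pieces (numba compilation, phantom rasterization, tiny training runs) are
paid once.
"""

import numpy as np
import pytest

from stinr.config import ExperimentConfig
from stinr.phantom import AnatomyParams, build_reference_anatomy, \
    default_motion_basis
from stinr.runner import build_motion_model_for, simulate_scenario


@pytest.fixture(scope="session")
def params32():
    """Desk-scale anatomy on a 32^3 grid at 6 mm."""
    return AnatomyParams(grid_shape=(32, 32, 32), spacing=6.0)


@pytest.fixture(scope="session")
def anatomy32(params32):
    return build_reference_anatomy(params32)


@pytest.fixture(scope="session")
def basis32(params32):
    return default_motion_basis(params32)


def tiny_config(**kw):
    """A minutes-scale scenario configuration for end-to-end smoke tests."""
    defaults = dict(
        scenario="S1", n_frames=80, frame_rate=80 / 60.0,
        sim_shape=(32, 32, 32), sim_spacing=6.0,
        det_shape=(32, 32), pixel_pitch=(9.4, 9.4),
        opt_shape=(20, 20, 20), opt_spacing=9.6,
        stage_iters=(200, 150, 600), seed=0)
    defaults.update(kw)
    return ExperimentConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_s1_scan():
    cfg = tiny_config()
    return cfg, simulate_scenario(cfg)


@pytest.fixture(scope="session")
def tiny_s1_model(tiny_s1_scan):
    cfg, scan = tiny_s1_scan
    return build_motion_model_for(cfg, scan)
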