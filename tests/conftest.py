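import numpy as np
import pytest

from tomoopt.datamodel import (
    ImageGeometry,
    create_acquisition_geometry,
    default_image_geometry,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def ag2d():
    """Small 2D parallel-beam geometry, 30 angles over [0, 180)."""
    return create_acquisition_geometry(
        beam_type="parallel2D",
        angles=np.linspace(0.0, 180.0, 30, endpoint=False),
        pixel_num_h=32,
    )


@pytest.fixture
def ig2d(ag2d):
    return default_image_geometry(ag2d)


@pytest.fixture
def ag3d():
    """Steel-wire-like 3D geometry scaled down (angle, vertical, horizontal)."""
    return create_acquisition_geometry(
        beam_type="parallel3D",
        angles=np.linspace(0.0, 180.0, 13, endpoint=False),
        pixel_num_h=16,
        pixel_num_v=12,
    )


@pytest.fixture
def ig3d(ag3d):
    return default_image_geometry(ag3d)


@pytest.fixture
def steel_wire_ag():
    """The 91-projection, 160x135-detector configuration."""
    return create_acquisition_geometry(
        beam_type="parallel3D",
        angles=np.linspace(0.0, 180.0, 91, endpoint=True),
        pixel_num_h=160,
        pixel_num_v=135,
    )
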