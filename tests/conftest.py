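"""Shared fixtures: small, fast phantoms reused across the suite.

Unit tests run on a reduced raster/axial problem size (128 x 96 pixels,
93.75 um pitch, a few hundred sections); the acceptance suite exercises the
full 512 x 384 / 1,000-section scanner geometry where a criterion's
tolerance is stated in full-resolution pixels.
"""

from __future__ import annotations

import pytest

from poleprofile import (
    DiscTilt,
    build_surface,
    depth_map,
    locate_dpe,
    place_landmarks,
    render_enface,
)
from poleprofile.synthetic_eye import RenderParams

SMALL = RenderParams(nx=128, ny=96, n_sections=300, speckle_sd=0.0)
SMALL_NOISY = RenderParams(nx=128, ny=96, n_sections=300, speckle_sd=0.15)
# cohort phantoms have curved bases and deeper bumps: longer axial span
SMALL_COHORT = RenderParams(nx=128, ny=96, n_sections=800, speckle_sd=0.15)


@pytest.fixture(scope="session")
def small_params() -> RenderParams:
    return SMALL


@pytest.fixture(scope="session")
def bump_surface():
    """Flat-base phantom with a single 250-um bump at (0.5, -1.0) mm."""
    return build_surface(float("inf"), (0.5, -1.0), 250.0, 1.5)


@pytest.fixture(scope="session")
def tilted_landmarks(bump_surface):
    """Disc tilted 13 deg with the downhill azimuth at +30 deg (toward the
    inferotemporal fundus), disc-fovea angle 4 deg."""
    return place_landmarks(
        bump_surface,
        disc_offset_mm=4.6,
        disc_radius_mm=0.85,
        disc_fovea_angle_deg=4.0,
        tilt=DiscTilt(downhill_azimuth_deg=30.0, tilt_deg=13.0),
    )


@pytest.fixture(scope="session")
def small_volume(bump_surface, tilted_landmarks):
    return render_enface(bump_surface, SMALL, landmarks=tilted_landmarks)


@pytest.fixture(scope="session")
def small_depth(small_volume):
    return depth_map(small_volume)


@pytest.fixture(scope="session")
def small_dpe(small_volume, small_depth):
    return locate_dpe(small_volume, depth=small_depth)


@pytest.fixture(scope="session")
def noisy_volume(bump_surface, tilted_landmarks):
    return render_enface(bump_surface, SMALL_NOISY, seed=11, landmarks=tilted_landmarks)
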