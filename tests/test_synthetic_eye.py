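"""Phantom generator: surface truth, landmark geometry, rendering, cohorts."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest

from poleprofile import (
    DiscTilt,
    build_surface,
    place_landmarks,
    render_enface,
    rescan,
    simulate_truths,
)
from poleprofile.conventions import signed_angle_deg
from poleprofile.synthetic_eye import (
    CohortSpec,
    Dist,
    GroupSpec,
    PhantomParameterError,
    RenderParams,
    RenderRangeError,
    RescanSpec,
    default_cohort_spec,
    mirror_landmarks,
    mirror_volume,
    rendered_depth_um,
    simulate_cohort,
)
from conftest import SMALL, SMALL_COHORT, SMALL_NOISY


# --------------------------------------------------------------------------
# Surface
# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs",
    [
        {"bump_sigma_mm": 0.0},
        {"bump_sigma_mm": -1.0},
        {"base_radius_mm": 5.0},
        {"bump_amplitude_um": -10.0},
    ],
)
def test_surface_rejects_invalid_parameters(kwargs):
    good = dict(
        base_radius_mm=12.0, bump_center_mm=(0.0, 0.0), bump_amplitude_um=100.0,
        bump_sigma_mm=1.5,
    )
    with pytest.raises(PhantomParameterError):
        build_surface(**{**good, **kwargs})


def test_zero_amplitude_truth_is_base_tangency():
    s = build_surface(12.0, (2.0, 1.0), 0.0, 1.5)
    x, y, z = s.argmax_depth(step_mm=0.05)
    assert math.hypot(x, y) < 0.06  # tangency at the base center (fovea)
    assert z == pytest.approx(0.0, abs=1e-9)


def test_flat_base_truth_is_the_bump():
    s = build_surface(float("inf"), (0.0, -2.7), 200.0, 2.0)
    x, y, z = s.argmax_depth()
    assert (x, y) == pytest.approx((0.0, -2.7), abs=0.011)
    assert z == pytest.approx(200.0, abs=1e-6)


def test_curved_base_truth_matches_brute_force_grid():
    """Dense-grid argmax oracle on a 10-um grid, computed independently."""
    s = build_surface(12.0, (1.5, -2.0), 150.0, 1.5)
    xs = np.arange(-6.0, 6.0 + 0.005, 0.01)
    ys = np.arange(-4.5, 4.5 + 0.005, 0.01)
    X, Y = np.meshgrid(xs, ys)
    sag = (12.0 - np.sqrt(12.0**2 - (X**2 + Y**2))) * 1000.0
    Z = -sag + 150.0 * np.exp(-((X - 1.5) ** 2 + (Y + 2.0) ** 2) / (2 * 1.5**2))
    k = np.argmax(Z)
    x, y, z = s.argmax_depth()
    assert (x, y) == pytest.approx((X.flat[k], Y.flat[k]), abs=0.011)
    assert z == pytest.approx(Z.flat[k], abs=0.5)


# --------------------------------------------------------------------------
# Landmarks
# --------------------------------------------------------------------------


def test_disc_fovea_angle_reproduced_exactly(bump_surface):
    lm = place_landmarks(bump_surface, disc_fovea_angle_deg=6.4)
    assert lm.disc_fovea_angle_deg == pytest.approx(6.4, abs=1e-9)


def test_untilted_margin_is_level_on_flat_base():
    s = build_surface(float("inf"), (0.0, 0.0), 0.0, 1.0)
    lm = place_landmarks(s, tilt=None)
    assert np.allclose(lm.disc_margin[:, 2], lm.disc_margin[0, 2])
    assert lm.tilt_deg == 0.0


def test_tilted_margin_depth_range_matches_plane_geometry():
    """A circle in a plane tilted by theta spans 2 r sin(theta) in depth."""
    s = build_surface(float("inf"), (0.0, 0.0), 0.0, 1.0)
    r, theta = 0.85, 10.0
    lm = place_landmarks(s, disc_radius_mm=r, tilt=DiscTilt(20.0, theta))
    z = lm.disc_margin[:, 2]
    expected = 2000.0 * r * math.sin(math.radians(theta))
    assert z.max() - z.min() == pytest.approx(expected, rel=1e-3)
    # downhill-side margin is the deep side
    u = np.asarray(lm.tilt_downhill)
    proj = (lm.disc_margin[:, :2] - np.asarray(lm.disc_center_mm)) @ u
    assert np.corrcoef(proj, z)[0, 1] > 0.999


def test_disc_overlapping_fovea_rejected(bump_surface):
    with pytest.raises(PhantomParameterError):
        place_landmarks(bump_surface, disc_offset_mm=0.5, disc_radius_mm=0.85)


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------


def test_flat_surface_sections_are_uniform_within_layers():
    s = build_surface(float("inf"), (0.0, 0.0), 0.0, 1.0)
    vol = render_enface(s, SMALL)
    per_section_spread = vol.intensities.max(axis=(1, 2)) - vol.intensities.min(axis=(1, 2))
    assert (per_section_spread == 0).all()
    # the deepest band section is the same for every pixel
    band_val = vol.intensities.max()
    has_band = (vol.intensities == band_val).any(axis=(1, 2))
    deepest = np.nonzero(has_band)[0].max()
    assert (vol.intensities[deepest] == band_val).all()


def test_last_band_section_matches_analytic_level_set(bump_surface):
    vol = render_enface(bump_surface, SMALL)
    band_val = vol.intensities.max()
    has_band = (vol.intensities == band_val).any(axis=(1, 2))
    deepest = int(np.nonzero(has_band)[0].max())
    island = vol.intensities[deepest] == band_val
    zr, _ = rendered_depth_um(bump_surface, SMALL)
    expected = np.rint(zr / SMALL.section_pitch_um).astype(int) == deepest
    assert (island == expected).all()


def test_render_deterministic_under_seed(bump_surface):
    v1 = render_enface(bump_surface, SMALL_NOISY, seed=3)
    v2 = render_enface(bump_surface, SMALL_NOISY, seed=3)
    assert np.array_equal(v1.intensities, v2.intensities)
    v3 = render_enface(bump_surface, SMALL_NOISY, seed=4)
    assert not np.array_equal(v1.intensities, v3.intensities)


def test_render_range_error_names_first_pixel():
    deep = build_surface(float("inf"), (0.0, 0.0), 5000.0, 2.0)
    with pytest.raises(RenderRangeError, match=r"pixel \(row=\d+, col=\d+"):
        render_enface(deep, SMALL)


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------


def _degenerate_spec() -> CohortSpec:
    g = GroupSpec(
        name="myopic",
        weight=1.0,
        axial_length_mm=Dist(26.0, 0.0),
        se_diopter=Dist(-4.0, 0.0),
        age_yr=Dist(45.0, 0.0),
        rnfl_um=Dist(95.0, 0.0),
        cct_um=Dist(540.0, 0.0),
        vf_md_db=Dist(-1.0, 0.0),
        right_eye_fraction=1.0,
        male_fraction=1.0,
        category_weights={"inferior": 1.0},
        bump_amplitude_um=Dist(250.0, 0.0),
        bump_sigma_mm=Dist(1.5, 0.0),
        base_radius_mm=Dist(60.0, 0.0),
        disc_offset_mm=Dist(4.6, 0.0),
        disc_radius_mm=Dist(0.85, 0.0),
        disc_fovea_angle_deg=Dist(7.0, 0.0),
        tilt_deg=Dist(10.0, 0.0),
        tilt_azimuth_jitter_sd_deg=0.0,
    )
    return CohortSpec(groups=(g,), render=SMALL)


def test_zero_sd_cohort_reproduces_spec_means_exactly():
    truth = simulate_truths(_degenerate_spec(), 1, seed=0)[0]
    assert truth.covariates["axial_length_mm"] == 26.0
    assert truth.covariates["age_yr"] == 45.0
    assert truth.surface.bump_amplitude_um == 250.0
    assert truth.landmarks.tilt_deg == 10.0
    assert truth.laterality == "right"


def test_inferior_bumps_give_positive_disc_dpe_angles():
    truths = simulate_truths(_degenerate_spec(), 8, seed=1)
    angles = [
        signed_angle_deg(t.landmarks.disc_center_mm, t.true_dpe_mm) for t in truths
    ]
    assert np.mean(angles) > 0
    assert min(angles) > 0  # every planted-inferior DPE sits inferior


def test_cohort_group_counts_40_125():
    spec = default_cohort_spec(SMALL)
    truths = simulate_truths(spec, 165, seed=2)
    groups = [t.group for t in truths]
    assert groups.count("emmetropic") == 40
    assert groups.count("myopic") == 125
    for t in truths:
        assert t.covariates["axial_length_mm"] <= 30.0


def test_axial_length_exclusion_resamples_over_30mm():
    g = replace(
        _degenerate_spec().groups[0], axial_length_mm=Dist(29.5, 1.5, 24.01, math.inf)
    )
    spec = CohortSpec(groups=(g,), render=SMALL)
    truths = simulate_truths(spec, 12, seed=3)
    assert all(t.covariates["axial_length_mm"] <= 30.0 for t in truths)


def test_simulated_cohort_yields_left_eyes_mirrored():
    spec = default_cohort_spec(SMALL_COHORT)
    for sim in simulate_cohort(spec, 6, seed=4):
        assert sim.truth.laterality in ("right", "left")
        assert sim.volume.laterality == sim.truth.laterality
        assert sim.scan_landmarks.laterality == sim.truth.laterality
        if sim.truth.laterality == "left":
            # as-scanned landmarks are the mirror of the canonical truth
            assert sim.scan_landmarks.fovea_mm[0] == -sim.truth.landmarks.fovea_mm[0]


# --------------------------------------------------------------------------
# Mirroring
# --------------------------------------------------------------------------


def test_mirror_round_trip_is_identity(tilted_landmarks, small_volume):
    lm2 = mirror_landmarks(mirror_landmarks(tilted_landmarks))
    assert np.allclose(lm2.disc_margin, tilted_landmarks.disc_margin, atol=1e-12)
    assert lm2.fovea_mm == tilted_landmarks.fovea_mm
    assert lm2.laterality == tilted_landmarks.laterality
    v2 = mirror_volume(mirror_volume(small_volume))
    assert np.array_equal(v2.intensities, small_volume.intensities)
    assert v2.origin_mm == small_volume.origin_mm


def test_mirroring_preserves_signed_truth_angles():
    """Left-format storage then right-format ingestion leaves the signed
    disc-fovea angle unchanged (all truth angles are defined canonically)."""
    s = build_surface(float("inf"), (0.8, -1.2), 200.0, 1.5)
    lm = place_landmarks(s, disc_fovea_angle_deg=5.5, tilt=DiscTilt(25.0, 12.0))
    back = mirror_landmarks(mirror_landmarks(lm))
    assert back.disc_fovea_angle_deg == pytest.approx(lm.disc_fovea_angle_deg, abs=1e-12)


# --------------------------------------------------------------------------
# Re-scans
# --------------------------------------------------------------------------


def _small_truth(render=SMALL, **overrides):
    from poleprofile.synthetic_eye import make_eye_truth

    s = build_surface(float("inf"), (0.5, -1.0), 250.0, 1.5)
    lm = place_landmarks(s, tilt=DiscTilt(30.0, 13.0))
    cov = {"axial_length_mm": 26.0, "se_diopter": -4.0}
    return make_eye_truth("eye000", "myopic", "right", s, lm, render, cov)


def test_rescan_identity_without_jitter_or_noise(small_volume):
    truth = _small_truth()
    again = rescan(truth, RescanSpec(fixation_sd_mm=0.0), seed=9)
    assert np.array_equal(again.volume.intensities, small_volume.intensities)
    assert again.offset_mm == (0.0, 0.0)


def test_rescan_with_jitter_shifts_detected_dpe():
    from poleprofile import locate_dpe

    truth = _small_truth()
    scan = rescan(truth, RescanSpec(fixation_sd_mm=0.1), seed=21)
    dpe = locate_dpe(scan.volume)
    dx = dpe.center_mm[0] - 0.5
    dy = dpe.center_mm[1] - (-1.0)
    tol = 1.5 * SMALL.lateral_pitch_mm
    assert dx == pytest.approx(scan.offset_mm[0], abs=tol)
    assert dy == pytest.approx(scan.offset_mm[1], abs=tol)
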