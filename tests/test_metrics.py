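"""Flow-profile metric tests: trivial closed forms, independent
double-loop oracles, and invariance properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vavr import metrics
from vavr.errors import UndefinedMetricError
from vavr.plane import VelocityPlane
from vavr.synthetic import JetParams, make_jet_plane


# ----------------------------------------------------------------------
# independent brute-force oracles (plain Python loops, no numpy reductions)
# ----------------------------------------------------------------------

def oracle_nfd(plane, weighted=True):
    n = sx = sy = 0.0
    cx = cy = 0.0
    for i in range(plane.x.size):
        if plane.mask[i]:
            n += 1
            cx += plane.x[i]
            cy += plane.y[i]
    cx /= n
    cy /= n
    diameter = 2.0 * math.sqrt(n * plane.spacing ** 2 / math.pi)
    wsum = 0.0
    for i in range(plane.x.size):
        if plane.mask[i] and plane.vz[i] > 0:
            w = plane.vz[i] if weighted else 1.0
            sx += w * plane.x[i]
            sy += w * plane.y[i]
            wsum += w
    fx, fy = sx / wsum, sy / wsum
    return math.hypot(fx - cx, fy - cy) / diameter


def oracle_wpd(plane):
    total = n = 0.0
    for i in range(plane.x.size):
        if not plane.mask[i]:
            continue
        through = abs(plane.vz[i])
        inplane = math.hypot(plane.vx[i], plane.vy[i])
        if through + inplane == 0:
            continue
        total += through / (through + inplane)
        n += 1
    return total / n


def oracle_angle(plane):
    total = n = 0.0
    for i in range(plane.x.size):
        if not plane.mask[i]:
            continue
        speed = math.sqrt(plane.vx[i] ** 2 + plane.vy[i] ** 2
                          + plane.vz[i] ** 2)
        if speed == 0:
            continue
        total += math.degrees(math.acos(max(-1.0, min(1.0,
                                                      plane.vz[i] / speed))))
        n += 1
    return total / n


def _plane_from_mask(mask2d, vx, vy, vz, spacing=1.0):
    ny, nx = mask2d.shape
    xg, yg = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing)
    m = mask2d.ravel()
    return VelocityPlane(x=xg.ravel(), y=yg.ravel(),
                         vx=np.where(m, vx.ravel(), 0.0),
                         vy=np.where(m, vy.ravel(), 0.0),
                         vz=np.where(m, vz.ravel(), 0.0),
                         mask=m, spacing=spacing)


# ----------------------------------------------------------------------
# lumen geometry
# ----------------------------------------------------------------------

class TestLumenGeometry:
    def test_disk(self):
        plane = make_jet_plane(JetParams(lumen_radius=10, grid_spacing=0.25))
        centroid, diameter = metrics.lumen_geometry(plane)
        np.testing.assert_allclose(centroid, [0.0, 0.0], atol=1e-12)
        assert abs(diameter - 20.0) < 0.25  # within one grid cell

    def test_translation_equivariance(self):
        plane = make_jet_plane(JetParams(lumen_radius=10, grid_spacing=0.5))
        c0, d0 = metrics.lumen_geometry(plane)
        shifted = VelocityPlane(x=plane.x + 3.0, y=plane.y, vx=plane.vx,
                                vy=plane.vy, vz=plane.vz, mask=plane.mask,
                                spacing=plane.spacing)
        c1, d1 = metrics.lumen_geometry(shifted)
        np.testing.assert_allclose(c1, c0 + np.array([3.0, 0.0]), atol=1e-12)
        assert d1 == d0

    def test_ellipse_equivalent_diameter(self):
        # semi-axes 10 x 5 mm -> area 50*pi -> diameter 2*sqrt(50)
        s = 0.05
        ax = np.arange(-11, 11, s)
        xg, yg = np.meshgrid(ax, ax)
        mask = (xg / 10.0) ** 2 + (yg / 5.0) ** 2 <= 1.0
        z = np.zeros_like(xg)
        plane = _plane_from_mask(mask, z, z, np.ones_like(xg), spacing=s)
        plane.x, plane.y = xg.ravel(), yg.ravel()
        _, diameter = metrics.lumen_geometry(plane)
        assert abs(diameter - 2.0 * math.sqrt(50.0)) < 0.02


# ----------------------------------------------------------------------
# NFD
# ----------------------------------------------------------------------

class TestNfd:
    def test_centered_jet_is_zero(self):
        plane = make_jet_plane(JetParams(jet_center_offset=(0, 0)))
        assert metrics.nfd(plane) == pytest.approx(0.0, abs=1e-12)

    def test_offset_plug_quarter_diameter(self):
        plane = make_jet_plane(JetParams(lumen_radius=10, grid_spacing=0.25,
                                         jet_center_offset=(5, 0),
                                         jet_radius=4))
        assert metrics.nfd(plane) == pytest.approx(0.25, abs=1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        plane = make_jet_plane(JetParams(
            lumen_radius=8, grid_spacing=0.8, jet_center_offset=(2, -1),
            jet_radius=3, tilt_deg=20, swirl_strength=0.4,
            retrograde_fraction=0.1, noise_sd=0.2, seed=seed))
        assert metrics.nfd(plane) == pytest.approx(oracle_nfd(plane),
                                                   abs=1e-12)
        assert metrics.nfd(plane, weighted=False) == pytest.approx(
            oracle_nfd(plane, weighted=False), abs=1e-12)

    def test_fully_retrograde_raises(self):
        plane = make_jet_plane(JetParams())
        plane.vz[plane.mask] = -1.0
        with pytest.raises(UndefinedMetricError):
            metrics.nfd(plane)

    def test_scale_invariance(self):
        plane = make_jet_plane(JetParams(jet_center_offset=(2, 1),
                                         jet_radius=3, noise_sd=0.1, seed=5))
        base = metrics.nfd(plane)
        plane.vx *= 7.0
        plane.vy *= 7.0
        plane.vz *= 7.0
        assert metrics.nfd(plane) == pytest.approx(base, rel=1e-12)

    def test_translation_invariance(self):
        plane = make_jet_plane(JetParams(jet_center_offset=(2, 1),
                                         jet_radius=3))
        base = metrics.nfd(plane)
        plane.x += 17.3
        plane.y -= 4.1
        assert metrics.nfd(plane) == pytest.approx(base, rel=1e-12)


# ----------------------------------------------------------------------
# WPD
# ----------------------------------------------------------------------

class TestWpd:
    def test_pure_axial_is_one(self):
        plane = make_jet_plane(JetParams(jet_radius=12.5))
        assert metrics.wpd(plane) == 1.0

    def test_pure_inplane_is_zero(self):
        plane = make_jet_plane(JetParams(jet_radius=12.5))
        plane.vx[plane.mask] = 1.0
        plane.vz[:] = 0.0
        assert metrics.wpd(plane) == 0.0

    def test_equal_components_half(self):
        plane = make_jet_plane(JetParams(jet_radius=12.5, peak_velocity=1.0))
        plane.vx[plane.mask] = 1.0  # |inplane| == |through| everywhere
        assert metrics.wpd(plane) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_brute_force_oracle(self, seed):
        plane = make_jet_plane(JetParams(
            lumen_radius=8, grid_spacing=0.8, jet_center_offset=(-1, 2),
            jet_radius=3, swirl_strength=0.6, noise_sd=0.15, seed=seed))
        assert metrics.wpd(plane) == pytest.approx(oracle_wpd(plane),
                                                   abs=1e-12)

    def test_monotone_in_swirl(self):
        values = [metrics.wpd(make_jet_plane(JetParams(
            jet_radius=12.5, swirl_strength=s))) for s in (0.0, 0.2, 0.5, 1.0)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_all_zero_raises(self):
        plane = make_jet_plane(JetParams(peak_velocity=0.0))
        with pytest.raises(UndefinedMetricError):
            metrics.wpd(plane)


# ----------------------------------------------------------------------
# flow angle
# ----------------------------------------------------------------------

class TestFlowAngle:
    def test_pure_axial_is_zero(self):
        plane = make_jet_plane(JetParams(jet_radius=12.5))
        assert metrics.flow_angle(plane) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("tilt", [10.0, 30.0, 60.0])
    def test_uniform_tilt(self, tilt):
        plane = make_jet_plane(JetParams(jet_radius=12.5, tilt_deg=tilt))
        assert metrics.flow_angle(plane) == pytest.approx(tilt, abs=1e-9)

    def test_matches_brute_force_oracle(self):
        plane = make_jet_plane(JetParams(
            lumen_radius=8, grid_spacing=0.8, jet_radius=3, tilt_deg=25,
            swirl_strength=0.5, retrograde_fraction=0.2, noise_sd=0.1,
            seed=11))
        assert metrics.flow_angle(plane) == pytest.approx(
            oracle_angle(plane), abs=1e-9)

    def test_zero_angle_iff_wpd_one(self):
        plane = make_jet_plane(JetParams(jet_radius=12.5))
        assert metrics.flow_angle(plane) == pytest.approx(0.0, abs=1e-12)
        assert metrics.wpd(plane) == 1.0
        tilted = make_jet_plane(JetParams(jet_radius=12.5, tilt_deg=5))
        assert metrics.flow_angle(tilted) > 0
        assert metrics.wpd(tilted) < 1

    def test_retrograde_exceeds_ninety(self):
        plane = make_jet_plane(JetParams(jet_radius=12.5))
        plane.vz[plane.mask] = -1.0
        assert metrics.flow_angle(plane) == pytest.approx(180.0, abs=1e-9)


# ----------------------------------------------------------------------
# vmax
# ----------------------------------------------------------------------

class TestVmax:
    def test_plug_peak(self):
        plane = make_jet_plane(JetParams(peak_velocity=1.9))
        assert metrics.vmax(plane) == pytest.approx(1.9)

    def test_all_zero_field(self):
        plane = make_jet_plane(JetParams(peak_velocity=0.0))
        assert metrics.vmax(plane) == 0.0

    def test_tilted_magnitude(self):
        tilt = 30.0
        plane = make_jet_plane(JetParams(peak_velocity=1.5, tilt_deg=tilt,
                                         jet_radius=12.5))
        assert metrics.vmax(plane) == pytest.approx(
            1.5 / math.cos(math.radians(tilt)), rel=1e-12)


# ----------------------------------------------------------------------
# scaling invariance as a property over random fields
# ----------------------------------------------------------------------

@settings(max_examples=25, deadline=None)
@given(scale=st.floats(min_value=1e-3, max_value=1e3),
       seed=st.integers(min_value=0, max_value=10_000))
def test_wpd_angle_scale_invariant(scale, seed):
    plane = make_jet_plane(JetParams(lumen_radius=6, grid_spacing=0.6,
                                     jet_radius=3, swirl_strength=0.3,
                                     noise_sd=0.1, seed=seed))
    w0, a0 = metrics.wpd(plane), metrics.flow_angle(plane)
    plane.vx *= scale
    plane.vy *= scale
    plane.vz *= scale
    assert metrics.wpd(plane) == pytest.approx(w0, rel=1e-9)
    assert metrics.flow_angle(plane) == pytest.approx(a0, rel=1e-9)


def test_grid_refinement_reduces_error():
    """Metrics at half spacing sit closer to the analytic values."""
    analytic = 5.0 / 20.0
    errs = []
    for spacing in (1.0, 0.5):
        plane = make_jet_plane(JetParams(lumen_radius=10, grid_spacing=spacing,
                                         jet_center_offset=(5, 0),
                                         jet_radius=4))
        errs.append(abs(metrics.nfd(plane) - analytic))
    assert errs[1] < errs[0]
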