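"""Geometric measurements: bending angle, in-plane footprint, height,
ring diameter, state deltas."""

import itertools

import numpy as np
import pytest

from mscgate.errors import ConventionError, InsufficientDataError, SelectionError
from mscgate.geometry import (
    GeometryProfile,
    compare_states,
    inplane_radius_area,
    measure_geometry,
    midplane_bending_angle,
    ring_diameter,
    tmd_height,
)
from mscgate.structio import MembraneSlab, _rotation_about
from mscgate.synthetic import ToyChannelSpec, make_toy_channel

from conftest import simple_structure


def toy_with_slab(**kwargs):
    s, truth = make_toy_channel(ToyChannelSpec(**kwargs))
    return s, truth, MembraneSlab(*truth.tm_slab)


class TestBendingAngle:
    @pytest.mark.parametrize("angle", [0.0, 10.0, 20.0, 30.0, 40.0])
    def test_cone_angle_recovery(self, angle):
        """Generator cone angles are recovered within 2 degrees under
        0.3 A coordinate jitter."""
        s, truth, slab = toy_with_slab(
            cone_angle=angle, jitter_sd=0.3, seed=int(angle)
        )
        measured = midplane_bending_angle(s, slab)
        assert abs(measured - angle) <= 2.0

    def test_flat_bundle_within_one_degree(self):
        s, _, slab = toy_with_slab(cone_angle=0.0, jitter_sd=0.2, seed=1)
        assert midplane_bending_angle(s, slab) <= 1.0

    def test_monotone_in_generator_angle(self):
        """Steeper generated cones measure strictly steeper."""
        measured = []
        for angle in (5.0, 15.0, 25.0, 35.0):
            s, _, slab = toy_with_slab(cone_angle=angle, jitter_sd=0.3, seed=42)
            measured.append(midplane_bending_angle(s, slab))
        assert all(b > a for a, b in zip(measured, measured[1:]))

    def test_invariant_under_z_rotation_and_translation(self):
        s, _, slab = toy_with_slab(cone_angle=25.0, jitter_sd=0.2, seed=3)
        ref = midplane_bending_angle(s, slab)
        rot = _rotation_about(np.array([0.0, 0.0, 1.0]), 0.83)
        rotated = s.transformed(rot)
        assert abs(midplane_bending_angle(rotated, slab) - ref) < 1e-9
        shifted = s.transformed(np.eye(3), np.array([0.0, 0.0, 10.0]))
        shifted_slab = MembraneSlab(slab.z_min + 10.0, slab.z_max + 10.0)
        assert abs(midplane_bending_angle(shifted, shifted_slab) - ref) < 1e-9

    def test_too_few_points_raises(self):
        s = simple_structure(np.random.default_rng(0).normal(size=(6, 3)))
        with pytest.raises(InsufficientDataError):
            midplane_bending_angle(s, MembraneSlab(-20, 20))


def cylinder_structure(radius, n_phi=120, z_levels=(-8, -4, 0, 4, 8)):
    phis = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    pts = [
        (radius * np.cos(p), radius * np.sin(p), z)
        for z, p in itertools.product(z_levels, phis)
    ]
    return simple_structure(np.array(pts))


class TestInplaneArea:
    def test_cylinder_analytic_area(self):
        """A 40 A cylinder has hull area ~ pi * 4^2 = 50.3 nm2, R ~ 4 nm."""
        s = cylinder_structure(40.0)
        R, A = inplane_radius_area(s, MembraneSlab(-10, 10))
        assert A == pytest.approx(np.pi * 16.0, rel=0.01)
        assert R == pytest.approx(4.0, abs=0.02)

    def test_dilation_area_change(self):
        """Dilating the cylinder by 5 A adds ~ pi(4.5^2 - 4^2) = 13.4 nm2."""
        slab = MembraneSlab(-10, 10)
        _, a0 = inplane_radius_area(cylinder_structure(40.0), slab)
        _, a1 = inplane_radius_area(cylinder_structure(45.0), slab)
        assert a1 - a0 == pytest.approx(np.pi * (4.5**2 - 4.0**2), rel=0.01)

    def test_hull_bounds_any_inscribed_triangle(self):
        """Brute force: the hull area is >= the area of every triangle of
        projected points."""
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(25, 3)) * np.array([12.0, 9.0, 4.0])
        s = simple_structure(pts)
        _, hull_area = inplane_radius_area(s, MembraneSlab(-20, 20))
        xy = pts[:, :2]
        best = 0.0
        for i, j, k in itertools.combinations(range(len(xy)), 3):
            u, v = xy[j] - xy[i], xy[k] - xy[i]
            best = max(best, 0.5 * abs(u[0] * v[1] - u[1] * v[0]))
        assert hull_area * 100.0 >= best - 1e-9  # hull in nm2, triangles in A2

    def test_hull_radius_recovery(self):
        """Measured footprint radius matches generator truth within 0.2 nm."""
        for angle in (0.0, 20.0, 40.0):
            s, truth, slab = toy_with_slab(
                cone_angle=angle, jitter_sd=0.3, seed=int(angle) + 50
            )
            R, _ = inplane_radius_area(s, slab)
            assert abs(R - truth.true_hull_radius_nm) <= 0.2

    def test_empty_band_raises(self):
        s = cylinder_structure(40.0)  # atoms only at z in {-8,-4,0,4,8}
        with pytest.raises(InsufficientDataError):
            inplane_radius_area(s, MembraneSlab(-50.0, 30.0), band=0.5)


class TestHeight:
    def test_known_span_recovered(self):
        """A flat 60 A bundle measures 60 +/- 2 A."""
        s, _, _ = toy_with_slab(
            cone_angle=0.0, tm_span=60.0, periplasmic_cap=False, seed=2
        )
        assert tmd_height(s) == pytest.approx(60.0, abs=2.0)

    def test_translation_invariance(self):
        s, _, _ = toy_with_slab(cone_angle=20.0, seed=3)
        h0 = tmd_height(s)
        shifted = s.transformed(np.eye(3), np.array([0.0, 0.0, 10.0]))
        assert tmd_height(shifted) == pytest.approx(h0, abs=1e-9)

    def test_robust_to_single_outlier(self):
        s, _, _ = toy_with_slab(cone_angle=0.0, tm_span=60.0, periplasmic_cap=False, seed=2)
        h0 = tmd_height(s)
        out = s.copy()
        out.positions = np.vstack([out.positions, [0.0, 0.0, 500.0]])
        for arr_name in ("atom_names", "elements", "residue_names", "chain_ids"):
            setattr(out, arr_name, np.append(getattr(out, arr_name), "X"))
        out.residue_numbers = np.append(out.residue_numbers, 9999)
        out.vdw_radii = np.append(out.vdw_radii, 1.7)
        assert tmd_height(out) == pytest.approx(h0, abs=3.0)


class TestRingDiameter:
    def test_seven_points_at_77A(self):
        """Seven atoms at radius 77 A give the 154 A closed-ring diameter."""
        phis = np.linspace(0, 2 * np.pi, 7, endpoint=False)
        pts = np.column_stack([77 * np.cos(phis), 77 * np.sin(phis), np.full(7, 30.0)])
        s = simple_structure(pts, residue_numbers=[1401] * 7)
        assert ring_diameter(s, "1401") == pytest.approx(154.0, abs=1e-9)

    def test_single_axial_point_is_zero(self):
        s = simple_structure([[0.0, 0.0, 12.0]], residue_numbers=[1401])
        assert ring_diameter(s, "1401") == 0.0

    def test_rotation_invariance(self):
        s, _, _ = toy_with_slab(seed=4, jitter_sd=0.2)
        d0 = ring_diameter(s, "1401-1499")
        rot = _rotation_about(np.array([0.0, 0.0, 1.0]), 1.234)
        assert ring_diameter(s.transformed(rot), "1401-1499") == pytest.approx(
            d0, abs=1e-9
        )

    def test_empty_selection_raises(self):
        s, _, _ = toy_with_slab(seed=4)
        with pytest.raises(SelectionError):
            ring_diameter(s, "7000-8000")


def profile(theta, R, height=70.0, convention="explicit", ring=None):
    return GeometryProfile(
        theta=theta,
        R_inplane=R,
        area=float(np.pi * R**2),
        tmd_height=height,
        ring_diameter=ring,
        slab=(-20.0, 20.0),
        slab_convention=convention,
    )


class TestCompareStates:
    def test_canonical_delta(self):
        """30->15 deg with R 7.8131->8.9131 nm gives delta_R = 1.1 nm and an
        annulus-consistent area change."""
        delta = compare_states(profile(30.0, 7.8131), profile(15.0, 8.9131, 51.0))
        assert delta.delta_R == pytest.approx(1.1, abs=1e-4)
        assert delta.theta_c == pytest.approx(np.pi / 6, abs=1e-9)
        assert delta.theta_o == pytest.approx(np.pi / 12, abs=1e-9)
        assert delta.delta_height == pytest.approx(19.0, abs=1e-9)
        # pi*(Ro^2 - Rc^2) vs 2*pi*Rc*dR: consistent within 15% here
        assert delta.annular

    def test_identity_delta_is_zero(self):
        p = profile(30.0, 7.8)
        delta = compare_states(p, p)
        assert delta.delta_R == 0.0
        assert delta.delta_A == 0.0
        assert delta.delta_height == 0.0

    def test_delta_A_is_area_difference(self):
        closed, open_ = profile(30.0, 7.0), profile(12.0, 9.5)
        delta = compare_states(closed, open_)
        assert delta.delta_A == pytest.approx(open_.area - closed.area, abs=1e-12)

    def test_mixed_conventions_rejected(self):
        with pytest.raises(ConventionError):
            compare_states(
                profile(30.0, 7.8), profile(15.0, 8.9, convention="hydrophobic-belt")
            )


def test_mimic_pair_recovery(mimic_pair, mimic_slabs):
    """The closed/open MscK mimic reproduces its generation targets:
    30->15 deg bending, +1.1 nm footprint radius, ring 154->178 A."""
    (closed, open_, truth) = mimic_pair
    profs = []
    for s, slab in zip((closed, open_), mimic_slabs):
        profs.append(
            measure_geometry(
                s, slab, ring_selection="1401-1499", slab_convention="tm-extent"
            )
        )
    delta = compare_states(profs[0], profs[1])
    assert np.degrees(delta.theta_c - delta.theta_o) == pytest.approx(15.0, abs=1.0)
    assert delta.delta_R == pytest.approx(truth["delta_R_nm"], abs=0.1)
    assert profs[0].ring_diameter == pytest.approx(154.0, abs=2.0)
    assert profs[1].ring_diameter == pytest.approx(178.0, abs=2.0)
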