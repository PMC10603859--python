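import numpy as np
import pytest

from caroseg import geometry as g
from caroseg import quantify as q


def cylinder(r_mab, r_lib, length, step=2.0, z0=0.0):
    contours = {}
    for z in np.arange(z0, z0 + length + 1e-9, step):
        contours[float(z)] = (
            g.circle_contour(r_mab, z=z, boundary_kind="MAB"),
            g.circle_contour(r_lib, z=z, boundary_kind="LIB"))
    return g.ContourStack(contours=contours, bifurcation_z=z0 + length,
                          isd=step)


class TestVesselVolume:
    def test_cylinder(self, cylinder_stack):
        # enclosed volume of the r=2 mm boundary over 10 mm: 40*pi
        v = q.vessel_volume(cylinder_stack, "LIB")
        assert v == pytest.approx(40 * np.pi, rel=0.01)
        assert q.vessel_volume(cylinder_stack, "MAB") \
            == pytest.approx(160 * np.pi, rel=0.01)

    def test_cone_frustum(self):
        # MAB radius 2 -> 4 mm over 9 mm: volume = pi*9/3 * (4 + 8 + 16)
        contours = {}
        for z in np.arange(0.0, 9.0 + 1e-9, 3.0):
            r = 2.0 + 2.0 * z / 9.0
            contours[float(z)] = (
                g.circle_contour(r, z=z, boundary_kind="MAB", n=256),
                g.circle_contour(r / 2, z=z, boundary_kind="LIB", n=256))
        stack = g.ContourStack(contours=contours, bifurcation_z=9.0, isd=3.0)
        v = q.vessel_volume(stack, "MAB")
        expect = np.pi * 9 / 3 * (4 + 8 + 16)
        assert v == pytest.approx(expect, rel=0.01)

    def test_single_slice_rejected(self):
        stack = g.ContourStack(contours={
            0.0: (g.circle_contour(4.0, boundary_kind="MAB"),
                  g.circle_contour(2.0, boundary_kind="LIB"))},
            bifurcation_z=0.0, isd=2.0)
        with pytest.raises(ValueError):
            q.vessel_volume(stack, "MAB")


class TestVWV:
    def test_annular_cylinder(self, cylinder_stack):
        assert q.vwv(cylinder_stack) == pytest.approx(120 * np.pi, rel=0.01)

    def test_scaling_law(self):
        small = cylinder(3.0, 1.5, 10.0)
        big = cylinder(6.0, 3.0, 10.0)
        assert q.vwv(big) == pytest.approx(4 * q.vwv(small), rel=0.01)

    def test_branch_additivity(self, cylinder_stack):
        by_branch = q.vwv(cylinder_stack, per_branch=True)
        assert by_branch["total"] == pytest.approx(
            by_branch["CCA"] + by_branch["ICA"], rel=1e-9)
        total = q.vwv(cylinder_stack)
        assert by_branch["total"] == pytest.approx(total, rel=1e-9)

    def test_reslice_convergence(self, cylinder_stack):
        v1 = q.vwv(cylinder_stack, reslice_step=0.2)
        v2 = q.vwv(cylinder_stack, reslice_step=0.1)
        assert abs(v1 - v2) / v2 < 0.002

    def test_truth_stack_matches_analytic(self, geometry_only_cases):
        case = geometry_only_cases[0]
        truth = case.geometry.truth_stack(0.35, include_ends=True)
        v = q.vwv(truth, grid_spacing=0.1)
        assert v == pytest.approx(case.geometry.analytic_wall_volume(),
                                  rel=0.01)


class TestCorrespond:
    def test_concentric_uniform_distance(self):
        mab = g.circle_contour(4.0, boundary_kind="MAB", n=256)
        lib = g.circle_contour(2.0, boundary_kind="LIB", n=256)
        pairs = q.correspond(mab, lib, n_points=100)
        d = np.array([p.distance for p in pairs])
        assert np.all(np.abs(d - 2.0) < 0.05)

    def test_eccentric_min_max(self):
        mab = g.circle_contour(4.0, boundary_kind="MAB", n=512)
        lib = g.circle_contour(2.0, center=(1.0, 0.0), boundary_kind="LIB",
                               n=512)
        pairs = q.correspond(mab, lib, n_points=200)
        d = np.array([p.distance for p in pairs])
        assert d.min() == pytest.approx(1.0, abs=0.15)
        assert d.max() == pytest.approx(3.0, abs=0.15)

    def test_resolution_convergence(self):
        mab = g.circle_contour(4.0, boundary_kind="MAB", n=512)
        lib = g.circle_contour(2.0, boundary_kind="LIB", n=512)
        m16 = np.mean([p.distance for p in q.correspond(mab, lib, 16)])
        m256 = np.mean([p.distance for p in q.correspond(mab, lib, 256)])
        assert m16 == pytest.approx(m256, rel=0.01)

    def test_rigid_motion_invariance(self):
        mab = g.circle_contour(4.0, boundary_kind="MAB", n=256)
        lib = g.circle_contour(2.0, center=(0.8, 0.2), boundary_kind="LIB",
                               n=256)
        d0 = sorted(p.distance for p in q.correspond(mab, lib, 64))
        shift = np.array([2.5, -1.5])
        mab2 = g.Contour(points=mab.points + shift, z=0, boundary_kind="MAB")
        lib2 = g.Contour(points=lib.points + shift, z=0, boundary_kind="LIB")
        d1 = sorted(p.distance for p in q.correspond(mab2, lib2, 64))
        np.testing.assert_allclose(d0, d1, atol=1e-6)

    def test_lib_outside_rejected(self):
        mab = g.circle_contour(2.0, boundary_kind="MAB")
        lib = g.circle_contour(2.0, center=(3.0, 0), boundary_kind="LIB")
        with pytest.raises(ValueError):
            q.correspond(mab, lib)

    def test_order_preserved(self):
        mab = g.circle_contour(4.0, boundary_kind="MAB", n=256)
        lib = g.circle_contour(2.0, center=(0.5, 0.5), boundary_kind="LIB",
                               n=256)
        thetas = [p.theta for p in q.correspond(mab, lib, 64)]
        assert thetas == sorted(thetas)


class TestVWTMap:
    def test_uniform_wall(self, cylinder_stack):
        vmap = q.vwt_map(cylinder_stack)
        vals = vmap.grid[np.isfinite(vmap.grid)]
        assert np.all(np.abs(vals - 2.0) < 0.06)
        assert vmap.mean() == pytest.approx(2.0, rel=0.01)

    def test_plaque_argmax_location(self, geometry_only_cases):
        from caroseg.phantom import Plaque
        case = geometry_only_cases[0]
        geo = case.geometry
        geo = type(geo)(**{**geo.__dict__})
        bif = geo.bifurcation_z
        geo.plaques = [Plaque(branch="CCA", z_center=bif - 7.0,
                              theta_center=np.pi / 2, z_extent=6.0,
                              theta_extent=np.pi, max_thickness=1.2)]
        stack = geo.truth_stack(1.0)
        vmap = q.vwt_map(stack, grid_spacing=0.1)
        i, j = np.unravel_index(np.nanargmax(vmap.grid), vmap.grid.shape)
        z_at_max = vmap.row_z[i]
        theta_at_max = 2 * np.pi * j / vmap.grid.shape[1]
        assert abs(z_at_max - (bif - 7.0)) <= 3.0
        ang_err = np.angle(np.exp(1j * (theta_at_max - np.pi / 2)))
        assert abs(ang_err) <= np.pi / 2

    def test_l_shape_ica_block(self, geometry_only_cases):
        case = geometry_only_cases[0]
        vmap = q.vwt_map(case.geometry.truth_stack(2.0), grid_spacing=0.1)
        ica_rows = [i for i, v in enumerate(vmap.row_vessel) if v == "ICA"]
        cca_rows = [i for i, v in enumerate(vmap.row_vessel) if v == "CCA"]
        assert np.isfinite(vmap.grid[cca_rows]).all()
        assert np.isnan(vmap.grid[ica_rows]).any()  # truncated columns
        assert vmap.bifurcation_row == max(cca_rows)


class TestMapSummary:
    def test_constant_map(self, cylinder_stack):
        vmap = q.vwt_map(cylinder_stack)
        assert q.map_summary(vmap) == pytest.approx(2.0, rel=0.01)

    def test_paired_identical_maps(self, cylinder_stack):
        vmap = q.vwt_map(cylinder_stack)
        a, b = q.map_difference(vmap, vmap)
        assert np.allclose(a - b, 0.0)

    def test_offset_map(self, cylinder_stack):
        from dataclasses import replace
        vmap = q.vwt_map(cylinder_stack)
        shifted = replace(vmap, grid=vmap.grid + 0.3)
        a, b = q.map_difference(vmap, shifted)
        assert np.mean(b - a) == pytest.approx(0.3, abs=1e-9)

    def test_empty_map_rejected(self):
        vmap = q.VWTMap(grid=np.full((2, 3), np.nan),
                        row_z=np.array([0.0, 1.0]),
                        row_vessel=["CCA", "CCA"], bifurcation_row=1)
        with pytest.raises(ValueError):
            q.map_summary(vmap)
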