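import numpy as np
import pytest

from caroseg import metrics as m
from caroseg import phantom as ph


class TestSampleCohort:
    def test_deterministic(self):
        p = ph.CohortParams(render=False)
        c1 = ph.sample_cohort(2, p, seed=5)
        c2 = ph.sample_cohort(2, p, seed=5)
        for (b1, f1), (b2, f2) in zip(c1, c2):
            assert b1.geometry.r_mab_cca == b2.geometry.r_mab_cca
            assert len(b1.geometry.plaques) == len(b2.geometry.plaques)
            z = b1.truth.slice_zs[3]
            np.testing.assert_array_equal(b1.truth.contours[z][0].points,
                                          b2.truth.contours[z][0].points)
            assert len(f1.geometry.plaques) == len(f2.geometry.plaques)

    def test_different_seeds_differ(self):
        p = ph.CohortParams(render=False)
        a = ph.sample_cohort(1, p, seed=1)[0][0]
        b = ph.sample_cohort(1, p, seed=2)[0][0]
        assert a.geometry.r_mab_cca != b.geometry.r_mab_cca

    def test_zero_patients_rejected(self):
        with pytest.raises(ValueError):
            ph.sample_cohort(0, ph.CohortParams(render=False))

    def test_invalid_params_rejected(self):
        p = ph.CohortParams(render=False, lib_ratio_range=(1.2, 1.4))
        with pytest.raises(ValueError):
            ph.sample_cohort(1, p)

    def test_progression_only_followup_grows_wall(self):
        p = ph.CohortParams(render=False)
        for base, fu in ph.sample_cohort(4, p, seed=9):
            assert fu.geometry.analytic_wall_volume() \
                >= base.geometry.analytic_wall_volume() - 1e-9

    def test_zero_progression_noise_copies_baseline(self):
        p = ph.CohortParams(render=False, progression_noise=0.0)
        base, fu = ph.sample_cohort(1, p, seed=3)[0]
        assert fu.geometry.analytic_wall_volume() \
            == pytest.approx(base.geometry.analytic_wall_volume(), rel=1e-9)


class TestGeometryInvariants:
    def test_lib_below_mab_everywhere(self, geometry_only_cases):
        geo = geometry_only_cases[0].geometry
        theta = np.linspace(0, 2 * np.pi, 90, endpoint=False)
        for z in np.linspace(geo.bifurcation_z - 15,
                             geo.bifurcation_z + 10, 40):
            rm = geo.mab_radius(z, theta)
            rl = geo.lib_radius(z, theta)
            assert np.all(rl < rm)
            assert np.all(rl > 0)

    def test_truth_contours_are_exact_level_sets(self, geometry_only_cases):
        case = geometry_only_cases[0]
        geo = case.geometry
        z = case.truth.slice_zs[5]
        mab = case.truth.contours[z][0]
        center = geo.centerline(z)
        rel = mab.points - center
        r = np.hypot(rel[:, 0], rel[:, 1])
        theta = np.arctan2(rel[:, 1], rel[:, 0])
        np.testing.assert_allclose(r, geo.mab_radius(z, theta), atol=1e-9)


class TestRenderVolume:
    def test_noise_free_tissue_classes(self, geometry_only_cases):
        geo = geometry_only_cases[0].geometry
        noise = ph.NoiseParams(speckle=False, blur_sigma_mm=0.0,
                               shadows=False, hypoechoic=False)
        vol = ph.render_volume(geo, noise=noise)
        k = vol.nearest_slice(geo.bifurcation_z - 7.0)
        sl = vol.voxels[k]
        c = geo.centerline(geo.bifurcation_z - 7.0)
        j = int(round((c[1] - vol.origin[1]) / vol.spacing[1]))
        i = int(round((c[0] - vol.origin[0]) / vol.spacing[0]))
        lumen = sl[j, i]
        wall = sl[j, i + int(3.2 / vol.spacing[0])]
        background = sl[5, 5]
        assert lumen < background < wall
        levels = np.unique(sl)
        assert len(levels) <= 3  # piecewise-constant tissue classes
        expected = np.array([noise.lumen_level, noise.background_level,
                             noise.wall_level])
        for v in levels:
            assert np.min(np.abs(expected - v)) < 1e-6

    def test_same_seed_identical(self, geometry_only_cases):
        geo = geometry_only_cases[0].geometry
        v1 = ph.render_volume(geo, noise=ph.NoiseParams(seed=4))
        v2 = ph.render_volume(geo, noise=ph.NoiseParams(seed=4))
        np.testing.assert_array_equal(v1.voxels, v2.voxels)

    def test_shadow_darkens_cone(self, geometry_only_cases):
        geo = geometry_only_cases[0].geometry
        from dataclasses import replace as drep
        geo = drep(geo, plaques=[ph.Plaque(
            branch="CCA", z_center=geo.bifurcation_z - 7.0,
            theta_center=np.pi / 2, z_extent=6.0, theta_extent=np.pi,
            max_thickness=1.0, calcified=True)])
        base = ph.NoiseParams(speckle=False, blur_sigma_mm=0.0,
                              shadows=False, hypoechoic=False)
        with_shadow = ph.NoiseParams(speckle=False, blur_sigma_mm=0.0,
                                     shadows=True, hypoechoic=False)
        v0 = ph.render_volume(geo, noise=base)
        v1 = ph.render_volume(geo, noise=with_shadow)
        assert v1.voxels.mean() < v0.voxels.mean()
        k = v0.nearest_slice(geo.bifurcation_z - 7.0)
        diff = v0.voxels[k] - v1.voxels[k]
        assert diff.max() > 0  # dropout present in the shadowed slice

    def test_bad_spacing_rejected(self, geometry_only_cases):
        with pytest.raises(ValueError):
            ph.render_volume(geometry_only_cases[0].geometry,
                             spacing=(0.2, -0.2, 0.35))


class TestVirtualObserver:
    def test_noise_free_identity(self, geometry_only_cases):
        case = geometry_only_cases[0]
        model = ph.ObserverModel(radial_noise_sd=0.0,
                                 bifurcation_sd_per_isd={2.0: 0.0})
        stack = ph.virtual_observer(case, 2.0, model, trial_seed=0)
        ref = case.geometry.truth_stack(2.0)
        assert set(stack.contours) == set(ref.contours)
        for z in stack.contours:
            np.testing.assert_allclose(stack.contours[z][0].points,
                                       ref.contours[z][0].points)

    def test_trials_differ(self, geometry_only_cases):
        case = geometry_only_cases[0]
        model = ph.ObserverModel(radial_noise_sd=0.2, seed=1)
        t1 = ph.virtual_observer(case, 2.0, model, trial_seed=0)
        t2 = ph.virtual_observer(case, 2.0, model, trial_seed=1)
        z = [z for z in t1.contours if z in t2.contours][2]
        d = m.dice(t1.contours[z][0], t2.contours[z][0])
        assert d < 1.0

    def test_perturbed_contours_valid(self, geometry_only_cases):
        case = geometry_only_cases[1]
        model = ph.ObserverModel(radial_noise_sd=0.35, seed=2)
        stack = ph.virtual_observer(case, 1.0, model, trial_seed=5)
        for z, (mab, lib) in stack.contours.items():
            assert mab.area > 0 and lib.area > 0
            assert mab.contains(lib, tol=1e-6)

    def test_more_noise_lowers_dice(self, geometry_only_cases):
        case = geometry_only_cases[0]
        means = []
        for sd in (0.05, 0.3):
            dscs = []
            for trial in range(20):
                model = ph.ObserverModel(radial_noise_sd=sd, seed=7)
                t1 = ph.virtual_observer(case, 2.0, model,
                                         trial_seed=2 * trial)
                t2 = ph.virtual_observer(case, 2.0, model,
                                         trial_seed=2 * trial + 1)
                zs = [z for z in t1.contours if z in t2.contours]
                dscs += [m.dice(t1.contours[z][0], t2.contours[z][0])
                         for z in zs[::4]]
            means.append(np.mean(dscs))
        assert means[1] < means[0]

    def test_bifurcation_jitter_on_slice_grid(self, geometry_only_cases):
        case = geometry_only_cases[0]
        vz = ph.DEFAULT_SPACING[2]
        model = ph.ObserverModel(radial_noise_sd=0.0,
                                 bifurcation_sd_per_isd={2.0: 0.5}, seed=3)
        for trial in range(5):
            stack = ph.virtual_observer(case, 2.0, model, trial_seed=trial)
            jit = stack.bifurcation_z - case.geometry.bifurcation_z
            assert abs(jit / vz - round(jit / vz)) < 1e-9
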