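import numpy as np
import pytest

from poroarch import (PackingError, make_compression_curve, make_fbm_surface,
                      make_granule_packing, make_grf_trabecular,
                      make_sierpinski2d, make_solid)


class TestSolids:
    def test_slab_porosity_closed_form(self):
        vol, truth = make_solid("slab", (50, 10, 10), thickness_vox=10)
        assert truth["porosity_fraction"] == pytest.approx(0.8)
        assert vol.n_pore / vol.n_voxels == pytest.approx(0.8)

    def test_sphere_closed_form_truth(self):
        r = 10
        vol, truth = make_solid("sphere", (41, 41, 41), radius_vox=r)
        assert truth["interface_area_vox2"] == pytest.approx(4 * np.pi * r**2)
        assert truth["porosity_fraction"] == pytest.approx(
            1 - (4 / 3) * np.pi * r**3 / 41**3)
        # voxel count close to analytic volume (center-inclusion exactness)
        assert vol.n_material == pytest.approx((4 / 3) * np.pi * r**3,
                                               rel=0.01)

    def test_cylinder_pore_truth(self):
        vol, truth = make_solid("cylinder", (20, 47, 47), radius_vox=8,
                                phase="pore")
        assert truth["thickness_vox"] == 16
        assert truth["porosity_fraction"] == pytest.approx(
            np.pi * 64 / 47**2)

    def test_geometry_must_fit(self):
        with pytest.raises(ValueError):
            make_solid("sphere", (10, 10, 10), radius_vox=8)


class TestGrf:
    def test_quantile_porosity_exact_to_one_voxel(self):
        vol, truth = make_grf_trabecular((48, 48, 48), 0.753, 40.0, seed=3)
        n = vol.n_voxels
        assert abs(vol.n_pore - round(0.753 * n)) <= 1

    def test_seed_determinism(self):
        a, _ = make_grf_trabecular((24, 24, 24), 0.6, 30.0, seed=9)
        b, _ = make_grf_trabecular((24, 24, 24), 0.6, 30.0, seed=9)
        np.testing.assert_array_equal(a.mask, b.mask)
        c, _ = make_grf_trabecular((24, 24, 24), 0.6, 30.0, seed=10)
        assert (a.mask != c.mask).any()

    def test_higher_porosity_lower_surface_density(self):
        from poroarch import compute_surface_density
        lo, _ = make_grf_trabecular((64, 64, 64), 0.691, 60.0, seed=5)
        hi, _ = make_grf_trabecular((64, 64, 64), 0.888, 60.0, seed=5)
        assert compute_surface_density(hi) < compute_surface_density(lo)


class TestPacking:
    def test_single_solid_sphere_closed_form(self):
        vol, truth = make_granule_packing((40, 40, 40), 1, 200.0, 0.0,
                                          seed=1, voxel_size_um=10.0,
                                          allow_boundary_clip=False)
        expected = 1 - vol.n_material / 40**3
        assert truth["porosity_fraction"] == pytest.approx(expected)
        assert vol.n_material == pytest.approx((4 / 3) * np.pi * 10**3,
                                               rel=0.05)

    def test_inner_porosity_raises_stack_porosity(self):
        solid, t0 = make_granule_packing((64, 64, 64), 10, 200.0, 0.0,
                                         seed=2, voxel_size_um=10.0)
        porous, t1 = make_granule_packing((64, 64, 64), 10, 200.0, 0.5,
                                          seed=2, voxel_size_um=10.0)
        assert t1["porosity_fraction"] > t0["porosity_fraction"]

    def test_doubling_n_decreases_porosity(self):
        a, ta = make_granule_packing((64, 64, 64), 8, 200.0, 0.0, seed=4,
                                     voxel_size_um=10.0)
        b, tb = make_granule_packing((64, 64, 64), 16, 200.0, 0.0, seed=4,
                                     voxel_size_um=10.0)
        assert tb["porosity_fraction"] < ta["porosity_fraction"]

    def test_seed_determinism(self):
        a, _ = make_granule_packing((32, 32, 32), 4, 120.0, 0.3, seed=8,
                                    voxel_size_um=10.0)
        b, _ = make_granule_packing((32, 32, 32), 4, 120.0, 0.3, seed=8,
                                    voxel_size_um=10.0)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_impossible_packing_reports_achieved(self):
        with pytest.raises(PackingError, match="granules"):
            make_granule_packing((32, 32, 32), 500, 160.0, 0.0, seed=1,
                                 voxel_size_um=10.0,
                                 max_attempts_per_granule=20)


class TestFractalFixtures:
    def test_sierpinski_level1(self):
        img = make_sierpinski2d(1)
        assert img.shape == (3, 3)
        assert img.sum() == 8 and not img[1, 1]

    def test_sierpinski_level5_counts(self):
        img = make_sierpinski2d(5)
        assert img.shape == (243, 243)
        assert int(img.sum()) == 8**5

    def test_fbm_determinism_and_range(self):
        a = make_fbm_surface((64, 64), 0.5, 11)
        b = make_fbm_surface((64, 64), 0.5, 11)
        np.testing.assert_array_equal(a, b)
        assert a.min() == 0.0 and a.max() == pytest.approx(255.0)

    def test_fbm_rejects_bad_hurst(self):
        with pytest.raises(ValueError):
            make_fbm_surface((32, 32), 1.5, 0)


class TestCompressionCurve:
    def test_triangle_ground_truth(self):
        curve, truth = make_compression_curve(100.0, 0.0, 400.0, 0.0, 0)
        assert truth == {"stiffness": 100.0, "max_displacement": 4.0,
                         "work_to_failure": 800.0}
        assert curve.load.max() >= 400.0

    def test_toe_area_analytic(self):
        # integral of k d^2/(2 toe) over the toe plus the linear ramp
        k, toe, cap = 50.0, 1.0, 400.0
        curve, truth = make_compression_curve(k, toe, cap, 0.0, 0)
        d_cap = toe / 2 + cap / k
        assert truth["max_displacement"] == pytest.approx(d_cap)
        area = k * toe**2 / 6 + (k * toe / 2 + cap) / 2 * (d_cap - toe)
        assert truth["work_to_failure"] == pytest.approx(area)
        # numerical integral of the noiseless trace agrees
        num = np.trapezoid(np.minimum(curve.load, cap),
                           curve.displacement)
        assert num == pytest.approx(area, rel=0.01)

    def test_noise_seed_determinism(self):
        a, _ = make_compression_curve(80.0, 0.5, 400.0, 5.0, 3)
        b, _ = make_compression_curve(80.0, 0.5, 400.0, 5.0, 3)
        np.testing.assert_array_equal(a.load, b.load)
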