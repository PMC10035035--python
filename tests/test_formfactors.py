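"""Geometric scattering primitives against limits and quadrature oracles."""

import numpy as np
import pytest

from oracle_utils import (
    disc_amplitude_grid,
    ellipsoid_revolution_intensity_quad,
    mc_ellipsoid_intensity,
    radial_shell_amplitude,
)
from solusaxs import formfactors as ff

W = 9.41e-6  # water SLD


class TestSphere:
    def test_forward_limit_is_contrast_times_volume(self):
        R, dr = 120.0, 2e-6
        a0 = ff.sphere_amplitude(np.array([0.0]), R, dr)[0]
        assert a0 == pytest.approx(dr * 4 / 3 * np.pi * R**3, rel=1e-12)

    def test_first_zero_at_qR_4p4934(self):
        R = 100.0
        q = np.linspace(4.2, 4.8, 2001) / R
        amp = ff.sphere_amplitude(q, R, 1e-6)
        q_zero = q[np.argmin(np.abs(amp))]
        assert q_zero * R == pytest.approx(4.4934, abs=2e-3)

    def test_series_matches_exact_at_crossover(self):
        # continuity across the small-x series switch
        R = 50.0
        q = np.array([0.9e-3 / R, 1.1e-3 / R])
        amp = ff.sphere_amplitude(q, R, 1e-6)
        assert abs(amp[0] - amp[1]) / amp[0] < 1e-6

    def test_intensity_matches_radial_quadrature(self, q20):
        R, dr = 100.0, 2e-6
        closed = ff.sphere_amplitude(q20, R, dr) ** 2
        oracle = radial_shell_amplitude(q20, [R], [dr], 0.0) ** 2
        assert np.max(np.abs(closed - oracle)) <= 1e-3 * np.max(closed)


class TestShell:
    PROF = ff.ShellProfile((200.0, 206.0, 236.0, 242.0),
                           (W, 1.44e-5, 8.2e-6, 1.44e-5), W)

    def test_contrast_matched_layers_scatter_nothing(self, q20):
        prof = ff.ShellProfile((100.0, 130.0), (W, W), W)
        assert np.allclose(ff.shell_amplitude(q20, prof), 0.0)

    def test_single_layer_reduces_to_sphere(self, q20):
        prof = ff.ShellProfile((80.0,), (1.2e-5,), W)
        a = ff.shell_amplitude(q20, prof)
        b = ff.sphere_amplitude(q20, 80.0, 1.2e-5 - W)
        np.testing.assert_allclose(a, b, rtol=1e-14)

    def test_vesicle_profile_matches_radial_quadrature(self, q20):
        a = ff.shell_amplitude(q20, self.PROF)
        b = radial_shell_amplitude(q20, self.PROF.boundaries, self.PROF.slds, W)
        assert np.max(np.abs(a - b)) <= 1e-6 * np.max(np.abs(a))

    def test_forward_limit_total_excess(self):
        a0 = ff.shell_amplitude(np.array([0.0]), self.PROF)[0]
        assert a0 == pytest.approx(self.PROF.total_excess_scattering(), rel=1e-12)

    def test_bad_boundaries_rejected(self):
        with pytest.raises(ValueError):
            ff.ShellProfile((100.0, 90.0), (1e-5, 1e-5), W)
        with pytest.raises(ValueError):
            ff.ShellProfile((100.0,), (1e-5, 2e-5), W)


class TestEllipsoid:
    def test_sphere_degeneracy(self, q20):
        R, sld = 30.0, 7.8e-6
        i_ell = ff.ellipsoid_orientavg_intensity(q20, [((R, R, R), sld)], W)
        i_sph = ff.sphere_amplitude(q20, R, sld - W) ** 2
        np.testing.assert_allclose(i_ell, i_sph, rtol=1e-10)

    def test_revolution_matches_adaptive_quadrature(self, q20):
        a, c, sld = 16.0, 24.0, 7.8e-6
        mine = ff.ellipsoid_orientavg_intensity(q20, [((a, a, c), sld)], W)
        oracle = ellipsoid_revolution_intensity_quad(q20, a, c, sld, W)
        assert np.max(np.abs(mine - oracle) / oracle) < 1e-6

    def test_triaxial_matches_monte_carlo(self, q20):
        layers = [((14.0, 20.0, 28.0), 7.8e-6)]
        mine = ff.ellipsoid_orientavg_intensity(q20, layers, W)
        oracle = mc_ellipsoid_intensity(q20, layers, W, seed=3)
        assert np.max(np.abs(mine - oracle) / mine) < 5e-3

    def test_revolution_branch_consistent_with_product_grid(self, q20):
        # a == b takes the fast single-angle path; a = b + epsilon the
        # 2D product grid; both must agree
        fast = ff.ellipsoid_orientavg_intensity(q20, [((16.0, 16.0, 24.0), 7.8e-6)], W)
        slow = ff.ellipsoid_orientavg_intensity(
            q20, [((16.0, 16.0 + 1e-9, 24.0), 7.8e-6)], W)
        np.testing.assert_allclose(fast, slow, rtol=1e-6)

    def test_quadrature_order_doubling_converged(self, q20):
        layers = [((14.0, 20.0, 28.0), 7.8e-6), ((21.0, 27.0, 35.0), 1.3e-5)]
        base = ff.ellipsoid_orientavg_intensity(q20, layers, W)
        fine = ff.ellipsoid_orientavg_intensity(q20, layers, W,
                                                n_alpha=152, n_beta=152)
        assert np.max(np.abs(base - fine) / np.abs(fine)) < 5e-4


class TestDisc:
    ARGS = dict(core_radius=38.0, rim_thickness=12.0, half_height=11.0,
                face_thickness=6.0, sld_core=8.2e-6, sld_face=1.44e-5,
                sld_rim=1.1e-5, solvent_sld=W)

    def test_forward_limit_is_volume_sum(self):
        a0 = ff.coreshell_disc_amplitude(np.array([0.0]), np.array([0.7]),
                                         **self.ARGS)[0, 0]
        Rc, tr = self.ARGS["core_radius"], self.ARGS["rim_thickness"]
        hh, tf = self.ARGS["half_height"], self.ARGS["face_thickness"]
        v_core = 2 * np.pi * Rc**2 * hh
        v_face = 2 * np.pi * Rc**2 * (hh + tf) - v_core
        v_rim = 2 * np.pi * ((Rc + tr) ** 2 - Rc**2) * (hh + tf)
        expected = ((self.ARGS["sld_core"] - W) * v_core
                    + (self.ARGS["sld_face"] - W) * v_face
                    + (self.ARGS["sld_rim"] - W) * v_rim)
        assert a0 == pytest.approx(expected, rel=1e-10)

    def test_zero_rim_uniform_sld_reduces_to_cylinder(self, q20):
        alpha = np.array([0.4, 1.1])
        a = ff.coreshell_disc_amplitude(
            q20, alpha, core_radius=40.0, rim_thickness=0.0, half_height=10.0,
            face_thickness=5.0, sld_core=1.2e-5, sld_face=1.2e-5,
            sld_rim=0.0, solvent_sld=W)
        b = ff.cylinder_amplitude(q20, alpha, 40.0, 15.0, 1.2e-5 - W)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    @pytest.mark.parametrize("alpha", [0.3, 0.9, 1.4])
    def test_amplitude_matches_realspace_grid(self, q20, alpha):
        mine = ff.coreshell_disc_amplitude(q20, np.array([alpha]), **self.ARGS)[:, 0]
        oracle = disc_amplitude_grid(q20, alpha, *[
            self.ARGS[k] for k in ("core_radius", "rim_thickness",
                                   "half_height", "face_thickness", "sld_core",
                                   "sld_face", "sld_rim", "solvent_sld")])
        assert np.max(np.abs(mine - oracle)) < 5e-3 * np.max(np.abs(mine))

    def test_orientavg_nonnegative_and_finite(self, q200):
        i_q = ff.disc_orientavg_intensity(q200, **self.ARGS)
        assert np.all(i_q >= 0) and np.all(np.isfinite(i_q))


class TestFlexibleRod:
    def test_forward_limit(self):
        radii, slds = [15.0, 23.0], [7.8e-6, 1.4e-5]
        i0 = ff.flexible_rod_intensity(np.array([1e-8]), 800.0, 200.0,
                                       radii, slds, W)[0]
        a_cs = ((7.8e-6 - W) * np.pi * 15**2
                + (1.4e-5 - W) * np.pi * (23**2 - 15**2))
        assert i0 == pytest.approx((a_cs * 800.0) ** 2, rel=1e-6)

    def test_rigid_limit_uses_rod_average(self, q200):
        i_stiff = ff.flexible_rod_intensity(q200, 400.0, 400.0, [15.0],
                                            [7.8e-6], W)
        s_rod = ff.rod_longitudinal_factor(q200, 400.0)
        a_cs = ff.circular_cs_amplitude(q200, [15.0], [7.8e-6], W)
        np.testing.assert_allclose(i_stiff, s_rod * (a_cs * 400.0) ** 2,
                                   rtol=1e-12)

    def test_q_inverse_scaling_regime(self):
        # rigid rod: log-log slope ~ -1 between 1/L and 1/R scales
        q = np.geomspace(1.0 / 150.0, 1.0 / 40.0, 40)
        i_q = ff.flexible_rod_intensity(q, 900.0, 900.0, [10.0], [7.8e-6], W)
        slope = np.polyfit(np.log(q), np.log(i_q), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)

    def test_wormlike_factor_limits(self):
        # -> 1 at q -> 0; monotone decay at low q
        s = ff.wormlike_chain_factor(np.array([0.0, 1e-4, 1e-3, 1e-2]),
                                     2000.0, 300.0)
        assert s[0] == pytest.approx(1.0)
        assert np.all(np.diff(s) < 0)

    def test_invalid_lengths_rejected(self):
        with pytest.raises(ValueError):
            ff.flexible_rod_intensity(np.array([0.01]), -5.0, 10.0, [10.0],
                                      [1e-5], W)


def test_quadrature_cache_respects_interval():
    x1, w1 = ff._gauss_legendre(16, 0.0, 1.0)
    x2, w2 = ff._gauss_legendre(16, 0.0, 2.0)
    assert w1.sum() == pytest.approx(1.0)
    assert w2.sum() == pytest.approx(2.0)
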