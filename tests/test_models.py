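"""Assembly models: structure factors, reductions, forward intensities."""

import numpy as np
import pytest

from oracle_utils import paracrystal_pair_sum
from solusaxs import formfactors as ff
from solusaxs.composition import CompositionLedger
from solusaxs.models import (
    A2_TO_CM2,
    AsymmetricBilayerParams,
    AsymmetricVesicleModel,
    BicelleModel,
    BicelleParams,
    MicelleModel,
    MicelleParams,
    VesicleModel,
    VesicleParams,
    WormModel,
    WormParams,
    multilamellar_structure_factor,
    py_hard_sphere_sq,
    vesicle_intensity,
)

W = 9.41e-6


class TestPercusYevick:
    def test_ideal_gas_limit(self, q200):
        assert np.allclose(py_hard_sphere_sq(q200, 25.0, 0.0), 1.0)

    def test_compressibility_limit(self):
        # S(0) = (1-phi)^4/(1+2phi)^2
        phi = 0.3
        s0 = py_hard_sphere_sq(np.array([1e-9]), 25.0, phi)[0]
        assert s0 == pytest.approx((1 - phi) ** 4 / (1 + 2 * phi) ** 2, rel=1e-8)

    def test_closed_form_and_quadrature_branches_agree(self):
        # the small-qd quadrature branch must join the closed form smoothly
        R = 25.0
        q = np.array([0.49999 / (2 * R), 0.50001 / (2 * R)])
        s = py_hard_sphere_sq(q, R, 0.25)
        assert abs(s[0] - s[1]) < 1e-5

    def test_high_q_asymptote(self):
        q = np.array([51.0 / 25.0, 80.0 / 25.0])
        s = py_hard_sphere_sq(q, 25.0, 0.3)
        assert np.all(np.abs(s - 1.0) < 1e-3)

    def test_unphysical_volume_fraction_rejected(self):
        with pytest.raises(ValueError):
            py_hard_sphere_sq(np.array([0.01]), 25.0, 0.8)


class TestMultilamellarStacking:
    def test_single_layer_is_unity(self, q200):
        assert np.allclose(multilamellar_structure_factor(q200, 1, 65.0, 6.0), 1.0)

    def test_bragg_peak_position(self):
        d = 65.0
        q = np.linspace(0.06, 0.13, 2000)
        s = multilamellar_structure_factor(q, 5, d, 3.0)
        q_peak = q[np.argmax(s)]
        assert q_peak == pytest.approx(2 * np.pi / d, abs=0.002)

    @pytest.mark.parametrize("n,sigma", [(2, 0.0), (4, 6.0), (9, 12.0)])
    def test_closed_form_matches_pair_sum(self, q200, n, sigma):
        closed = multilamellar_structure_factor(q200, n, 65.0, sigma)
        oracle = paracrystal_pair_sum(q200, n, 65.0, sigma)
        np.testing.assert_allclose(closed, oracle, atol=1e-10)

    def test_forward_limit_is_n(self):
        s0 = multilamellar_structure_factor(np.array([1e-12]), 6, 65.0, 6.0)[0]
        assert s0 == pytest.approx(6.0, rel=1e-6)


class TestReductionLattice:
    """The stated degeneracies must hold essentially bit-tight."""

    def test_no_multilamellar_fraction_ignores_layering(self, q200):
        base = dict(mean_radius=250.0, radius_polydispersity=0.2,
                    tail_thickness=30.0)
        a = VesicleModel(VesicleParams(**base, f_multilamellar=0.0, n_layers=7,
                                       d_spacing=80.0), W)
        b = VesicleModel(VesicleParams(**base, f_multilamellar=0.0, n_layers=1), W)
        np.testing.assert_array_equal(a.mean_sq_amplitude(q200),
                                      b.mean_sq_amplitude(q200))

    def test_zero_volume_fraction_means_no_structure_factor(self, q200):
        p = dict(shape="ellipsoid_revolution", core_a=16.0, core_b=16.0,
                 core_c=24.0, shell_thickness=6.0)
        a = MicelleModel(MicelleParams(**p, hs_volume_fraction=0.0), W)
        b = MicelleModel(MicelleParams(**p, hs_volume_fraction=0.2,
                                       hs_radius=26.0), W)
        i_a, i_b = a.mean_sq_amplitude(q200), b.mean_sq_amplitude(q200)
        assert not np.allclose(i_a, i_b)  # S(q) does act ...
        c = MicelleModel(MicelleParams(**p, hs_volume_fraction=0.0,
                                       hs_radius=26.0), W)
        np.testing.assert_array_equal(i_a, c.mean_sq_amplitude(q200))

    def test_zero_fuzziness_is_sharp_coreshell_sphere(self, q200):
        p = MicelleParams(shape="fuzzy_sphere", core_a=22.0, core_b=22.0,
                          core_c=22.0, shell_thickness=12.0, fuzziness_sigma=0.0)
        m = MicelleModel(p, W)
        prof = ff.ShellProfile((22.0, 34.0), (p.sld_core, p.sld_shell), W)
        np.testing.assert_allclose(m.mean_sq_amplitude(q200),
                                   ff.shell_amplitude(q200, prof) ** 2,
                                   rtol=1e-10)

    def test_symmetric_leaflets_reduce_to_three_shell(self, q200):
        pa = AsymmetricBilayerParams(x_in=0.17, x_out=0.17)
        asym = AsymmetricVesicleModel(pa, W)
        head, tail = pa.leaflet_slds(0.17)
        sym = VesicleModel(VesicleParams(sld_head=head, sld_tail=tail), W)
        i_a, i_s = asym.mean_sq_amplitude(q200), sym.mean_sq_amplitude(q200)
        assert np.max(np.abs(i_a - i_s)) <= 1e-10 * np.max(i_s)

    def test_sphere_chain_triaxial_revolution_sphere(self, q200):
        R, sld = 25.0, 7.9e-6
        tri = ff.ellipsoid_orientavg_intensity(
            q200, [((R, R + 1e-12, R), sld)], W)
        sph = ff.sphere_amplitude(q200, R, sld - W) ** 2
        assert np.max(np.abs(tri - sph)) <= 1e-10 * np.max(sph)


class TestVesicle:
    def test_zero_contrast_zero_intensity(self, dppc_ledger, q200):
        s = dppc_ledger.solvent_sld
        p = VesicleParams(sld_head=s, sld_tail=s)
        c = vesicle_intensity(p, dppc_ledger, q200)
        assert np.allclose(c.intensity, 0.0)

    def test_forward_intensity_from_composition(self, q200):
        p = VesicleParams(radius_polydispersity=0.0, number_density=1e13)
        m = VesicleModel(p, W)
        i0 = m.intensity(np.array([1e-9])).intensity[0]
        expected = 1e13 * m.total_excess_scattering() ** 2 * A2_TO_CM2
        assert i0 == pytest.approx(expected, rel=1e-6)

    def test_excessive_polydispersity_rejected(self):
        with pytest.raises(ValueError):
            VesicleModel(VesicleParams(radius_polydispersity=0.55), W)

    def test_d_spacing_must_exceed_bilayer(self):
        with pytest.raises(ValueError):
            VesicleModel(VesicleParams(f_multilamellar=0.3, n_layers=3,
                                       d_spacing=30.0), W)

    def test_lipids_per_particle_scale(self, dppc_ledger):
        m = VesicleModel.from_ledger(dppc_ledger, "DPPC",
                                     VesicleParams(radius_polydispersity=0.0))
        # ~2.5e4 lipids in a 50-nm vesicle; order-of-magnitude sanity
        assert 5e3 < m.lipids_per_particle < 1e5


class TestMicelle:
    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            MicelleParams(hs_volume_fraction=0.8).validate()

    def test_beta_is_unity_for_sphere(self, q200):
        # isotropic particle: decoupling beta = <A>^2/<A^2> = 1, so S_eff = S
        p = MicelleParams(shape="fuzzy_sphere", core_a=20.0, core_b=20.0,
                          core_c=20.0, shell_thickness=10.0,
                          fuzziness_sigma=0.0, hs_volume_fraction=0.2,
                          hs_radius=30.0)
        m = MicelleModel(p, W)
        sq, amp = m._form_moments(q200)
        s_py = py_hard_sphere_sq(q200, 30.0, 0.2)
        np.testing.assert_allclose(m.mean_sq_amplitude(q200), sq * s_py,
                                   rtol=1e-10)

    def test_aggregation_number_from_core_volume(self):
        led = CompositionLedger.from_names({"SDS": 10.0})
        p = MicelleParams(core_a=16.0, core_b=16.0, core_c=24.0)
        m = MicelleModel.from_ledger(led, "SDS", p)
        v_core = 4 / 3 * np.pi * 16 * 16 * 24
        assert m.params.aggregation_number == pytest.approx(
            v_core / led.species["SDS"].volume_tail)


class TestBicelle:
    def test_disc_has_deeper_minimum_than_equal_volume_oblate(self, q200):
        """A disc with radius ~ thickness shows a deeper intermediate-Q
        minimum than an oblate ellipsoid of the same volume and height."""
        sld = 1.1e-5
        R, h = 40.0, 17.0  # thickness 34 A ~ radius
        i_disc = ff.disc_orientavg_intensity(q200, R, 0.0, h, 1e-9,
                                             sld, sld, sld, W)
        a_eq = np.sqrt(1.5) * R  # same volume at the same half-height
        i_ell = ff.ellipsoid_orientavg_intensity(q200, [((a_eq, a_eq, h), sld)], W)
        win = (q200 > 0.05) & (q200 < 0.35)
        depth_disc = i_disc[win].min() / i_disc[0]
        depth_ell = i_ell[win].min() / i_ell[0]
        assert depth_disc < depth_ell

    def test_rim_sld_with_zero_detergent_is_lipid(self):
        led = CompositionLedger.from_names({"DMPC": 2.5, "SDS": 0.0})
        bp = BicelleParams(rim_detergent_fraction=0.0)
        m = BicelleModel.from_ledger(led, "DMPC", "SDS", bp)
        assert m.params.sld_rim == pytest.approx(led.species["DMPC"].sld_mean)

    def test_forward_intensity_volume_sum(self, q200):
        p = BicelleParams()
        m = BicelleModel(p, W)
        i0 = m.mean_sq_amplitude(np.array([1e-9]))[0]
        assert i0 == pytest.approx(m.total_excess_scattering() ** 2, rel=1e-6)


class TestWorm:
    def test_rigid_parametrization_is_named_rod(self):
        assert WormModel(WormParams(kuhn_length=5000.0)).name == "rod"
        assert WormModel(WormParams(kuhn_length=100.0)).name == "worm"

    def test_nonnegative_intensity(self, q200):
        for kuhn in (100.0, 900.0):
            m = WormModel(WormParams(kuhn_length=kuhn), W)
            assert np.all(m.mean_sq_amplitude(q200) >= 0)


@pytest.mark.parametrize("build", [
    lambda: VesicleModel(VesicleParams(f_multilamellar=0.3, n_layers=4), W),
    lambda: MicelleModel(MicelleParams(hs_volume_fraction=0.2), W),
    lambda: MicelleModel(MicelleParams(shape="triaxial", core_b=20.0), W),
    lambda: MicelleModel(MicelleParams(shape="fuzzy_sphere", core_b=16.0,
                                       core_c=16.0, fuzziness_sigma=4.0), W),
    lambda: BicelleModel(BicelleParams(), W),
    lambda: WormModel(WormParams(), W),
    lambda: AsymmetricVesicleModel(AsymmetricBilayerParams(x_in=0.1,
                                                           x_out=0.4), W),
])
def test_all_models_nonnegative_finite(build, q200):
    i_q = build().mean_sq_amplitude(q200)
    assert np.all(np.isfinite(i_q)) and np.all(i_q >= 0)
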