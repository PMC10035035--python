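"""Coexistence mixtures, conservation constraints and kinetic trajectories."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from solusaxs.composition import CompositionLedger
from solusaxs.curves import QGrid
from solusaxs.mixtures import (
    ConstraintViolation,
    KineticSeries,
    PopulationMixture,
    fit_kinetic_series,
    fit_trajectory,
    mixture_intensity,
    solubilized_fraction_trajectory,
)
from solusaxs.models import (
    BicelleModel,
    BicelleParams,
    VesicleModel,
    VesicleParams,
)
from solusaxs.synthetic import InstrumentEmulation, scenario_fixtures


@pytest.fixture()
def coex_setup():
    ledger = CompositionLedger.from_names({"DPPC": 2.5, "SDS": 10.0})
    vesicle = VesicleModel.from_ledger(
        ledger, "DPPC", VesicleParams(mean_radius=240.0, tail_thickness=34.0))
    bicelle = BicelleModel.from_ledger(ledger, "DPPC", "SDS", BicelleParams())
    return ledger, vesicle, bicelle


def test_single_population_weight_one_is_bit_identical(coex_setup, q200):
    ledger, vesicle, bicelle = coex_setup
    mix = PopulationMixture([(vesicle, 1.0, 0.0), (bicelle, 0.0, 0.0)],
                            mode="mass-conserving")
    i_mix = mixture_intensity(mix, ledger, q200, "DPPC", "SDS").intensity
    n = ledger.number_concentration("DPPC") / vesicle.lipids_per_particle
    i_single = vesicle.intensity(q200, number_density=n).intensity
    np.testing.assert_array_equal(i_mix, i_single)


def test_mixture_linearity(coex_setup, q200):
    """Joint evaluation equals the sum of individually evaluated curves."""
    ledger, vesicle, bicelle = coex_setup
    mix = PopulationMixture([(vesicle, 0.4, 0.0), (bicelle, 0.6, 0.8)])
    i_joint = mixture_intensity(mix, ledger, q200, "DPPC", "SDS").intensity
    parts = []
    for model, fl, fd in mix.populations:
        m1 = PopulationMixture([(model, fl, fd)], mode="free")
        parts.append(mixture_intensity(m1, ledger, q200, "DPPC", "SDS").intensity)
    np.testing.assert_allclose(i_joint, sum(parts), rtol=1e-12)


def test_mass_conservation_violations(coex_setup):
    _, vesicle, bicelle = coex_setup
    with pytest.raises(ConstraintViolation):
        PopulationMixture([(vesicle, 0.5, 0.0), (bicelle, 0.3, 0.0)],
                          mode="mass-conserving")
    with pytest.raises(ConstraintViolation):
        PopulationMixture([(vesicle, 0.5, 0.7), (bicelle, 0.5, 0.7)],
                          mode="mass-conserving")
    # same fractions are fine when unconstrained
    PopulationMixture([(vesicle, 0.5, 0.0), (bicelle, 0.3, 0.0)], mode="free")


def test_lipid_conservation_across_densities(coex_setup):
    ledger, vesicle, bicelle = coex_setup
    mix = PopulationMixture([(vesicle, 0.35, 0.0), (bicelle, 0.65, 0.9)])
    n_v, n_b = mix.number_densities(ledger, "DPPC", "SDS")
    total = (n_v * vesicle.lipids_per_particle
             + n_b * bicelle.lipids_per_particle)
    assert total == pytest.approx(ledger.number_concentration("DPPC"), rel=1e-12)


class TestTrajectories:
    def test_boundary_values(self):
        p = {"f_start": 0.1, "f_end": 0.8, "k": 0.05}
        for model in ("single_exp", "stretched_exp", "two_stage"):
            f = solubilized_fraction_trajectory(np.array([0.0, 1e9]), model, p)
            assert f[0] == pytest.approx(0.1)
            assert f[-1] == pytest.approx(0.8, abs=1e-6)

    def test_single_exp_halftime(self):
        k = 0.02
        t_half = np.log(2) / k
        f = solubilized_fraction_trajectory(
            np.array([t_half]), "single_exp", {"f_start": 0.0, "f_end": 1.0, "k": k})
        assert f[0] == pytest.approx(0.5, rel=1e-12)

    def test_two_stage_holds_through_lag(self):
        p = {"f_start": 0.0, "f_end": 1.0, "k": 0.5, "t_lag": 10.0}
        f = solubilized_fraction_trajectory(np.array([0.0, 5.0, 10.0, 11.0]),
                                            "two_stage", p)
        assert np.all(f[:3] == 0.0) and f[3] > 0.0

    @given(t=st.lists(st.floats(0, 1e5), min_size=2, max_size=20),
           k=st.floats(1e-4, 10.0), f0=st.floats(0, 1), f1=st.floats(0, 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bounded_and_monotone(self, t, k, f0, f1):
        t = np.sort(np.asarray(t))
        f = solubilized_fraction_trajectory(
            t, "single_exp", {"f_start": f0, "f_end": f1, "k": k})
        assert np.all((f >= -1e-12) & (f <= 1 + 1e-12))
        d = np.diff(f)
        assert np.all(d >= -1e-12) if f1 >= f0 else np.all(d <= 1e-12)

    def test_rate_recovery_from_noisy_trajectory(self):
        rng = np.random.default_rng(8)
        k_true = 0.05
        t = np.linspace(1.0, 120.0, 20)
        f = solubilized_fraction_trajectory(
            t, "single_exp", {"f_start": 0.0, "f_end": 0.7, "k": k_true})
        noisy = np.clip(f + rng.normal(0, 0.01, t.size), 0, 1)
        fitted = fit_trajectory(t, noisy, "single_exp")
        assert fitted["k"] == pytest.approx(k_true, rel=0.10)


class TestKineticSeries:
    def test_times_must_increase(self, q200):
        from solusaxs.curves import ScatteringCurve
        c = ScatteringCurve(q200, np.ones_like(q200))
        with pytest.raises(ValueError):
            KineticSeries([(1.0, c), (1.0, c)])

    def test_staged_series_recovered_per_frame(self):
        inst = InstrumentEmulation(n_points=250)
        fx = scenario_fixtures("dmpc_sds_20C_1to2", 11, inst)
        table = fit_kinetic_series(
            KineticSeries(fx["frames"]), fx["models"]["vesicle"],
            fx["models"]["solubilized"], fx["ledger"], "DMPC", "SDS")
        truth = np.array(fx["manifest"]["fractions"])
        assert np.max(np.abs(table["fraction"].values - truth)) < 0.05

    def test_frame_order_invariance(self):
        inst = InstrumentEmulation(n_points=120)
        fx = scenario_fixtures("dmpc_sds_20C_1to2", 2, inst)
        frames = fx["frames"]
        args = (fx["models"]["vesicle"], fx["models"]["solubilized"],
                fx["ledger"], "DMPC", "SDS")
        t1 = fit_kinetic_series(KineticSeries(frames), *args)
        shuffled = [frames[i] for i in (3, 0, 5, 1, 7, 2, 6, 4)]
        t2 = fit_kinetic_series(
            KineticSeries(sorted(shuffled, key=lambda f: f[0])), *args)
        np.testing.assert_array_equal(t1["fraction"].values,
                                      t2["fraction"].values)

    def test_mismatched_q_grids_rejected(self, coex_setup):
        from solusaxs.curves import ScatteringCurve
        ledger, vesicle, bicelle = coex_setup
        qa = QGrid.geomspace(n=50).values
        qb = QGrid.geomspace(n=60).values
        frames = [(t, ScatteringCurve(q, np.ones_like(q)))
                  for t, q in [(1.0, qa), (2.0, qb), (3.0, qa)]]
        with pytest.raises(ValueError, match="Q grid"):
            fit_kinetic_series(KineticSeries(frames), vesicle, bicelle,
                               ledger, "DPPC")
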