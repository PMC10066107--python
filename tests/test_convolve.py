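"""Convolution engine: UIR, ODE/quadrature/exponential-integrator agreement,
superposition and mass balance."""

import numpy as np
import pytest

from convopk.convolve import (
    ConcentrationProfile,
    DispositionParams,
    DoseEvent,
    simulate_expint,
    simulate_ode,
    simulate_quadrature,
    superpose,
    unit_impulse_response,
)
from convopk.release import ReleaseParams

ONE_CPT = DispositionParams(CL=7.0, V=100.0)


class TestUnitImpulseResponse:
    def test_initial_value_is_inverse_volume(self):
        assert unit_impulse_response(0.0, DispositionParams(CL=5, V=100)) == 0.01

    def test_halves_at_elimination_half_life(self):
        d = DispositionParams(CL=7, V=100)
        t_half = np.log(2) / d.kel
        assert unit_impulse_response(t_half, d) == pytest.approx(0.005, rel=1e-12)

    def test_two_compartment_with_zero_q_reduces_to_one(self):
        d1 = DispositionParams(CL=7, V=100)
        d2 = DispositionParams(CL=7, V=100, n_compartments=2, Q=0.0, V2=50.0)
        t = np.linspace(0, 100, 50)
        np.testing.assert_allclose(
            unit_impulse_response(t, d2), unit_impulse_response(t, d1), rtol=1e-10
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(CL=-1, V=100),
            dict(CL=7, V=0),
            dict(CL=7, V=100, Q=5.0),  # Q without 2 compartments
            dict(CL=7, V=100, n_compartments=2),  # missing Q/V2
            dict(CL=7, V=100, n_compartments=3, Q=1, V2=1),
        ],
    )
    def test_invalid_disposition_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DispositionParams(**kwargs)


class TestSimulateOde:
    def test_zero_dose_gives_zero_profile(self):
        rp = ReleaseParams("weibull1", TD=5, SS=2)
        grid = np.linspace(0, 48, 20)
        prof = simulate_ode(DoseEvent(0.0, 0.0), rp, ONE_CPT, grid)
        assert np.all(prof.conc == 0)

    def test_fast_release_approaches_bolus(self):
        # near-instantaneous release: profile must match the IV-bolus curve
        rp = ReleaseParams("weibull1", TD=1e-3, SS=5.0)
        grid = np.linspace(0.1, 72, 80)
        prof = simulate_ode(DoseEvent(0.0, 100.0), rp, ONE_CPT, grid)
        bolus = (100.0 / 100.0) * np.exp(-0.07 * grid) * 1000.0
        np.testing.assert_allclose(prof.conc, bolus, rtol=1e-3)

    def test_linearity_in_dose(self):
        rp = ReleaseParams("weibull1", TD=5, SS=2)
        grid = np.linspace(0, 96, 40)
        c1 = simulate_ode(DoseEvent(0, 50.0), rp, ONE_CPT, grid).conc
        c2 = simulate_ode(DoseEvent(0, 100.0), rp, ONE_CPT, grid).conc
        np.testing.assert_allclose(c2, 2.0 * c1, rtol=1e-7, atol=1e-12)

    def test_finite_difference_rate_option_matches_analytic(self, pp3m):
        grid = np.geomspace(1.0, 2000.0, 30)
        a = simulate_ode(DoseEvent(0, 350), pp3m.release, pp3m.disposition, grid)
        f = simulate_ode(
            DoseEvent(0, 350), pp3m.release, pp3m.disposition, grid, rate="fd"
        )
        np.testing.assert_allclose(f.conc, a.conc, rtol=1e-5)

    def test_grid_must_cover_dose_times(self):
        rp = ReleaseParams("weibull1", TD=5, SS=2)
        with pytest.raises(ValueError, match="cover all dose times"):
            simulate_ode(DoseEvent(100.0, 10.0), rp, ONE_CPT, np.linspace(0, 50, 10))

    def test_mass_balance_eliminated_equals_absorbed(self, er):
        # CL * integral(Cp) must approach F * dose once release and washout
        # are complete (0.5% on a long, fine grid)
        grid = np.linspace(0.0, 400.0, 4001)
        prof = simulate_ode(DoseEvent(0, 6.0), er.release, er.disposition, grid)
        eliminated = er.disposition.CL * np.trapezoid(prof.conc / 1000.0, prof.times)
        assert eliminated == pytest.approx(6.0, rel=5e-3)

    def test_flip_flop_terminal_slope_reflects_release_rate(self):
        # release time scale (1000 h) >> V/CL (14 h): the terminal log-slope
        # must equal the release rate constant, not the elimination rate
        rp = ReleaseParams("exponential", TD=1000.0)
        grid = np.linspace(0, 9000, 300)
        prof = simulate_ode(DoseEvent(0, 100.0), rp, ONE_CPT, grid)
        m = prof.times > 5000
        slope = np.polyfit(prof.times[m], np.log(prof.conc[m]), 1)[0]
        assert slope == pytest.approx(-1.0 / 1000.0, rel=0.01)
        assert abs(slope) < 0.1 * ONE_CPT.kel


class TestEngineAgreement:
    """The same convolution model realized three ways must agree."""

    @pytest.mark.parametrize("name", ["ER", "PP1M", "PP3M"])
    def test_ode_vs_quadrature_on_presets(self, presets, name):
        p = presets[name]
        grid = np.asarray(p.schedule_h)
        dose = DoseEvent(0.0, p.doses_mg[-1])
        ode = simulate_ode(dose, p.release, p.disposition, grid)
        quad = simulate_quadrature(dose, p.release, p.disposition, grid)
        scale = np.maximum(quad.conc, quad.conc.max() * 1e-9)
        assert np.max(np.abs(ode.conc - quad.conc) / scale) < 1e-4

    @pytest.mark.parametrize("name", ["ER", "PP1M", "PP3M", "PP12M"])
    def test_expint_vs_ode_on_presets(self, presets, name):
        p = presets[name]
        grid = np.asarray(p.schedule_h)
        dose = DoseEvent(0.0, p.doses_mg[0])
        ode = simulate_ode(dose, p.release, p.disposition, grid)
        fast = simulate_expint(dose, p.release, p.disposition, grid)
        scale = np.maximum(ode.conc, ode.conc.max() * 1e-9)
        assert np.max(np.abs(fast.conc - ode.conc) / scale) < 1e-5

    def test_exponential_release_matches_first_order_absorption_closed_form(self):
        # r(t) = 1 - exp(-ka t) convolved with a 1-cpt UIR is the textbook
        # first-order absorption model
        tau, F, D, V, CL = 5.0, 1.0, 100.0, 100.0, 7.0
        ka, kel = 1 / tau, CL / V
        rp = ReleaseParams("exponential", TD=tau)
        grid = np.linspace(0.5, 96, 60)
        closed = (ka / (ka - kel)) * (F * D / V) * (
            np.exp(-kel * grid) - np.exp(-ka * grid)
        ) * 1000.0
        quad = simulate_quadrature(DoseEvent(0, D), rp, DispositionParams(CL=CL, V=V), grid)
        np.testing.assert_allclose(quad.conc, closed, rtol=1e-6)


class TestSuperposition:
    def test_single_dose_identity(self, pp3m):
        grid = np.asarray(pp3m.schedule_h)
        single = simulate_ode(
            DoseEvent(0, 350.0), pp3m.release, pp3m.disposition, grid,
            metadata={"dose_mg": 350.0},
        )
        out = superpose(single, [DoseEvent(0.0, 350.0)])
        np.testing.assert_allclose(out.conc, single.conc, rtol=1e-9)

    def test_widely_separated_doses_repeat_the_first_peak(self):
        rp = ReleaseParams("weibull1", TD=2.0, SS=2.0)
        tau = 2000.0  # many elimination half-lives: complete washout
        grid = np.linspace(0.0, 2 * tau, 8001)
        single = simulate_ode(
            DoseEvent(0, 100.0), rp, ONE_CPT, grid, metadata={"dose_mg": 100.0}
        )
        both = superpose(single, [DoseEvent(0, 100.0), DoseEvent(tau, 100.0)])
        first = both.conc[(grid > 0) & (grid <= tau)].max()
        second = both.conc[grid > tau].max()
        assert second == pytest.approx(first, rel=1e-3)

    def test_repeated_three_monthly_doses_match_multidose_ode(self, pp3m):
        doses = [DoseEvent(i * 2160.0, 350.0) for i in range(12)]
        grid = np.linspace(0.0, 12 * 2160.0, 2500)
        fine = np.unique(np.concatenate([np.geomspace(0.25, 2160 * 12, 4000), grid]))
        single = simulate_expint(
            DoseEvent(0, 350.0), pp3m.release, pp3m.disposition, fine,
            metadata={"dose_mg": 350.0},
        )
        sup = superpose(single, doses, grid=grid)
        ode = simulate_ode(doses, pp3m.release, pp3m.disposition, grid)
        scale = np.maximum(ode.conc, ode.conc.max() * 1e-6)
        assert np.max(np.abs(sup.conc - ode.conc) / scale) < 1e-4

    def test_superposition_and_time_invariance_on_random_regimens(self, pp1m, rng):
        # 20 random regimens: multi-dose response equals the sum of shifted
        # single-dose responses (linearity + time invariance)
        grid = np.linspace(0.0, 6000.0, 600)
        fine = np.unique(np.concatenate([np.geomspace(0.1, 6000.0, 3000), grid]))
        unit = simulate_expint(
            DoseEvent(0, 1.0), pp1m.release, pp1m.disposition, fine,
            metadata={"dose_mg": 1.0},
        )
        for _ in range(20):
            n = int(rng.integers(2, 6))
            times = np.sort(rng.uniform(0.0, 3000.0, n))
            amounts = rng.uniform(10.0, 200.0, n)
            doses = [DoseEvent(float(t), float(a)) for t, a in zip(times, amounts)]
            multi = simulate_expint(doses, pp1m.release, pp1m.disposition, grid)
            sup = superpose(unit, doses, grid=grid)
            scale = np.maximum(multi.conc, multi.conc.max() * 1e-4)
            assert np.max(np.abs(sup.conc - multi.conc) / scale) < 2e-3

    def test_grid_shorter_than_regimen_rejected(self, pp3m):
        grid = np.linspace(0, 100, 50)
        single = simulate_ode(
            DoseEvent(0, 350.0), pp3m.release, pp3m.disposition, grid,
            metadata={"dose_mg": 350.0},
        )
        with pytest.raises(ValueError, match="extend the grid"):
            superpose(single, [DoseEvent(0, 350.0)], grid=np.linspace(0, 500, 20))


class TestConcentrationProfile:
    def test_csv_roundtrip(self, tmp_path):
        prof = ConcentrationProfile(
            np.array([0.0, 1.0, 2.0]), np.array([0.0, 5.5, 3.25]),
            {"product": "demo", "dose_mg": 10},
        )
        path = tmp_path / "prof.csv"
        prof.to_csv(path)
        back = ConcentrationProfile.from_csv(path)
        np.testing.assert_array_equal(back.times, prof.times)
        np.testing.assert_array_equal(back.conc, prof.conc)
        assert back.metadata["product"] == "demo"

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ConcentrationProfile(np.array([0.0, 1.0, 1.0]), np.zeros(3))

    def test_tiny_negative_solver_noise_clipped(self):
        prof = ConcentrationProfile(np.array([0.0, 1.0]), np.array([1.0, -1e-9]))
        assert prof.conc[1] == 0.0
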