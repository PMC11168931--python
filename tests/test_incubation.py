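"""Vial gas kinetics: rate corrections, Henry conversions, biokinetic fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from n2osink import incubation as inc
from n2osink.bethedge import BetHedgeParams, simulate
from n2osink.incubation import (GasSeries, RateSeries, VialSpec,
                                aqueous_from_ppmv, cell_trajectory,
                                dissolved_concentration, electron_flow,
                                fit_growth_rate, fit_michaelis_menten,
                                growth_yield, henry_equilibrium,
                                interval_rates, o2_onset_threshold,
                                specific_rates)


def make_rates(times_h, rates_mol_h, gas="O2") -> RateSeries:
    t = np.asarray(times_h, float)
    r = np.asarray(rates_mol_h, float)
    cum = np.concatenate([[0.0], np.cumsum(r * np.diff(t))])
    return RateSeries(gas=gas, interval_midpoints_h=0.5 * (t[:-1] + t[1:]),
                      rate_mol_h=r, interval_edges_h=t, cumulative_mol=cum)


# ---------------------------------------------------------------------------
# domain-type validation
# ---------------------------------------------------------------------------

class TestValidation:
    def test_vial_rejects_bad_geometry(self):
        with pytest.raises(ValueError):
            VialSpec(liquid_volume_ml=0.0)
        with pytest.raises(ValueError):
            VialSpec(sample_volume_ml=80.0, headspace_volume_ml=70.0)
        with pytest.raises(ValueError):
            VialSpec(kla=-1.0)

    def test_series_rejects_non_monotone_times(self):
        with pytest.raises(ValueError):
            GasSeries("O2", [0.0, 1.0, 1.0], [1e-5, 1e-5, 1e-5])

    def test_sampling_event_must_coincide_with_measurement(self):
        with pytest.raises(ValueError):
            GasSeries("O2", [0.0, 1.0], [1e-5, 1e-5], sampling_events_h=[0.5])


# ---------------------------------------------------------------------------
# interval rates
# ---------------------------------------------------------------------------

class TestIntervalRates:
    def test_no_corrections_reduce_to_difference_quotients(self):
        vial = VialSpec(sample_volume_ml=0.0, leak_coefficient=0.0)
        s = GasSeries("O2", [0.0, 1.0, 2.0], np.array([10, 8, 6]) * 1e-6)
        rs = interval_rates(s, vial)
        np.testing.assert_allclose(rs.rate_mol_h, [-2e-6, -2e-6])
        np.testing.assert_allclose(rs.cumulative_consumption_mol,
                                   [0.0, 2e-6, 4e-6])

    def test_sampling_dilution_bookkeeping(self):
        # 10% of headspace sampled right after the t=0 reading:
        # biological consumption = 10*0.9 - 8 = 1 umol over the interval
        vial = VialSpec(headspace_volume_ml=70.0, sample_volume_ml=7.0)
        s = GasSeries("N2O", [0.0, 1.0], [10e-6, 8e-6], sampling_events_h=[0.0])
        rs = interval_rates(s, vial)
        np.testing.assert_allclose(rs.rate_mol_h, [-1e-6])

    def test_leak_balanced_by_production(self):
        # constant amount with an outward leak implies production A*lambda
        lam = 0.05
        vial = VialSpec(sample_volume_ml=0.0, leak_coefficient=lam)
        a = 5e-6
        s = GasSeries("N2", [0.0, 2.0, 4.0], [a, a, a])
        rs = interval_rates(s, vial)
        np.testing.assert_allclose(rs.rate_mol_h, a * lam, rtol=1e-12)

    def test_leak_closed_form_exponential(self):
        # pure leak, no biology: A(t) = A0 exp(-lam t) gives rate 0
        lam, a0 = 0.1, 1e-5
        vial = VialSpec(sample_volume_ml=0.0, leak_coefficient=lam)
        t = np.array([0.0, 1.0, 3.0])
        s = GasSeries("N2O", t, a0 * np.exp(-lam * t))
        rs = interval_rates(s, vial)
        np.testing.assert_allclose(rs.rate_mol_h, 0.0, atol=1e-20)

    def test_rejects_single_point(self):
        vial = VialSpec()
        s = GasSeries("O2", [0.0], [1e-5])
        with pytest.raises(ValueError):
            interval_rates(s, vial)


# ---------------------------------------------------------------------------
# Henry equilibria and dissolved concentrations
# ---------------------------------------------------------------------------

class TestHenry:
    def test_zero_maps_to_zero(self):
        assert henry_equilibrium(0.0, "N2O", 15.0) == 0.0

    def test_n2o_at_15c_matches_published_equivalence(self):
        # 12.9 uM N2O ~= 389 ppmv in the gas phase at 15 degC
        assert henry_equilibrium(12.9, "N2O", 15.0) == pytest.approx(389.0, rel=0.02)

    @given(st.floats(1e-3, 1e4), st.floats(0.5, 39.5),
           st.sampled_from(["N2O", "O2"]))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity(self, ppmv, temp, gas):
        back = henry_equilibrium(aqueous_from_ppmv(ppmv, gas, temp), gas, temp)
        assert back == pytest.approx(ppmv, rel=1e-10)

    def test_unsupported_gas_rejected(self):
        with pytest.raises(ValueError):
            henry_equilibrium(1.0, "CH4", 15.0)

    def test_o2_solubility_magnitude(self):
        # air-saturated fresh water at 15 degC holds ~315 uM O2
        c = aqueous_from_ppmv(209460.0, "O2", 15.0)
        assert c == pytest.approx(315.0, rel=0.02)


class TestDissolved:
    def test_no_flux_equilibrium(self):
        vial = VialSpec()
        t = np.array([0.0, 1.0, 2.0])
        s = GasSeries("N2O", t, np.full(3, 5e-5))
        rs = make_rates(t, [0.0, 0.0], gas="N2O")
        d = dissolved_concentration(s, vial, rs)
        from n2osink.constants import ppmv_from_mol_per_vial
        ppmv = ppmv_from_mol_per_vial(5e-5, vial.headspace_volume_ml,
                                      vial.temperature_c)
        expect = aqueous_from_ppmv(ppmv, "N2O", vial.temperature_c)
        np.testing.assert_allclose(d.concentration_um, expect, rtol=1e-12)

    def test_linear_offset_by_consumption(self):
        vial = VialSpec(kla=10.0, liquid_volume_ml=50.0)
        t = np.array([0.0, 1.0])
        s = GasSeries("N2O", t, np.full(2, 5e-5))
        # choose r so that r/(kla*V_liq) = 5 uM
        r = 5e-6 * 10.0 * 0.05  # mol/h
        d0 = dissolved_concentration(s, vial, make_rates(t, [0.0], "N2O"))
        d1 = dissolved_concentration(s, vial, make_rates(t, [-r], "N2O"))
        np.testing.assert_allclose(d0.concentration_um - d1.concentration_um,
                                   5.0, rtol=1e-9)

    def test_zero_kla_with_consumption_rejected(self):
        vial = VialSpec(kla=0.0)
        t = np.array([0.0, 1.0])
        s = GasSeries("N2O", t, [5e-5, 4e-5])
        with pytest.raises(ValueError):
            dissolved_concentration(s, vial, make_rates(t, [-1e-5], "N2O"))

    def test_matches_simulator_liquid_state_when_transfer_fast(self):
        # re-infer dissolved N2O from simulated headspace; fast kla
        vial = VialSpec(kla=100.0, sample_volume_ml=0.0)
        params = BetHedgeParams(f_nosz=1.0)
        sim = simulate(params, vial, {"O2": 2e-5, "N2O": 1e-4},
                       t_end_h=40.0, n_output=800)
        s = GasSeries("N2O", sim.times_h, sim.n2o_headspace_mol)
        rs = interval_rates(s, vial)
        d = dissolved_concentration(s, vial, rs)
        truth = np.interp(d.times_h, sim.times_h, sim.n2o_aq_um)
        mask = truth > 20.0   # compare while N2O is well above depletion
        assert mask.sum() > 50
        np.testing.assert_allclose(d.concentration_um[mask], truth[mask],
                                   rtol=0.05)


# ---------------------------------------------------------------------------
# cells and specific rates
# ---------------------------------------------------------------------------

class TestCellsAndSpecificRates:
    def test_zero_consumption_keeps_n_ini(self):
        t = np.array([0.0, 1.0, 2.0])
        traj = cell_trajectory(1e8, 5e13, 2e13, make_rates(t, [0.0, 0.0]))
        np.testing.assert_allclose(traj.n_cells, 1e8)

    def test_direct_arithmetic(self):
        # n_ini 1e8 + 5e13 cells/mol * 1e-5 mol = 6e8 cells
        t = np.array([0.0, 1.0])
        traj = cell_trajectory(1e8, 5e13, 0.0, make_rates(t, [-1e-5]))
        assert traj.n_cells[-1] == pytest.approx(6e8)

    def test_negative_yield_rejected(self):
        t = np.array([0.0, 1.0])
        with pytest.raises(ValueError):
            cell_trajectory(1e8, -5e13, 0.0, make_rates(t, [-1e-5]))

    def test_matches_simulator_biomass(self, reference_sim, default_params,
                                       default_vial):
        # cumulated consumptions must include the dissolved-inventory draw-down;
        # observations on the GC schedule itself (one reading per sampling)
        sim = reference_sim
        sched = np.arange(1.0, 60.0, 1.0)
        grid = np.concatenate([[0.0], sched])
        keep = np.isin(sim.times_h, grid)

        def series_at_schedule(gas):
            full = sim.headspace_series(gas)
            return GasSeries(gas=gas, times_h=full.times_h[keep],
                             amount_mol=full.amount_mol[keep],
                             sampling_events_h=sched)

        o2 = inc.liquid_corrected_rates(series_at_schedule("O2"), default_vial)
        n2o = inc.liquid_corrected_rates(series_at_schedule("N2O"), default_vial)
        traj = cell_trajectory(default_params.n_ini, default_params.y_o2,
                               default_params.y_n2o, o2, n2o)
        truth = np.interp(traj.times_h, sim.times_h, sim.cells_total)
        np.testing.assert_allclose(traj.n_cells, truth, rtol=0.01)

    def test_specific_rate_arithmetic(self):
        # 1 umol/h over 1e9 cells = 1 fmol/cell/h
        t = np.array([0.0, 1.0])
        rs = make_rates(t, [1e-6])
        traj = cell_trajectory(1e9, 0.0, 0.0, make_rates(t, [0.0]))
        np.testing.assert_allclose(specific_rates(rs, traj), [1.0])

    def test_specific_rate_approaches_vmax_during_unrestricted_growth(
            self, reference_sim, default_params, default_vial):
        sim = reference_sim
        sched = np.arange(1.0, 60.0, 1.0)
        o2 = interval_rates(sim.headspace_series("O2", sched), default_vial)
        traj = cell_trajectory(default_params.n_ini, default_params.y_o2,
                               default_params.y_n2o, o2)
        v = -specific_rates(o2, traj)
        d = dissolved_concentration(sim.headspace_series("O2", sched),
                                    default_vial, o2)
        # during O2-saturated growth the cell-specific rate ~ V_max
        v_max_true = default_params.mu_max_o2 / default_params.y_o2 * 1e15
        sat = d.concentration_um > 30.0    # >> K_m = 0.9 uM
        assert sat.sum() > 3
        assert np.median(v[sat][2:]) == pytest.approx(v_max_true, rel=0.05)

    def test_zero_cells_rejected(self):
        t = np.array([0.0, 1.0])
        traj = cell_trajectory(0.0, 0.0, 0.0, make_rates(t, [0.0]))
        with pytest.raises(ValueError):
            specific_rates(make_rates(t, [1e-6]), traj)


# ---------------------------------------------------------------------------
# growth-rate and Michaelis-Menten fitting
# ---------------------------------------------------------------------------

class TestGrowthRateFit:
    def test_exact_exponential_recovered(self):
        t = np.linspace(0.0, 10.0, 12)
        mids = 0.5 * (t[:-1] + t[1:])
        r = -1e-6 * np.exp(0.29 * mids)
        fit = fit_growth_rate(make_rates(t, r))
        assert fit.mu == pytest.approx(0.29, abs=1e-9)

    def test_constant_rates_give_zero_mu(self):
        t = np.linspace(0.0, 5.0, 8)
        fit = fit_growth_rate(make_rates(t, np.full(7, -1e-6)))
        assert fit.mu == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_rates_rejected(self):
        t = np.linspace(0.0, 5.0, 8)
        with pytest.raises(ValueError):
            fit_growth_rate(make_rates(t, np.zeros(7)), window_h=(0.0, 5.0))

    def test_monte_carlo_bias_below_two_percent(self):
        # lognormal noise CV 5%, n=10, 200 replicates
        rng = np.random.default_rng(42)
        t = np.linspace(0.0, 9.0, 11)
        mids = 0.5 * (t[:-1] + t[1:])
        clean = 1e-6 * np.exp(0.29 * mids)
        sigma = np.sqrt(np.log1p(0.05**2))
        mus = []
        for _ in range(200):
            noisy = clean * rng.lognormal(-sigma**2 / 2, sigma, mids.size)
            mus.append(fit_growth_rate(make_rates(t, -noisy),
                                       window_h=(0.0, 9.0)).mu)
        assert abs(np.mean(mus) - 0.29) / 0.29 < 0.02


class TestMichaelisMenten:
    def test_exact_data_recovered_to_machine_precision(self):
        c = np.linspace(0.5, 120.0, 25)
        v = 0.66 * c / (12.9 + c)
        fit = fit_michaelis_menten(v, c)
        assert fit.v_max == pytest.approx(0.66, rel=1e-8)
        assert fit.k_m == pytest.approx(12.9, rel=1e-8)

    def test_flat_data_flags_saturation_boundary(self):
        c = np.linspace(1.0, 100.0, 10)
        fit = fit_michaelis_menten(np.full(10, 0.5), c)
        assert fit.at_boundary

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_michaelis_menten([0.1, 0.2, 0.3], [1.0, 2.0, 3.0])

    def test_monte_carlo_km_error_below_ten_percent(self):
        # additive noise sd = 2% of V_max, n=20, 500 replicates
        rng = np.random.default_rng(7)
        c = np.linspace(1.0, 100.0, 20)
        clean = 0.66 * c / (12.9 + c)
        errs = []
        for _ in range(500):
            noisy = clean + rng.normal(0.0, 0.02 * 0.66, c.size)
            fit = fit_michaelis_menten(noisy, c)
            errs.append(abs(fit.k_m - 12.9) / 12.9)
        assert np.median(errs) < 0.10


# ---------------------------------------------------------------------------
# electron flow, yields, onset
# ---------------------------------------------------------------------------

class TestElectronFlowAndYield:
    @pytest.mark.parametrize("rate,gas,expected", [
        (0.72, "O2", 2.88),     # ~2.9 fmol e-/cell/h aerobically
        (0.66, "N2O", 1.32),    # ~1.3 fmol e-/cell/h anaerobically
        (0.0, "O2", 0.0),
    ])
    def test_electron_equivalents(self, rate, gas, expected):
        assert electron_flow(rate, gas) == pytest.approx(expected)

    def test_unknown_gas_rejected(self):
        with pytest.raises(ValueError):
            electron_flow(1.0, "CO2")

    def test_perfectly_linear_pairs_give_exact_slope(self):
        g = np.array([1e-5, 2e-5, 3e-5])
        n = 1e8 + 4e14 * g
        fit = growth_yield(n, g, "O2")
        assert fit.y_cells_per_mol == pytest.approx(4e14, rel=1e-12)

    def test_two_points_equal_difference_quotient(self):
        fit = growth_yield([2e8, 5e8], [1e-5, 2e-5], "N2O")
        assert fit.y_cells_per_mol == pytest.approx(3e13, rel=1e-12)

    def test_electron_yield_ratio_recovered(self):
        # anaerobic electron yield generated at 85% of the aerobic one
        cdw = 250.0  # fg/cell
        y_e_o2 = 5.0                     # g CDW per mol e-
        y_o2 = y_e_o2 * 4.0 / (cdw * 1e-15)
        y_e_n2o = 0.85 * y_e_o2
        y_n2o = y_e_n2o * 2.0 / (cdw * 1e-15)
        g = np.array([0.5e-5, 1e-5, 2e-5, 4e-5])
        f_o2 = growth_yield(1e8 + y_o2 * g, g, "O2", cell_dry_weight_fg=cdw)
        f_n2o = growth_yield(1e8 + y_n2o * g, g, "N2O", cell_dry_weight_fg=cdw)
        assert f_n2o.y_e_gcdw_per_mol_e / f_o2.y_e_gcdw_per_mol_e == \
            pytest.approx(0.85, rel=1e-9)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            growth_yield([1e8, 2e8], [1e-5, 1e-5], "O2")


class TestOnset:
    @staticmethod
    def _detect(o2_switch_um):
        vial = VialSpec(sample_volume_ml=0.0)
        params = BetHedgeParams(f_nosz=0.5, o2_switch=o2_switch_um)
        sim = simulate(params, vial, {"O2": 3e-5, "N2O": 1e-4},
                       t_end_h=30.0, n_output=6000)
        t = sim.times_h
        rates = np.diff(-sim.cum_n2o_mol) / np.diff(t)
        rs = make_rates(t, rates, gas="N2O")
        d = inc.DissolvedSeries("O2", t, sim.o2_aq_um)
        return o2_onset_threshold(d, rs, noise_floor_mol_h=1e-9)

    def test_naive_cells_onset_detected_in_band(self):
        res = self._detect(1.5)
        assert res.found and 1.0 <= res.onset_um <= 2.0

    def test_primed_cells_onset_detected_in_band(self):
        res = self._detect(5.0)
        assert res.found and 4.0 <= res.onset_um <= 6.0

    def test_no_consumption_reports_no_onset(self):
        t = np.linspace(0.0, 10.0, 11)
        rs = make_rates(t, np.zeros(10), gas="N2O")
        d = inc.DissolvedSeries("O2", t, np.linspace(200.0, 0.0, 11))
        res = o2_onset_threshold(d, rs)
        assert not res.found
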