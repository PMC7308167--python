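"""ODE assembly, RK4 stepping, conservation and the run driver."""

import math

import numpy as np
import pandas as pd
import pytest

from sulfur_dynamics.forcing import DailyForcing
from sulfur_dynamics.integrator import (
    derivatives,
    equilibrium_spin_up,
    mass_balance_audit,
    rk4_step,
    run_simulation,
    simulate_solution,
)
from sulfur_dynamics.soil_processes import (
    SoilState,
    adsorption_equilibrium,
    adsorption_rate,
    immobilization_rate,
    litterfall,
    mineralization_labile,
    mineralization_stable,
    plant_uptake,
    solution_concentration,
)

LN2 = math.log(2.0)


def day_from_row(row) -> DailyForcing:
    return DailyForcing(**{k: row[k] for k in row.index})


@pytest.fixture()
def quiet_day(constant_forcing):
    # 8 deg C, optimal moisture, no water fluxes, no deposition
    return day_from_row(constant_forcing(1).iloc[0])


class TestDerivatives:
    def test_all_zero_without_forcing(self, quiet_day, exelberg):
        derivs, fluxes = derivatives(SoilState(), quiet_day, exelberg)
        assert all(v == 0.0 for v in derivs.values())
        assert all(v == 0.0 for v in fluxes.values())

    def test_single_stable_pool_pathway(self, quiet_day, exelberg):
        state = SoilState(stable=1000.0)
        derivs, _ = derivatives(state, quiet_day, exelberg)
        lam = LN2 / (exelberg.hl_stable_yr * 365.25)
        assert derivs["stable"] == pytest.approx(-lam * 1000.0)
        assert derivs["sol"] == pytest.approx(lam * 1000.0)
        assert derivs["fol"] == derivs["labile"] == derivs["ads"] == 0.0

    def test_conservation_identity(self, constant_forcing, exelberg):
        # mid-season day with every pathway active
        f = constant_forcing(1, wet_dep=30.0, so2_air=0.004, fog_precip=2.0,
                             infiltration=6.0, percolation=3.0,
                             kc_lai=1.0, doy=200)
        day = day_from_row(f.iloc[0])
        state = SoilState(sol=800.0, fol=400.0, labile=300.0, stable=5000.0,
                          ads=2000.0, acu=50.0)
        derivs, fluxes = derivatives(state, day, exelberg)
        total_rate = sum(derivs.values())
        assert total_rate == pytest.approx(
            fluxes["infiltration_S"] + fluxes["dry"] - fluxes["leaching"],
            rel=1e-12, abs=1e-12)

    def test_matches_hand_assembled_rate_laws(self, constant_forcing, exelberg):
        p = exelberg
        f = constant_forcing(1, wet_dep=12.0, so2_air=0.003, infiltration=4.0,
                             percolation=2.0, kc_lai=0.8, doy=200,
                             soil_temp=12.0, theta=0.2)
        day = day_from_row(f.iloc[0])
        state = SoilState(sol=900.0, fol=350.0, labile=250.0, stable=4000.0,
                          ads=1800.0, acu=10.0)
        derivs, fluxes = derivatives(state, day, p)

        conc = solution_concentration(state.sol, p.z_r, day.theta)
        u_plant = plant_uptake(conc, day.kc_lai, state.acu, p)
        u_micro = immobilization_rate(conc, p, day.soil_temp, day.theta)
        m_st = mineralization_stable(state.stable, p, day.soil_temp, day.theta)
        m_lab = mineralization_labile(state.labile, conc, p, day.soil_temp,
                                      day.theta)
        d_ads = adsorption_rate(
            state.ads, adsorption_equilibrium(conc, p.k_max_ads, p.k_l_ads),
            p.hl_ads_d)
        litter = litterfall(state.fol, day.kc_lai, day.kc_lai, day.doy,
                            day.doy_lc, day.doy_le)
        inf_s = day.wet_dep  # no bypass: all solute infiltrates same day
        leac = state.sol * day.percolation / (p.z_r * day.theta)

        assert derivs["sol"] == pytest.approx(
            inf_s + m_st + m_lab - leac - u_plant - u_micro - d_ads)
        assert derivs["fol"] == pytest.approx(p.f_fol * u_plant - litter)
        organic_in = (1.0 - p.f_fol) * u_plant + litter
        assert derivs["labile"] == pytest.approx(
            p.f_labile * organic_in + u_micro - m_lab)
        assert derivs["stable"] == pytest.approx(
            (1.0 - p.f_labile) * organic_in - m_st)
        assert derivs["ads"] == pytest.approx(d_ads)
        assert fluxes["u_micro"] == pytest.approx(u_micro)

    def test_negative_pool_rejected(self, quiet_day, exelberg):
        state = SoilState(sol=5.0)
        state.sol = -5.0  # bypass construction-time validation
        with pytest.raises(ValueError, match="invariant"):
            derivatives(state, quiet_day, exelberg)


class TestRk4Step:
    def test_zero_derivatives_leave_state(self, quiet_day, exelberg):
        state = SoilState()
        new, flux = rk4_step(state, quiet_day, exelberg)
        assert new == state
        assert flux["leaching"] == 0.0 and flux["clipped"] == 0.0

    def test_exponential_decay_accuracy(self, quiet_day, exelberg):
        # labile pool alone decays with lambda*dt = ln2/21.99 ~ 0.032;
        # one RK4 step must match exp decay to ~(lambda*dt)^5/120.
        # immobilization is switched off so nothing feeds back.
        p = exelberg.with_values(v_coeff_immobil=0.0)
        state = SoilState(labile=1000.0)
        new, _ = rk4_step(state, quiet_day, p)
        lam = LN2 / p.hl_labile_d
        assert new.labile == pytest.approx(1000.0 * math.exp(-lam), rel=1e-6)

    def test_invalid_dt_raises(self, quiet_day, exelberg):
        with pytest.raises(ValueError):
            rk4_step(SoilState(), quiet_day, exelberg, dt=0.0)

    def test_flux_ledger_consistent_with_state_change(self, constant_forcing,
                                                      exelberg):
        f = constant_forcing(1, wet_dep=25.0, infiltration=5.0,
                             percolation=4.0, kc_lai=1.0, doy=180)
        state = SoilState(sol=700.0, labile=200.0, stable=3000.0, ads=1500.0)
        new, flux = rk4_step(state, day_from_row(f.iloc[0]), exelberg)
        d_total = new.total() - state.total() - flux["wet_dep"]
        net = -(flux["leaching"] + flux["bypass_S"]) + flux["occult"] + flux["dry"]
        assert d_total == pytest.approx(net, abs=1e-10)


class TestRunSimulation:
    def test_zero_everything_stays_zero(self, constant_forcing, exelberg):
        f = constant_forcing(365)
        res = run_simulation(f, exelberg, SoilState())
        assert (res.states[["sol", "fol", "labile", "stable", "ads"]]
                .to_numpy() == 0.0).all()
        assert (res.fluxes[["leaching", "u_plant", "m_stable"]]
                .to_numpy() == 0.0).all()

    def test_bitwise_deterministic(self, constant_forcing, exelberg):
        f = constant_forcing(200, wet_dep=10.0, infiltration=3.0,
                             percolation=1.0)
        init = SoilState(sol=500.0, labile=100.0, stable=2000.0, ads=800.0)
        a = run_simulation(f, exelberg, init)
        b = run_simulation(f, exelberg, init)
        pd.testing.assert_frame_equal(a.states, b.states)
        pd.testing.assert_frame_equal(a.fluxes, b.fluxes)

    def test_light_path_matches_full_path(self, constant_forcing, exelberg):
        f = constant_forcing(150, wet_dep=8.0, infiltration=3.0,
                             percolation=2.0, kc_lai=1.0)
        init = SoilState(sol=400.0, labile=80.0, stable=1500.0, ads=600.0)
        full = run_simulation(f, exelberg, init)
        light = simulate_solution(f, exelberg, init)
        np.testing.assert_array_equal(
            full.states["sol"].to_numpy()[1:], light)

    def test_forcing_gap_rejected(self, constant_forcing, exelberg):
        f = constant_forcing(60)
        gappy = pd.concat([f.iloc[:20], f.iloc[30:]], ignore_index=True)
        with pytest.raises(ValueError, match="consecutive"):
            run_simulation(gappy, exelberg, SoilState())

    def test_leaf_off_empties_foliage(self, constant_forcing, exelberg):
        # no dry deposition and no uptake: autumn litterfall must move the
        # whole foliage pool to the organic pools by DoY_LE
        from sulfur_dynamics.soil_processes import smoothstep

        f = constant_forcing(365, start="2010-01-01")
        doy = f["doy"].to_numpy()
        f["kc_lai"] = [smoothstep(d, 270, 300, 1.0, 0.0) if d <= 300 else 0.0
                       for d in doy]
        init = SoilState(fol=500.0)
        p = exelberg.with_values(v_starve_plant=0.0)  # no uptake into foliage
        res = run_simulation(f, p, init)
        states = res.states.set_index(pd.DatetimeIndex(res.states["date"]))
        assert states["fol"].iloc[-1] == pytest.approx(0.0, abs=1e-9)
        litter_sum = res.fluxes["litter"].sum()
        assert litter_sum == pytest.approx(500.0, rel=1e-9)
        stable_gain = states["stable"].iloc[-1] - 0.0
        assert stable_gain < 500.0 * (1 - exelberg.f_labile) + 1e-6

    def test_acu_resets_on_new_year(self, constant_forcing, exelberg):
        f = constant_forcing(400, start="2010-06-01", wet_dep=20.0,
                             infiltration=5.0, kc_lai=1.0)
        init = SoilState(sol=2000.0)
        res = run_simulation(f, exelberg, init)
        states = res.states.iloc[1:].set_index(
            pd.DatetimeIndex(res.states["date"][1:]))
        dec31 = states.loc["2010-12-31", "acu"]
        jan1 = states.loc["2011-01-01", "acu"]
        assert dec31 > 0.0
        assert jan1 < dec31 * 0.01

    def test_annual_summary_budget(self, constant_forcing, exelberg):
        f = constant_forcing(730, start="2010-01-01", wet_dep=5.0,
                             infiltration=2.0, percolation=1.0)
        init = SoilState(sol=300.0, stable=1000.0)
        res = run_simulation(f, exelberg, init)
        ann = res.annual()
        assert set(ann.index) == {2010, 2011}
        daily = res.fluxes
        y2010 = pd.DatetimeIndex(daily["date"]).year == 2010
        assert ann.loc[2010, "input"] == pytest.approx(
            daily.loc[y2010, ["wet_dep", "occult", "dry"]].sum().sum())
        assert ann.loc[2010, "output"] == pytest.approx(
            daily.loc[y2010, ["leaching", "bypass_S"]].sum().sum())


class TestMassBalance:
    def test_audit_on_active_run(self, constant_forcing, exelberg):
        f = constant_forcing(500, wet_dep=15.0, so2_air=0.005, fog_precip=0.5,
                             infiltration=4.0, percolation=3.0, kc_lai=1.0)
        init = SoilState(sol=600.0, labile=150.0, stable=2500.0, ads=1200.0)
        res = run_simulation(f, exelberg, init)
        report = mass_balance_audit(res.states, res.fluxes)
        assert report.relative_error < 1e-12
        assert report.max_daily_error < 1e-9

    def test_without_export_total_is_nondecreasing(self, constant_forcing,
                                                   exelberg):
        f = constant_forcing(300, wet_dep=10.0, infiltration=3.0)  # no percolation
        res = run_simulation(f, exelberg, SoilState(sol=100.0))
        total = res.states["total"].to_numpy()
        assert (np.diff(total) >= -1e-12).all()

    def test_misaligned_series_raise(self, constant_forcing, exelberg):
        f = constant_forcing(50, wet_dep=5.0, infiltration=2.0)
        res = run_simulation(f, exelberg, SoilState())
        with pytest.raises(ValueError, match="misaligned"):
            mass_balance_audit(res.states.iloc[:-2], res.fluxes)


class TestSpinUp:
    def test_spin_up_reaches_fixed_point(self, constant_forcing, exelberg):
        # constant low deposition: the solution pool settles where
        # input balances leaching + transformation losses
        f = constant_forcing(365, wet_dep=2.0, infiltration=3.0,
                             percolation=1.0)
        state = equilibrium_spin_up(f, exelberg, SoilState(), max_cycles=60,
                                    tol=1e-4)
        res = run_simulation(f, exelberg, state)
        drift = abs(res.final_state.sol - state.sol) / max(state.sol, 1.0)
        assert drift < 1e-3
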