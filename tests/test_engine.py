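"""Simulation engine: conservation laws, equilibria, dosing, growth dilution."""

import copy
import math

import numpy as np
import pytest

from conftest import make_inert_config
from vegftrap.config import default_xenograft_config
from vegftrap.engine import CompiledModel, DoseSchedule, dose_to_input
from vegftrap.units import SECONDS_PER_DAY, half_life_to_rate


class TestDoseConversion:
    def test_hand_arithmetic_2p5_mg_per_kg(self):
        # 2.5 mg/kg, 25 g mouse, 115 kDa -> 0.543 nmol delivered
        rate = dose_to_input(2.5, 25.0, 115e3, 1.0, 60.0)
        delivered_pmol = rate * 60.0 * 1e-3  # pM/s * s * L
        assert math.isclose(delivered_pmol, 543.478, rel_tol=1e-4)

    def test_linearity_in_dose(self):
        r1 = dose_to_input(0.5, 25.0, 115e3, 1.0, 60.0)
        r2 = dose_to_input(25.0, 25.0, 115e3, 1.0, 60.0)
        assert math.isclose(r2 / r1, 50.0, rel_tol=1e-12)

    def test_short_infusion_approaches_bolus_increment(self):
        # total delivered is duration-independent; the bolus limit is the
        # same increment concentrated at t=0
        for dur in (60.0, 1.0, 1e-3):
            rate = dose_to_input(1.0, 25.0, 115e3, 1.0, dur)
            assert math.isclose(rate * dur, 1.0 * 25e-6 / 115e3 * 1e12 / 1e-3,
                                rel_tol=1e-12)

    def test_zero_molecular_weight_rejected(self):
        with pytest.raises(ValueError):
            dose_to_input(1.0, 25.0, 0.0, 1.0, 60.0)

    def test_half_life_conversion(self):
        # 72 h half-life -> 1.6e-4 min^-1
        rate_per_min = half_life_to_rate(72 * 3600.0) * 60.0
        assert math.isclose(rate_per_min, 1.6e-4, rel_tol=0.01)


class TestSteadyState:
    def test_zero_secretion_keeps_vegf_at_zero(self):
        cfg = default_xenograft_config()
        for k in ("q_muscle_molecules_per_cell_s", "q_ec_molecules_per_cell_s",
                  "q_tumor_molecules_per_cell_s"):
            cfg["secretion"][k] = 0.0
        model = CompiledModel.from_config(cfg)
        y = model.steady_state()
        for comp in ("normal", "blood", "tumor"):
            for name in ("vegf_mouse", "vegf_human"):
                assert y[model._obs[f"{name}_{comp}"]].sum() == pytest.approx(0.0, abs=1e-9)

    def test_alpha2m_synthesis_clearance_balance(self, xenograft_model,
                                                 xenograft_steady_state):
        # synthesis was set from mass balance at the measured plasma levels
        m, y = xenograft_model, xenograft_steady_state
        native = y[m.index["blood:fluid:a2Mn"]]
        active = y[m.index["blood:fluid:a2Mf"]]
        assert native == pytest.approx(1.4e6, rel=1e-2)  # 1.4 uM
        assert active == pytest.approx(1.4e4, rel=1e-2)  # 14 nM

    def test_steady_state_invariant_under_further_integration(
        self, xenograft_model, xenograft_steady_state
    ):
        m, y = xenograft_model, xenograft_steady_state
        res = m.simulate(schedule=None, t_out_days=np.array([0.0, 5.0]),
                         horizon_days=5.0, y0=y, rtol=1e-8)
        # growth is enabled in the default config; freeze it via drug-free
        # restart at fixed volume instead
        from scipy.integrate import solve_ivp

        sol = solve_ivp(
            lambda t, yy: m.rhs(t, yy, 0.0, growth_on=False),
            (0.0, 5 * SECONDS_PER_DAY), y, method="BDF",
            jac=lambda t, yy: m.jac(t, yy, 0.0, growth_on=False),
            rtol=1e-8, atol=1e-6,
        )
        yf = sol.y[:, -1]
        scale = 1.0 + np.abs(y[: m.n_species])
        drift = np.abs(yf[: m.n_species] - y[: m.n_species]) / scale
        assert drift.max() < 1e-4

    def test_near_linearity_of_free_vegf_in_secretion(self):
        # doubling all secretion rates roughly doubles free VEGF at low occupancy
        cfg = default_xenograft_config()
        m1 = CompiledModel.from_config(cfg)
        cfg2 = copy.deepcopy(cfg)
        for k in ("q_muscle_molecules_per_cell_s", "q_ec_molecules_per_cell_s",
                  "q_tumor_molecules_per_cell_s"):
            cfg2["secretion"][k] = 2.0 * cfg2["secretion"][k]
        m2 = CompiledModel.from_config(cfg2)
        y1, y2 = m1.steady_state(), m2.steady_state()
        for obs in ("vegf_mouse_normal", "vegf_human_tumor"):
            r = y2[m2._obs[obs]].sum() / y1[m1._obs[obs]].sum()
            assert 1.8 < r < 2.2


class TestBindingEquilibrium:
    def test_two_species_equilibrium_matches_kd_algebra(self):
        # closed system: only Trap-V164 binding active in blood, nothing else
        cfg = make_inert_config()
        cfg["kinetics"]["Trap:V"] = {"kon_per_M_s": 1.0e7, "koff_per_s": 5.0e-6}
        model = CompiledModel.from_config(cfg)
        y0 = np.zeros(model.n_state)
        T0, V0 = 100.0, 10.0  # pM
        y0[model.index["blood:fluid:Trap"]] = T0
        y0[model.index["blood:fluid:V164"]] = V0
        res = model.simulate(schedule=None, t_out_days=np.array([0.0, 40.0]),
                             horizon_days=40.0, y0=y0, pre_equilibrate=False,
                             rtol=1e-10)
        c_sim = res.states[-1, model.index["blood:fluid:Trap_V164"]]
        # analytic root of kon (T0-C)(V0-C) = koff C
        kd = 5e-6 / (1e7 * 1e-12)  # pM
        b = T0 + V0 + kd
        c_true = (b - math.sqrt(b * b - 4 * T0 * V0)) / 2.0
        assert c_sim == pytest.approx(c_true, rel=1e-6)


class TestConservation:
    def test_growth_only_run_conserves_amounts_and_dilutes_concentration(self):
        cfg = make_inert_config(tumor_volume_cm3=0.01)
        model = CompiledModel.from_config(cfg)
        assert model.growth_enabled
        y0 = np.zeros(model.n_state)
        i_v = model.index["tumor:fluid:V165"]
        i_r = model.index["tumor:tumor_cell:R1"]
        y0[i_v] = 50.0
        y0[i_r] = 200.0
        days = 5.0
        res = model.simulate(schedule=None, t_out_days=np.array([0.0, days]),
                             horizon_days=days, y0=y0, pre_equilibrate=False,
                             rtol=1e-10)
        v_ratio = model.tumor_volume(days * SECONDS_PER_DAY) / model.tumor_volume(0.0)
        for i, c0 in ((i_v, 50.0), (i_r, 200.0)):
            c_end = res.states[-1, i]
            # concentration falls as V0/V(t); amount C*V is conserved
            assert c_end * v_ratio == pytest.approx(c0, rel=1e-4)

    def test_drug_mass_audit_after_bolus(self, xenograft_model):
        m = xenograft_model
        y0 = m.steady_state()
        res = m.simulate(schedule=DoseSchedule(2.5), t_out_days=np.linspace(0.1, 14, 24),
                         y0=y0, rtol=1e-8)
        amounts = np.array(
            [m.trap_amount_pmol(res.states[i], res.t_abs_s[i])
             for i in range(len(res.t_days))]
        )
        assert np.all(np.abs(amounts / amounts[0] - 1.0) < 1e-4)

    def test_receptor_totals_conserved_under_binding_only(self):
        cfg = default_xenograft_config()
        for k in cfg["trafficking"]:
            cfg["trafficking"][k] = 0.0  # no internalization or insertion
        cfg["growth"]["enabled"] = False
        model = CompiledModel.from_config(cfg)
        y0 = model.initial_guess()
        # provoke binding by injecting free VEGF everywhere
        for comp in ("normal", "blood", "tumor"):
            for iso in ("V120", "V164", "V121", "V165"):
                y0[model.index[f"{comp}:fluid:{iso}"]] += 5.0
        res = model.simulate(schedule=None, t_out_days=np.array([0.0, 2.0]),
                             horizon_days=2.0, y0=y0, pre_equilibrate=False,
                             rtol=1e-9)
        for surf, rec in (("muscle_fiber", "R1"), ("EC_luminal_normal", "N1"),
                          ("tumor_cell", "N2")):
            t0 = model.surface_receptor_total(res.states[0], surf, rec)
            t1 = model.surface_receptor_total(res.states[-1], surf, rec)
            assert t1 == pytest.approx(t0, rel=1e-6)

    def test_trajectories_remain_nonnegative(self, xenograft_model):
        y0 = xenograft_model.steady_state()
        res = xenograft_model.simulate(
            schedule=DoseSchedule.twice_weekly(25.0),
            t_out_days=np.linspace(0, 14, 29), y0=y0, rtol=1e-8,
        )
        assert res.min_concentration() >= -1e-12


class TestDosing:
    def test_zero_dose_leaves_drug_free_steady_state(self):
        cfg = default_xenograft_config()
        cfg["growth"]["enabled"] = False
        cfg["growth"]["initial_volume_cm3"] = 0.1
        model = CompiledModel.from_config(cfg)
        y0 = model.steady_state()
        res = model.simulate(schedule=DoseSchedule(0.0),
                             t_out_days=np.array([0.0, 7.0, 14.0]), y0=y0, rtol=1e-8)
        scale = 1.0 + np.abs(y0[: model.n_species])
        drift = np.abs(res.states[-1, : model.n_species] - y0[: model.n_species]) / scale
        assert drift.max() < 1e-4
        assert res.observable("trap_free").max() == 0.0

    def test_two_compartment_mode_equals_tumor_volume_zero(self):
        from vegftrap.config import default_normal_mouse_config

        cfg3 = default_xenograft_config()
        cfg3["growth"]["enabled"] = False
        cfg3["growth"]["initial_volume_cm3"] = 0.0  # tumor present but V == 0
        cfg3["secretion"]["q_muscle_molecules_per_cell_s"] = 0.002
        cfg3["secretion"]["q_ec_molecules_per_cell_s"] = 0.057
        m3 = CompiledModel.from_config(cfg3)
        m2 = CompiledModel.from_config(default_normal_mouse_config())
        t_out = np.array([0.0, 1.0, 3.0, 7.0])
        r3 = m3.simulate(schedule=DoseSchedule(2.5), t_out_days=t_out, rtol=1e-8)
        r2 = m2.simulate(schedule=DoseSchedule(2.5), t_out_days=t_out, rtol=1e-8)
        shared = [sid for sid in m2.species_ids if sid in m3.index]
        assert len(shared) == m2.n_species
        for sid in shared:
            a = r3.states[:, m3.index[sid]]
            b = r2.states[:, m2.index[sid]]
            np.testing.assert_allclose(a, b, rtol=1e-5, atol=1e-9, err_msg=sid)
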