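import math

import numpy as np
import pytest

import brainpk as bp
from brainpk.parameters import DoseRegimen, PERFUSION_TISSUES
from brainpk.partition import ConfigurationError


def auc(profile, t_end=None):
    t, c = profile.times_h, profile.conc_ng_ml
    if t_end is not None:
        m = t <= t_end + 1e-9
        t, c = t[m], c[m]
    return np.trapezoid(c, t)


class TestBrainFluxes:
    def test_symmetric_unbound_concentrations_give_zero_flux(self, male_drug, rat):
        phys = rat.model_copy(update={"q_bulk": 0.0, "q_sink": 0.0})
        cu = 50_000.0  # ng/L everywhere (unbound)
        amounts = (
            cu / (male_drug.fu_plasma / male_drug.blood_plasma_ratio) * phys.v_brain_blood,
            cu / male_drug.fu_brain * phys.v_brain_mass,
            cu * phys.v_csf,
        )
        assert bp.brain_fluxes(amounts, male_drug, phys) == (0.0, 0.0, 0.0)

    def test_bbb_flux_hand_arithmetic(self, male_drug, rat):
        """100 ng/mL unbound in brain blood against an empty brain with
        PSB = 0.84 mL/min must push 84 ng/min across the BBB."""
        cu = 100_000.0  # ng/L
        a_bb = cu / (male_drug.fu_plasma / male_drug.blood_plasma_ratio) * rat.v_brain_blood
        _, d_bm, _ = bp.brain_fluxes((a_bb, 0.0, 0.0), male_drug, rat)
        assert d_bm / 60.0 == pytest.approx(84.0, rel=1e-12)

    def test_brain_metabolism_removes_exactly_clmet_times_unbound(self, male_drug, rat):
        amounts = (1e4, 2e4, 3e3)
        base = bp.brain_fluxes(amounts, male_drug, rat)
        met_drug = male_drug.model_copy(update={"cl_met_brain": 0.5})
        with_met = bp.brain_fluxes(amounts, met_drug, rat)
        cu_bm = male_drug.fu_brain * amounts[1] / rat.v_brain_mass
        assert base[1] - with_met[1] == pytest.approx(0.5 * cu_bm, rel=1e-12)
        assert with_met[0] == base[0] and with_met[2] == base[2]


class TestSimulate:
    def test_zero_dose_gives_zero_profiles(self, male_drug, rat, male_kp):
        reg = DoseRegimen(dose_mg_per_kg=0.0, n_doses=1, simulation_end_h=24.0)
        res = bp.PBPKModel(male_drug, rat, reg, male_kp).simulate(np.linspace(0, 24, 25))
        for prof in res.profiles.values():
            assert np.all(prof.conc_ng_ml == 0.0)

    def test_closed_barriers_keep_brain_empty(self, male_drug, rat, male_kp):
        sealed = male_drug.model_copy(update={"psb_ml_min": 0.0, "psc_ml_min": 0.0})
        reg = DoseRegimen(dose_mg_per_kg=4.0, n_doses=1, simulation_end_h=24.0)
        res = bp.PBPKModel(sealed, rat, reg, male_kp).simulate(np.linspace(0, 24, 49))
        assert res.profiles["brain_mass"].conc_ng_ml.max() == pytest.approx(0.0, abs=1e-9)
        assert res.profiles["csf"].conc_ng_ml.max() == pytest.approx(0.0, abs=1e-9)
        assert res.profiles["plasma_total"].conc_ng_ml.max() > 100.0

    def test_ecf_is_fu_brain_times_brain_mass(self, male_single_dose, male_drug):
        bm = male_single_dose.profiles["brain_mass"].conc_ng_ml
        ecf = male_single_dose.profiles["brain_ecf"].conc_ng_ml
        assert np.allclose(ecf, male_drug.fu_brain * bm, rtol=1e-12)

    def test_male_plasma_auc_matches_reported_prediction(self, male_single_dose):
        """Single 4 mg/kg dose: plasma AUC0-72 within 1.5-fold of the
        21,050 h.ng/mL whole-body-simulator prediction."""
        value = auc(male_single_dose.profiles["plasma_total"], 72.0)
        assert 21050 / 1.5 <= value <= 21050 * 1.5

    def test_missing_kp_tissue_raises(self, male_drug, rat, male_kp):
        reg = DoseRegimen(dose_mg_per_kg=4.0, n_doses=1, simulation_end_h=24.0)
        bad = {t: v for t, v in male_kp.items() if t != "muscle"}
        with pytest.raises(ConfigurationError):
            bp.PBPKModel(male_drug, rat, reg, bad)

    def test_increasing_clearance_decreases_auc(self, male_drug, rat, male_kp):
        reg = DoseRegimen(dose_mg_per_kg=4.0, n_doses=1, simulation_end_h=72.0)
        t = np.linspace(0, 72, 145)
        aucs = []
        for scale in (0.5, 1.0, 2.0):
            d = male_drug.model_copy(
                update={"cl_systemic_ml_min": male_drug.cl_systemic_ml_min * scale}
            )
            res = bp.PBPKModel(d, rat, reg, male_kp).simulate(t)
            aucs.append(auc(res.profiles["plasma_total"]))
        assert aucs[0] > aucs[1] > aucs[2]


class TestMassBalance:
    def test_closure_below_1e6(self, male_single_dose):
        mb = male_single_dose.mass_balance(rtol=1e-6)
        live = mb.absorbed_ng > 0
        assert mb.rel_error[live].max() < 1e-6

    def test_everything_eventually_eliminated(self, male_drug, rat, male_kp):
        reg = DoseRegimen(dose_mg_per_kg=4.0, n_doses=1, simulation_end_h=400.0)
        res = bp.PBPKModel(male_drug, rat, reg, male_kp).simulate(
            np.linspace(0, 400, 201)
        )
        mb = res.mass_balance()
        fa_dose = male_drug.fa * reg.dose_amount_ng(rat.body_weight_kg)
        assert mb.eliminated_ng.iloc[-1] == pytest.approx(fa_dose, rel=0.005)

    def test_no_clearance_conserves_dose(self, male_drug, rat, male_kp):
        drug = male_drug.model_copy(update={"cl_systemic_ml_min": 0.0})
        reg = DoseRegimen(dose_mg_per_kg=4.0, n_doses=1, simulation_end_h=200.0)
        res = bp.PBPKModel(drug, rat, reg, male_kp).simulate(np.linspace(0, 200, 101))
        mb = res.mass_balance()
        fa_dose = drug.fa * reg.dose_amount_ng(rat.body_weight_kg)
        assert mb.in_body_ng.iloc[-1] == pytest.approx(fa_dose, rel=1e-3)
        assert mb.eliminated_ng.iloc[-1] == pytest.approx(0.0, abs=fa_dose * 1e-9)

    def test_multi_dose_absorption_bounded(self, male_drug, rat, male_kp):
        reg = DoseRegimen(
            dose_mg_per_kg=4.0, n_doses=5, interval_tau_h=24.0, simulation_end_h=120.0
        )
        res = bp.PBPKModel(male_drug, rat, reg, male_kp).simulate(
            np.linspace(0, 120, 241)
        )
        cap = male_drug.fa * 5 * reg.dose_amount_ng(rat.body_weight_kg)
        assert res.absorbed_ng[-1] <= cap * (1 + 1e-12)


class TestLinearity:
    def test_superposition_of_repeat_doses(self, male_drug, rat, male_kp):
        """The 3-dose profile equals the sum of time-shifted single-dose
        profiles (linear kinetics)."""
        t = np.linspace(0, 72, 145)  # 0.5 h grid aligned with the 24 h interval
        reg3 = DoseRegimen(
            dose_mg_per_kg=4.0, n_doses=3, interval_tau_h=24.0, simulation_end_h=72.0
        )
        multi = bp.PBPKModel(male_drug, rat, reg3, male_kp).simulate(t)
        reg1 = DoseRegimen(dose_mg_per_kg=4.0, n_doses=1, simulation_end_h=72.0)
        single = bp.PBPKModel(male_drug, rat, reg1, male_kp).simulate(t)
        c1 = single.profiles["plasma_total"].conc_ng_ml
        expected = c1.copy()
        for shift_idx in (48, 96):  # 24 h and 48 h in 0.5 h steps
            expected[shift_idx:] += c1[: t.size - shift_idx]
        observed = multi.profiles["plasma_total"].conc_ng_ml
        assert np.allclose(observed, expected, rtol=5e-6, atol=1e-6)

    def test_one_compartment_closed_form_half_life(self, male_drug, rat):
        """All Kp = 1, unit binding ratios and wide-open brain barriers turn
        the body into one well-stirred volume: terminal half-life must match
        ln2 * V / CL within 2 %."""
        uni = male_drug.model_copy(
            update=dict(
                blood_plasma_ratio=1.0,
                fu_plasma=1.0,
                fu_brain=1.0,
                psb_ml_min=500.0,
                psc_ml_min=500.0,
                pse_ml_min=500.0,
            )
        )
        kp1 = {t: 1.0 for t in PERFUSION_TISSUES}
        v_total = (
            sum(rat.volumes.values())
            + rat.v_arterial
            + rat.v_venous
            + rat.v_brain_blood
            + rat.v_brain_mass
            + rat.v_csf
        )
        expected = math.log(2) * v_total / uni.cl_plasma_L_h
        reg = DoseRegimen(dose_mg_per_kg=4.0, n_doses=1, simulation_end_h=120.0)
        res = bp.PBPKModel(uni, rat, reg, kp1).simulate(np.linspace(0, 120, 241))
        fit = bp.NCA(res.profiles["plasma_total"]).fit()
        assert fit.t_half == pytest.approx(expected, rel=0.02)
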