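"""Hepatic impairment scaling, induction/turnover and sensitivity analysis."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import cabpbpk as cp
from cabpbpk.engine import OneCompartmentModel, PBPKSystem
from cabpbpk.metrics import auc_last
from cabpbpk.params import SPLANCHNIC, DoseRegimen, RangeError
from cabpbpk.scenarios import (IMPAIRMENT_GRADES, InductionModel,
                               apply_impairment, enzyme_turnover_step,
                               induction_fold, local_sensitivity,
                               pbpk_output_fn, simulate_ddi)


class TestImpairment:
    def test_control_is_identity(self, physiology):
        scaled = apply_impairment(physiology, "control")
        assert scaled.hematocrit == physiology.hematocrit
        assert scaled.plasma_protein_scale == physiology.plasma_protein_scale
        for n in physiology.organs:
            assert scaled.organs[n].flow_l_h == physiology.organs[n].flow_l_h
            assert scaled.organs[n].volume_l == physiology.organs[n].volume_l

    def test_moderate_grade_factors(self, physiology):
        scaled = apply_impairment(physiology, "moderate")
        base = physiology
        assert scaled.hematocrit == 0.37
        # CYP3A4 activity scalar 0.40 acts on the hepatic expression
        assert scaled.cyp3a4_expression["liver"] == \
            pytest.approx(0.40 * base.cyp3a4_expression["liver"])
        assert scaled.organs["liver"].volume_l == \
            pytest.approx(0.65 * base.organs["liver"].volume_l)
        for n in SPLANCHNIC:
            assert scaled.organs[n].flow_l_h == \
                pytest.approx(0.36 * base.organs[n].flow_l_h)
        assert scaled.organs["brain"].flow_l_h == base.organs["brain"].flow_l_h

    def test_mild_grade_factors(self, physiology):
        scaled = apply_impairment(physiology, "mild")
        assert scaled.hematocrit == 0.39
        assert scaled.organs["gut"].flow_l_h == \
            pytest.approx(0.40 * physiology.organs["gut"].flow_l_h)
        assert scaled.organs["kidney"].flow_l_h == \
            pytest.approx(0.88 * physiology.organs["kidney"].flow_l_h)

    def test_protein_factor_raises_unbound_fraction(self, drug, physiology,
                                                    ehc_params):
        """The moderate grade's protein factor (>1) must increase fu, per the
        clinical observation of higher unbound fraction in those patients."""
        base = PBPKSystem(drug, physiology, ehc_params)
        scaled = PBPKSystem(drug, apply_impairment(physiology, "moderate"),
                            ehc_params)
        assert scaled.fu > base.fu
        mild = PBPKSystem(drug, apply_impairment(physiology, "mild"),
                          ehc_params)
        assert mild.fu < base.fu

    def test_invariants_preserved(self, physiology):
        for grade in IMPAIRMENT_GRADES:
            scaled = apply_impairment(physiology, grade)
            assert 0 < scaled.hematocrit < 1
            assert all(o.flow_l_h >= 0 for o in scaled.organs.values())
            assert all(o.volume_l > 0 for o in scaled.organs.values())
            # cardiac output re-derives from the scaled flows
            assert scaled.cardiac_output_l_h > 0

    def test_unknown_grade_rejected(self, physiology):
        with pytest.raises(RangeError, match="grade"):
            apply_impairment(physiology, "severe")


class TestInductionFold:
    def test_no_perpetrator_no_induction(self):
        assert induction_fold(0.0, 9.0, 0.34) == 1.0

    def test_half_maximal_at_ec50(self):
        assert induction_fold(0.34, 9.0, 0.34) == pytest.approx(1.0 + 4.5)

    def test_saturates_at_emax(self):
        assert induction_fold(1e9, 9.0, 0.34) == pytest.approx(10.0, rel=1e-6)


class TestEnzymeTurnover:
    def test_baseline_is_stationary(self):
        assert enzyme_turnover_step(5.0, 5.0, 1.0, 0.03) == pytest.approx(0.0)

    def test_steady_state_is_fold_times_baseline(self):
        # at E = 5*E0 under constant fold 5 the derivative vanishes
        assert enzyme_turnover_step(25.0, 5.0, 5.0, 0.03) == pytest.approx(0.0)

    def test_washout_follows_closed_form(self):
        """After induction stops, E relaxes to E0 as E0 + (E_i - E0)e^(-kt)."""
        e0, e_init, kdeg = 2.0, 9.0, 0.05
        sol = solve_ivp(lambda t, y: enzyme_turnover_step(y[0], e0, 1.0, kdeg),
                        (0.0, 80.0), [e_init], rtol=1e-10, atol=1e-12,
                        t_eval=np.linspace(0.0, 80.0, 9))
        expected = e0 + (e_init - e0) * np.exp(-kdeg * sol.t)
        np.testing.assert_allclose(sol.y[0], expected, rtol=1e-7)
        # half-life of the excess is ln2/kdeg
        t_half = np.log(2.0) / kdeg
        mid = e0 + (e_init - e0) / 2.0
        sol2 = solve_ivp(lambda t, y: enzyme_turnover_step(y[0], e0, 1.0, kdeg),
                         (0.0, t_half), [e_init], rtol=1e-10, atol=1e-12)
        assert sol2.y[0, -1] == pytest.approx(mid, rel=1e-6)


class TestSimulateDdi:
    def test_zero_emax_leaves_victim_untouched(self, drug, physiology,
                                               ehc_params, regimen,
                                               fast_options, formulations):
        reg = dataclasses.replace(regimen, dose=140.0,
                                  formulation=formulations["capsule"])
        ind = InductionModel(emax=0.0, start_h=-24.0, n_doses=4)
        rw, ro = simulate_ddi(drug, physiology, ehc_params, reg, ind,
                              t_end=72.0, options=fast_options)
        m = rw.times >= 0.0
        auc_w = auc_last(rw.times[m], rw.conc_plasma_ng_ml[m])
        auc_o = auc_last(ro.times, ro.conc_plasma_ng_ml)
        assert auc_w == pytest.approx(auc_o, rel=1e-4)

    def test_induction_reduces_exposure(self, drug, physiology, ehc_params,
                                        regimen, fast_options, formulations):
        reg = dataclasses.replace(regimen, dose=140.0,
                                  formulation=formulations["capsule"])
        ind = InductionModel(start_h=-120.0, n_doses=10)
        rw, ro = simulate_ddi(drug, physiology, ehc_params, reg, ind,
                              t_end=96.0, options=fast_options)
        m = rw.times >= 0.0
        auc_w = auc_last(rw.times[m], rw.conc_plasma_ng_ml[m])
        auc_o = auc_last(ro.times, ro.conc_plasma_ng_ml)
        assert auc_w < auc_o


class TestLocalSensitivity:
    @staticmethod
    def _one_compartment_auc(params):
        model = OneCompartmentModel(volume_l=params["V"],
                                    clearance_l_h=params["CL"])
        reg = DoseRegimen(dose=params["dose"], formulation=None, route="iv")
        res = model.simulate(reg, 150.0, grid_dt=0.05)
        ke = params["CL"] / params["V"]
        return auc_last(res.times, res.conc_plasma_umol_l) \
            + res.conc_plasma_umol_l[-1] / ke

    def test_dose_proportionality_sensitivity(self):
        base = {"dose": 100.0, "CL": 5.0, "V": 50.0}
        s = local_sensitivity(self._one_compartment_auc, base, "dose", 0.1)
        assert s == pytest.approx(1.0, abs=1e-3)

    def test_clearance_sensitivity_is_minus_one(self):
        base = {"dose": 100.0, "CL": 5.0, "V": 50.0}
        s = local_sensitivity(self._one_compartment_auc, base, "CL", 0.1)
        assert s == pytest.approx(-1.0, abs=0.02)

    def test_inactive_parameter_has_zero_sensitivity(self, drug, physiology,
                                                     ehc_params, regimen):
        opt = cp.SimulationOptions(mrp2_enabled=False, rtol=1e-7, atol=1e-10)
        fn = pbpk_output_fn(drug, physiology, ehc_params, regimen, 24.0,
                            output="auc_last", options=opt)
        s = local_sensitivity(fn, {"drug.kcat_mrp2": drug.kcat_mrp2},
                              "drug.kcat_mrp2", 0.25)
        assert s == pytest.approx(0.0, abs=1e-9)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(RangeError, match="parameter"):
            local_sensitivity(lambda p: 1.0, {"a": 1.0}, "b")
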