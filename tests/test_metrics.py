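"""Noncompartmental analysis and model-evaluation statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cabpbpk.engine import OneCompartmentModel
from cabpbpk.metrics import (ObservedProfile, SteadyStateError, auc_last,
                             cmax_tmax, css_average, ddi_ratios,
                             evaluate_profiles, fit_parameters, fold_fractions,
                             mrd, prediction_errors)
from cabpbpk.params import DoseRegimen, RangeError


class TestAucLast:
    def test_constant_profile(self):
        t = np.linspace(0.0, 10.0, 11)
        assert auc_last(t, np.full_like(t, 5.0)) == pytest.approx(50.0)

    def test_triangle(self):
        assert auc_last([0.0, 1.0], [0.0, 2.0]) == pytest.approx(1.0)

    def test_exponential_closed_form(self):
        """Dense trapezoid vs the analytic integral of C0*exp(-k t)."""
        k, c0, t_end = 0.3, 100.0, 24.0
        t = np.arange(0.0, t_end + 1e-12, 0.01)
        analytic = c0 / k * (1.0 - np.exp(-k * t_end))
        assert auc_last(t, c0 * np.exp(-k * t)) == \
            pytest.approx(analytic, rel=1e-4)

    def test_additive_over_partitions(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 50, 40))
        t[0], t[-1] = 0.0, 50.0
        c = rng.uniform(0, 10, t.size)
        k = 17
        total = auc_last(t, c)
        assert auc_last(t[:k + 1], c[:k + 1]) + auc_last(t[k:], c[k:]) == \
            pytest.approx(total, rel=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(RangeError):
            auc_last([1.0], [2.0])


class TestCmaxCss:
    def test_tie_resolved_to_earliest(self):
        cmax, tmax = cmax_tmax(([0.0, 1.0, 2.0, 3.0], [1.0, 5.0, 5.0, 2.0]))
        assert (cmax, tmax) == (5.0, 1.0)

    def test_monotone_decreasing_peaks_at_first_point(self):
        cmax, tmax = cmax_tmax(([0.0, 1.0, 2.0], [9.0, 4.0, 1.0]))
        assert (cmax, tmax) == (9.0, 0.0)

    def test_constant_concentration_is_its_own_css(self):
        t = np.linspace(0.0, 240.0, 2401)
        assert css_average((t, np.full_like(t, 7.0)), tau=24.0) == \
            pytest.approx(7.0)

    def test_superposition_closed_form(self):
        """Multiple-dose average Css of a one-compartment iv model equals
        D/(CL*tau) at steady state (superposition), within 0.5%."""
        v, cl, dose, tau = 50.0, 5.0, 100.0, 24.0
        model = OneCompartmentModel(volume_l=v, clearance_l_h=cl)
        reg = DoseRegimen(dose=dose, formulation=None, route="iv",
                          interval=tau, n_doses=10)
        res = model.simulate(reg, 240.0)
        css = css_average((res.times, res.conc_plasma_ng_ml), tau)
        dose_umol = dose * 1000.0 / model.mw
        expected = dose_umol / (cl * tau) * model.mw  # ng/mL
        assert css == pytest.approx(expected, rel=0.005)

    def test_steady_state_not_reached_is_diagnosed(self):
        model = OneCompartmentModel(volume_l=500.0, clearance_l_h=1.0)
        reg = DoseRegimen(dose=100.0, formulation=None, route="iv",
                          interval=24.0, n_doses=6)
        res = model.simulate(reg, 144.0)
        with pytest.raises(SteadyStateError):
            css_average((res.times, res.conc_plasma_ng_ml), 24.0)


class TestPredictionErrors:
    def test_perfect_prediction(self):
        pe, mpe, mape = prediction_errors([1.0, 2.0], [1.0, 2.0])
        assert np.allclose(pe, 0.0) and mpe == 0.0 and mape == 0.0

    def test_hand_example(self):
        pe, mpe, mape = prediction_errors([2.0, 0.5], [1.0, 1.0])
        np.testing.assert_allclose(pe, [100.0, -50.0])
        assert mpe == pytest.approx(25.0)
        assert mape == pytest.approx(75.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0.01, 1e3), st.floats(0.01, 1e3)),
                    min_size=1, max_size=20))
    def test_mape_dominates_mpe(self, pairs):
        pred, obs = map(np.array, zip(*pairs))
        _, mpe, mape = prediction_errors(pred, obs)
        assert mape >= abs(mpe) - 1e-9


class TestMrd:
    def test_perfect_agreement(self):
        assert mrd([1.0, 5.0], [1.0, 5.0]) == pytest.approx(1.0)

    def test_tenfold_everywhere(self):
        assert mrd([10.0, 100.0], [1.0, 10.0]) == pytest.approx(10.0)

    def test_hand_evaluation(self):
        # deviations +/- log10(2): RMS = 0.30103 -> MRD = 2.0
        assert mrd([1.0, 10.0], [2.0, 5.0]) == pytest.approx(2.0, rel=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(pairs=st.lists(st.tuples(st.floats(0.01, 1e3), st.floats(0.01, 1e3)),
                          min_size=1, max_size=20),
           scale=st.floats(0.01, 100.0))
    def test_symmetry_and_scale_invariance(self, pairs, scale):
        pred, obs = map(np.array, zip(*pairs))
        assert mrd(pred, obs) == pytest.approx(mrd(obs, pred), rel=1e-9)
        assert mrd(pred * scale, obs * scale) == \
            pytest.approx(mrd(pred, obs), rel=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(RangeError):
            mrd([0.0, 1.0], [1.0, 1.0])


class TestDdiRatios:
    def test_identical_profiles(self):
        prof = ([0.0, 1.0, 2.0], [1.0, 4.0, 2.0])
        assert ddi_ratios(prof, prof) == pytest.approx((1.0, 1.0))

    def test_printed_exposure_pair(self):
        """Constant profiles built from the printed AUC/Cmax pairs give the
        published ratios at 2 d.p."""
        with_rif = ([0.0, 13624.61 / 480.46], [480.46, 480.46])
        alone = ([0.0, 59738.08 / 551.17], [551.17, 551.17])
        auc_ratio, cmax_ratio = ddi_ratios(with_rif, alone)
        assert round(auc_ratio, 2) == 0.23
        assert round(cmax_ratio, 2) == 0.87


class TestFoldFractions:
    def test_perfect(self):
        assert fold_fractions([1.0, 2.0], [1.0, 2.0]) == (1.0, 1.0)

    def test_one_of_four_outside(self):
        f2, _ = fold_fractions([1.0, 1.0, 1.0, 3.0], [1.0, 1.0, 1.0, 1.0])
        assert f2 == pytest.approx(0.75)

    def test_boundary_is_inclusive(self):
        f2, _ = fold_fractions([2.0], [1.0])
        assert f2 == 1.0


class TestFitParameters:
    @staticmethod
    def _profile():
        t = np.linspace(0.5, 24.0, 12)
        k_true = 0.25
        return ObservedProfile(study_id="s", arm="a", times_h=t,
                               conc_ng_ml=100.0 * np.exp(-k_true * t),
                               dose_mg=1.0), t, k_true

    def test_objective_zero_at_truth(self):
        prof, t, k_true = self._profile()

        def predict(p):
            return [100.0 * np.exp(-p["k"] * t)]

        fit = fit_parameters([prof], predict, ["k"], {"k": (0.01, 1.0)},
                             {"k": k_true})
        assert fit.objective == pytest.approx(0.0, abs=1e-12)

    def test_recovers_rate_constant(self):
        prof, t, k_true = self._profile()

        def predict(p):
            return [100.0 * np.exp(-p["k"] * t)]

        fit = fit_parameters([prof], predict, ["k"], {"k": (0.01, 1.0)},
                             {"k": 0.6})
        assert fit.estimates["k"] == pytest.approx(k_true, rel=1e-3)


class TestEvaluateProfiles:
    def test_blq_points_excluded_and_counted(self):
        t_pred = np.linspace(0.0, 10.0, 101)
        pred = (t_pred, 10.0 * np.exp(-0.2 * t_pred))
        obs = ObservedProfile(study_id="s", arm="a",
                              times_h=np.array([1.0, 2.0, 4.0, 8.0]),
                              conc_ng_ml=np.array([8.2, 6.7, 0.0, 2.0]),
                              dose_mg=10.0)
        rep = evaluate_profiles(pred, obs)
        assert rep.n_excluded == 1
        assert rep.n_points == 3
        assert rep.mrd >= 1.0
        assert rep.mape_percent >= abs(rep.mpe_percent)
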