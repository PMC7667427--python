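import numpy as np
import pytest

from fgskinetics.kinetics import (
    AgentKinetics,
    TraceConditionWarning,
    UptakeCurves,
    bp_ratio,
    kety_closed_form,
    roi_signal,
    solve_control,
    solve_targeted,
)
from fgskinetics.plasma import PlasmaInput

from conftest import rk4_two_compartment


class TestAgentKinetics:
    def test_derived_rates(self):
        k = AgentKinetics(K1=0.4, k2=0.2, kon=0.1, koff=0.1, Bavail=10.0)
        assert k.k3 == pytest.approx(1.0)
        assert k.k4 == pytest.approx(0.1)
        assert k.KD == pytest.approx(1.0)
        assert k.BP == pytest.approx(10.0)

    def test_from_binding_potential_realizes_bp(self):
        k = AgentKinetics.from_binding_potential(0.3, 0.5, BP=7.0, k4=0.2)
        assert k.BP == pytest.approx(7.0)
        assert k.k4 == pytest.approx(0.2)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            AgentKinetics(K1=-0.1, k2=0.2)

    def test_vp_bounds(self):
        with pytest.raises(ValueError):
            AgentKinetics(K1=0.1, k2=0.2, vp=1.0)


class TestKetyClosedForm:
    def test_no_extravasation_gives_zero(self, peptide_plasma, minute_grid):
        out = kety_closed_form(0.0, 0.3, peptide_plasma, minute_grid)
        assert np.all(out == 0)

    def test_initial_condition(self, peptide_plasma):
        assert kety_closed_form(0.1, 0.02, peptide_plasma, [0.0])[0] == pytest.approx(0.0)

    def test_matches_fine_step_ode_oracle(self, peptide_plasma):
        K1, k2 = 0.1, 0.02
        times, cf, _ = rk4_two_compartment(K1, k2, 0.0, 0.0, peptide_plasma, 60.0)
        closed = kety_closed_form(K1, k2, peptide_plasma, times)
        mask = closed > 1e-12
        assert np.allclose(closed[mask], cf[mask], rtol=1e-6)

    def test_degenerate_rate_continuity(self, affibody_plasma):
        # k2 -> alpha limit equals the t*exp(-k2 t) branch
        t = np.linspace(0, 60, 61)
        at_limit = kety_closed_form(0.1, affibody_plasma.alpha, affibody_plasma, t)
        nearby = kety_closed_form(0.1, affibody_plasma.alpha + 1e-7, affibody_plasma, t)
        assert np.allclose(at_limit, nearby, rtol=1e-4, atol=1e-12)

    def test_negative_rates_rejected(self, peptide_plasma):
        with pytest.raises(ValueError):
            kety_closed_form(-0.1, 0.2, peptide_plasma, [0, 1])


class TestSolveTargeted:
    def test_no_binding_decouples_to_kety(self, peptide_plasma, minute_grid):
        k = AgentKinetics(K1=0.4, k2=0.2, kon=0.0, koff=0.3, Bavail=0.0)
        curves = solve_targeted(k, peptide_plasma, minute_grid)
        assert np.all(curves.Cb_T == 0)
        kety = kety_closed_form(0.4, 0.2, peptide_plasma, minute_grid)
        assert np.allclose(curves.Cf_T, kety, rtol=1e-6, atol=1e-12)

    def test_irreversible_binding_accumulates(self, peptide_plasma, minute_grid):
        k = AgentKinetics(K1=0.4, k2=0.2, kon=0.1, koff=0.0, Bavail=10.0)
        curves = solve_targeted(k, peptide_plasma, minute_grid)
        assert np.all(np.diff(curves.Cb_T) >= -1e-12)

    def test_matches_rk4_oracle(self, peptide_plasma, minute_grid):
        # peptide tumor kinetics with BP = 10 realized via kon*Bavail/koff
        k = AgentKinetics(K1=0.4, k2=0.2, kon=0.1, koff=0.1, Bavail=1.0)
        assert k.BP == pytest.approx(1.0)
        times, cf, cb = rk4_two_compartment(0.4, 0.2, k.k3, k.k4, peptide_plasma, 60.0)
        curves = solve_targeted(k, peptide_plasma, times[::250])
        idx = np.arange(0, times.size, 250)
        ref_cf, ref_cb = cf[idx], cb[idx]
        m = ref_cf > 1e-10
        assert np.allclose(curves.Cf_T[m], ref_cf[m], rtol=1e-5)
        m = ref_cb > 1e-10
        assert np.allclose(curves.Cb_T[m], ref_cb[m], rtol=1e-5)

    def test_trace_violation_flagged_not_fatal(self, peptide_plasma, minute_grid):
        k = AgentKinetics(K1=0.4, k2=0.2, kon=10.0, koff=0.01, Bavail=0.01)
        with pytest.warns(TraceConditionWarning):
            curves = solve_targeted(k, peptide_plasma, minute_grid)
        assert not curves.trace_ok


class TestSolveControl:
    def test_zero_influx(self, peptide_plasma, minute_grid):
        k = AgentKinetics(K1=0.0, k2=0.3)
        assert np.all(solve_control(k, peptide_plasma, minute_grid).Cf_C == 0)

    def test_agrees_with_closed_form(self, affibody_plasma, minute_grid):
        k = AgentKinetics(K1=0.01, k2=0.3)
        num = solve_control(k, affibody_plasma, minute_grid).Cf_C
        ana = kety_closed_form(0.01, 0.3, affibody_plasma, minute_grid)
        m = ana > 1e-12
        assert np.allclose(num[m], ana[m], rtol=1e-6)

    def test_pure_accumulation_limit(self, quasi_constant_plasma):
        # k2 -> 0 under a constant input: curve approaches K1 * integral(Cp)
        t = np.linspace(0, 100, 101)
        k = AgentKinetics(K1=0.05, k2=1e-9)
        out = solve_control(k, quasi_constant_plasma, t).Cf_C
        assert np.allclose(out, 0.05 * t, rtol=1e-4, atol=1e-9)


class TestRoiSignalAndBPRatio:
    def _curves(self, plasma, t, BP=4.0, vp=0.0):
        k = AgentKinetics(K1=0.2, k2=0.2, kon=0.1, koff=0.1, Bavail=BP, vp=vp)
        curves = solve_targeted(k, plasma, t)
        curves.Cf_C = solve_control(k, plasma, t).Cf_C
        return k, curves

    def test_zero_vp_gives_tissue_signal(self, peptide_plasma, minute_grid):
        k, curves = self._curves(peptide_plasma, minute_grid)
        roi_signal(curves, k, peptide_plasma)
        assert np.allclose(curves.roi_T, curves.Cf_T + curves.Cb_T)
        assert np.allclose(curves.roi_C, curves.Cf_C)

    def test_linearity_in_gain(self, peptide_plasma, minute_grid):
        k, curves = self._curves(peptide_plasma, minute_grid)
        roi_signal(curves, k, peptide_plasma, eta_T=1.0)
        base = curves.roi_T.copy()
        roi_signal(curves, k, peptide_plasma, eta_T=2.0)
        assert np.allclose(curves.roi_T, 2 * base)

    def test_vascular_only_signal_ratio(self, peptide_plasma):
        t = np.linspace(0, 10, 11)
        k = AgentKinetics(K1=0.0, k2=0.2, vp=0.05)
        curves = UptakeCurves(t=t)
        curves.Cf_T = np.zeros_like(t)
        curves.Cb_T = np.zeros_like(t)
        curves.Cf_C = np.zeros_like(t)
        roi_signal(curves, k, peptide_plasma, eta_T=3.0, eta_C=1.5)
        cp = peptide_plasma.concentration(t)
        ratio = curves.roi_T[cp > 0] / curves.roi_C[cp > 0]
        assert np.allclose(ratio, 2.0)

    def test_identical_channels_give_zero_ratio(self):
        x = np.linspace(1, 5, 20)
        assert np.allclose(bp_ratio(x, x), 0.0)

    def test_zero_control_flagged_as_nan(self):
        out = bp_ratio(np.array([1.0, 2.0]), np.array([0.0, 1.0]))
        assert np.isnan(out[0]) and out[1] == pytest.approx(1.0)

    def test_no_binding_ratio_is_zero(self, peptide_plasma, minute_grid):
        k = AgentKinetics(K1=0.2, k2=0.2, kon=0.0, koff=0.1, Bavail=0.0)
        curves = solve_targeted(k, peptide_plasma, minute_grid)
        curves.Cf_C = solve_control(k, peptide_plasma, minute_grid).Cf_C
        roi_signal(curves, k, peptide_plasma)
        ratio = bp_ratio(curves.roi_T, curves.roi_C)
        finite = np.isfinite(ratio)
        assert np.all(np.abs(ratio[finite]) < 1e-6)

    def test_dose_linearity_leaves_ratio_unchanged(self, peptide_plasma, minute_grid):
        k, curves = self._curves(peptide_plasma, minute_grid)
        roi_signal(curves, k, peptide_plasma)
        ratio1 = bp_ratio(curves.roi_T, curves.roi_C)

        scaled = PlasmaInput(
            A=peptide_plasma.A, alpha=peptide_plasma.alpha,
            B=peptide_plasma.B, beta=peptide_plasma.beta, scale=5.0,
        )
        k2, curves2 = self._curves(scaled, minute_grid)
        roi_signal(curves2, k2, scaled)
        assert np.allclose(curves2.roi_T[1:], 5 * curves.roi_T[1:], rtol=1e-6)
        ratio2 = bp_ratio(curves2.roi_T, curves2.roi_C)
        m = np.isfinite(ratio1)
        assert np.allclose(ratio2[m], ratio1[m], rtol=1e-5, atol=1e-8)


@pytest.mark.filterwarnings("ignore::fgskinetics.kinetics.TraceConditionWarning")
class TestEquilibrium:
    def test_bound_to_free_ratio_approaches_k3_over_k4(self, quasi_constant_plasma):
        k = AgentKinetics(K1=0.1, k2=0.2, kon=0.05, koff=0.1, Bavail=8.0)
        t_eq = 20 * max(1 / k.k2, 1 / k.k4)
        t = np.linspace(0, t_eq, 400)
        curves = solve_targeted(k, quasi_constant_plasma, t)
        ratio = curves.Cb_T[-1] / curves.Cf_T[-1]
        assert ratio == pytest.approx(k.k3 / k.k4, rel=0.01)

    def test_bp_ratio_approaches_binding_potential(self, quasi_constant_plasma):
        # matched agents, constant input, vp = 0: BPratio -> k3/k4 = BP
        k = AgentKinetics(K1=0.1, k2=0.2, kon=0.1, koff=0.1, Bavail=5.0)
        k2a = k.k2 / (1 + k.BP)
        t = np.linspace(0, 20 / k2a, 600)
        curves = solve_targeted(k, quasi_constant_plasma, t)
        curves.Cf_C = solve_control(k, quasi_constant_plasma, t).Cf_C
        roi_signal(curves, k, quasi_constant_plasma)
        ratio = bp_ratio(curves.roi_T, curves.roi_C)
        assert ratio[-1] == pytest.approx(k.BP, rel=0.02)
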