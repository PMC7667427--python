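import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from fgskinetics.metrics import (
    MetricTimeSeries,
    RegionSamples,
    auroc,
    cvr,
    cvr_from_moments,
    find_tmax,
    metric_time_series,
)


class TestCVR:
    def test_zero_contrast(self):
        s = RegionSamples([3.0, 3.5, 2.5], [3.5, 3.0, 2.5])
        assert cvr(s) == pytest.approx(0.0)

    def test_direct_substitution(self):
        # means 3 and 1, both sample SDs sqrt(2): CVR = 2/2 = 1
        s = RegionSamples([2.0, 4.0], [0.0, 2.0])
        assert cvr(s) == pytest.approx(1.0)

    def test_from_moments(self):
        assert cvr_from_moments(5.0, 2.0, 4.0, 3.0) == pytest.approx(0.6)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            cvr(RegionSamples([1.0, 1.0], [2.0, 2.0]))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            cvr(RegionSamples([1.0], [2.0, 3.0]))

    @settings(deadline=None, max_examples=50)
    @given(
        a=st.floats(0.01, 100.0),
        b=st.floats(-50.0, 50.0),
        seed=st.integers(0, 2**16),
    )
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        tum = rng.normal(2.0, 1.0, 30)
        bkg = rng.normal(0.0, 1.0, 30)
        base = cvr(RegionSamples(tum, bkg))
        shifted = cvr(RegionSamples(a * tum + b, a * bkg + b))
        assert shifted == pytest.approx(base, rel=1e-9)


class TestAUROC:
    def test_indistinguishable(self):
        s = RegionSamples([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert auroc(s) == pytest.approx(0.5)

    def test_perfect_separation(self):
        s = RegionSamples([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        assert auroc(s) == pytest.approx(1.0)

    def test_pair_counting_with_ties(self):
        # 9 pairs: 6 wins + 2 ties counted half -> 7/9
        s = RegionSamples([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert auroc(s) == pytest.approx(7.0 / 9.0)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            auroc(RegionSamples([], [1.0]))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        tum = rng.normal(1.0, 1.0, 50)
        bkg = rng.normal(0.0, 1.0, 50)
        base = auroc(RegionSamples(tum, bkg))
        transformed = auroc(RegionSamples(np.exp(tum), np.exp(bkg)))
        assert transformed == pytest.approx(base)

    def test_tracks_cvr_on_gaussian_populations(self):
        # AUROC should rank-correlate with CVR across a separation sweep
        rng = np.random.default_rng(42)
        cvrs, aucs = [], []
        for delta in np.linspace(0.0, 3.0, 15):
            tum = rng.normal(delta, 1.0, 1000)
            bkg = rng.normal(0.0, 1.0, 1000)
            s = RegionSamples(tum, bkg)
            cvrs.append(cvr(s))
            aucs.append(auroc(s))
        rho = spearmanr(cvrs, aucs).statistic
        assert rho > 0.95


class TestMetricTimeSeries:
    def _stacks(self, seed=0, contrast=0.0, n=8):
        rng = np.random.default_rng(seed)
        t = np.arange(n, dtype=float)
        stack = rng.normal(10.0, 1.0, size=(n, 10, 10))
        tumor = np.zeros((10, 10), bool)
        background = np.zeros((10, 10), bool)
        tumor[2:5, 2:5] = True
        background[6:9, 6:9] = True
        stack[:, tumor] += contrast
        return stack, tumor, background, t

    def test_no_contrast_gives_null_metrics(self):
        stack, tum, bkg, t = self._stacks(seed=1)
        out = metric_time_series(stack, None, tum, bkg, t, protocol="SA")
        assert np.all(out.cvr < 1.5)
        assert np.all(np.abs(out.auroc - 0.5) < 0.35)

    def test_sa_ignores_control_stack(self):
        stack, tum, bkg, t = self._stacks(seed=2, contrast=3.0)
        out1 = metric_time_series(stack, None, tum, bkg, t, protocol="SA")
        out2 = metric_time_series(stack, stack * 7.0, tum, bkg, t, protocol="SA")
        assert np.array_equal(out1.cvr, out2.cvr)

    def test_overlapping_masks_rejected(self):
        stack, tum, _, t = self._stacks()
        with pytest.raises(ValueError):
            metric_time_series(stack, None, tum, tum, t)

    def test_pa_requires_control(self):
        stack, tum, bkg, t = self._stacks()
        with pytest.raises(ValueError):
            metric_time_series(stack, None, tum, bkg, t, protocol="PA")


class TestFindTmax:
    def test_constant_curve_window_spans_grid(self):
        t = np.linspace(0, 60, 61)
        win = find_tmax(MetricTimeSeries(t=t, cvr=np.full(61, 2.0)))
        assert win.t_start_98 == t[0]
        assert win.t_end_98 == t[-1]
        assert win.t_start_98 <= win.t_max <= win.t_end_98

    def test_triangular_peak_geometry(self):
        # ramp slope 1/30 per min up to 30 then down: 98% crossings at
        # 30 +/- 0.02*30 = [29.4, 30.6] by linear interpolation
        t = np.linspace(0, 60, 61)
        c = np.where(t <= 30, t / 30, (60 - t) / 30)
        win = find_tmax(MetricTimeSeries(t=t, cvr=c))
        assert win.t_max == pytest.approx(30.0)
        assert win.t_start_98 == pytest.approx(29.4)
        assert win.t_end_98 == pytest.approx(30.6)

    def test_first_index_wins_on_ties(self):
        t = np.linspace(0, 10, 11)
        c = np.zeros(11)
        c[[3, 7]] = 5.0
        assert find_tmax(MetricTimeSeries(t=t, cvr=c)).t_max == pytest.approx(3.0)

    def test_all_nan_rejected(self):
        t = np.linspace(0, 10, 11)
        with pytest.raises(ValueError):
            find_tmax(MetricTimeSeries(t=t, cvr=np.full(11, np.nan)))

    @pytest.mark.filterwarnings("ignore::fgskinetics.kinetics.TraceConditionWarning")
    def test_dense_grid_consistency(self, peptide_plasma):
        # coarse-grid peak within one coarse step of a dense re-evaluation
        from fgskinetics.kinetics import AgentKinetics, kety_closed_form, solve_targeted

        k = AgentKinetics(K1=0.4, k2=0.2, kon=0.1, koff=0.1, Bavail=10.0)

        def curve(t):
            tum = solve_targeted(k, peptide_plasma, t)
            nrm = kety_closed_form(0.1, 0.02, peptide_plasma, t)
            sig_t = tum.Cf_T + tum.Cb_T
            pooled = sig_t + nrm
            c = np.zeros_like(pooled)
            ok = pooled > 0
            c[ok] = np.abs(sig_t[ok] - nrm[ok]) / np.sqrt(pooled[ok])
            return c

        coarse_t = np.arange(0.0, 60.0 + 1e-9, 1.0)
        dense_t = np.arange(0.0, 60.0 + 1e-9, 0.01)
        win_coarse = find_tmax(MetricTimeSeries(t=coarse_t, cvr=curve(coarse_t)))
        win_dense = find_tmax(MetricTimeSeries(t=dense_t, cvr=curve(dense_t)))
        assert abs(win_coarse.t_max - win_dense.t_max) <= 1.0

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 2**16))
    def test_window_always_contains_peak(self, seed):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 30, 40)
        c = np.abs(rng.normal(1.0, 0.5, 40))
        win = find_tmax(MetricTimeSeries(t=t, cvr=c))
        assert win.t_start_98 <= win.t_max <= win.t_end_98
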