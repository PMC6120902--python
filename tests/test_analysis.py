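import numpy as np
import pytest

from gabarect.analysis import (AnalysisError, IVCurve, burst_metrics, fit_biexp,
                               fit_sigmoid_iv, normalized_conductance,
                               rectification_index, remove_action_potentials)
from gabarect.cable import Trace
from gabarect.synapses import (kernel_conductance, KernelParams,
                               mg_block_factor, rectification_factor)


def rect_iv(holds, noise=0.0, rng=None, e_rev=-70.0):
    """Noiseless/noisy IV of a pure rectifying unit synapse."""
    holds = np.asarray(holds, dtype=float)
    i = (holds - e_rev) * rectification_factor(holds)
    if noise:
        i = i + rng.normal(0.0, noise * np.abs(i).max(), i.shape)
    return IVCurve(holds, i, e_rev=e_rev)


def linear_iv(holds, g=0.5, e_rev=-70.0):
    holds = np.asarray(holds, dtype=float)
    return IVCurve(holds, g * (holds - e_rev), e_rev=e_rev)


DENSE = np.arange(-94.0, 27.0, 2.0)
PROTOCOL = np.arange(-94.0, 27.0, 12.0)


class TestSigmoidFit:
    def test_noiseless_parameter_recovery(self):
        fit = fit_sigmoid_iv(rect_iv(DENSE))
        assert fit.e_rev == pytest.approx(-70.0, abs=0.7)
        assert fit.g_min == pytest.approx(0.25, rel=0.01)
        assert fit.g_max == pytest.approx(1.0, rel=0.01)
        assert fit.v50 == pytest.approx(-52.0, abs=0.52)
        assert fit.slope == pytest.approx(3.0, rel=0.01)
        assert not fit.slope_at_bound

    def test_linear_iv_degenerates(self):
        fit = fit_sigmoid_iv(linear_iv(DENSE))
        assert fit.g_max - fit.g_min == pytest.approx(0.0, abs=0.01 * 0.5)

    def test_slope_lower_bound_flagged_on_coarse_holds(self):
        # 12-mV spacing cannot resolve a 3-mV slope: the constraint pins it
        fit = fit_sigmoid_iv(rect_iv(PROTOCOL))
        assert fit.slope >= 12.0 - 1e-9
        assert fit.slope_at_bound

    def test_v50_recovery_calibrated_at_two_percent_noise(self):
        # Monte-Carlo-calibrated tolerance: p95(|dV50|) = 2.4 mV at sigma 2%
        rng = np.random.default_rng(7)
        errs = [abs(fit_sigmoid_iv(rect_iv(DENSE, 0.02, rng)).v50 + 52.0)
                for _ in range(200)]
        assert np.mean(np.asarray(errs) <= 3.0) >= 0.95
        assert np.median(errs) < 1.5

    def test_too_few_points_rejected(self):
        with pytest.raises(AnalysisError):
            fit_sigmoid_iv(rect_iv([-94.0, -70.0, -40.0, 0.0]))

    def test_normalization_by_minus_seventy(self):
        # reversal away from -70 so the normalization current is nonzero
        fit = fit_sigmoid_iv(rect_iv(DENSE, e_rev=-82.0), normalize_at=-70.0)
        assert fit.v50 == pytest.approx(-52.0, abs=0.6)


class TestRectificationIndex:
    def test_linear_synapse_gives_one(self):
        assert rectification_index(linear_iv(PROTOCOL)) == pytest.approx(1.0, abs=1e-6)

    def test_pure_rectifying_synapse_near_four(self):
        assert rectification_index(rect_iv(PROTOCOL)) == pytest.approx(4.0, abs=0.2)

    def test_mixed_synapse_near_two_and_half(self):
        i = (PROTOCOL + 70.0) * (0.2 + 0.8 * rectification_factor(PROTOCOL))
        ri = rectification_index(IVCurve(PROTOCOL, i, e_rev=-70.0))
        assert ri == pytest.approx(2.5, rel=0.05)

    def test_fit_interpolation_path(self):
        holds = np.arange(-97.0, 24.0, 6.0)  # nearest hold to -82 is 3 mV away
        ri = rectification_index(rect_iv(holds))
        assert ri == pytest.approx(4.0, rel=0.15)

    def test_noisy_replicates_centered_on_four(self):
        # per-replicate spread is wide because the -82 mV signal is only ~3 %
        # of the maximal current; the seeded median must stay near 4
        rng = np.random.default_rng(3)
        ris = [rectification_index(rect_iv(DENSE, 0.02, rng),
                                   interpolate_with_fit=True)
               for _ in range(100)]
        assert 3.8 <= np.median(ris) <= 4.2
        assert np.mean(np.abs(np.asarray(ris) - 4.0) < 1.5) >= 0.9

    def test_insufficient_outward_range_rejected(self):
        with pytest.raises(AnalysisError):
            rectification_index(rect_iv(np.arange(-94.0, -50.0, 6.0)))

    def test_voltage_independent_conductance_invariant(self):
        for g in (0.1, 1.0, 7.3):
            assert rectification_index(linear_iv(DENSE, g=g)) == pytest.approx(
                1.0, abs=1e-6)


class TestBiexpFit:
    def _trace(self, y, dt=0.05):
        return Trace("t", dt, dt, np.asarray(y))

    def test_single_exponential_decay(self):
        t = np.arange(0, 150, 0.05)
        y = np.where(t < 10, 0.0, 50 * np.exp(-(t - 10) / 15.0))
        fit = fit_biexp(self._trace(y))
        assert fit.weighted_tau == pytest.approx(15.0, rel=0.02)

    def test_weighted_tau_formula(self):
        t = np.arange(0, 400, 0.05)
        y = np.where(t < 10, 0.0,
                     0.7 * np.exp(-(t - 10) / 10.0) + 0.3 * np.exp(-(t - 10) / 50.0))
        fit = fit_biexp(self._trace(y))
        # (0.7*10 + 0.3*50) / 1.0
        assert fit.weighted_tau == pytest.approx(22.0, rel=0.05)

    def test_kernel_decay_recovery(self):
        t = np.arange(0, 300, 0.05)
        y = kernel_conductance(t - 10.0, KernelParams(1.0, 30.0), 1.0)
        fit = fit_biexp(self._trace(y))
        assert fit.weighted_tau == pytest.approx(30.0, rel=0.02)
        assert fit.tau_rise == pytest.approx(1.0, rel=0.2)

    def test_negative_going_psc(self):
        t = np.arange(0, 200, 0.05)
        y = -kernel_conductance(t - 10.0, KernelParams(1.0, 30.0), 80.0)
        fit = fit_biexp(self._trace(y))
        assert fit.amplitude == pytest.approx(-80.0, rel=0.01)
        assert fit.weighted_tau == pytest.approx(30.0, rel=0.02)

    def test_peak_at_edge_rejected(self):
        y = np.linspace(0, 1, 100)
        with pytest.raises(AnalysisError):
            fit_biexp(self._trace(y))


class TestBurstMetrics:
    def test_flat_trace_zero_integral(self):
        tr = Trace("flat", 0.1, 0.1, np.full(5000, -70.0))
        m = burst_metrics(tr)
        assert m.integral == 0.0 and m.t_start is None

    def test_band_limited_rectangle_area(self):
        from scipy.ndimage import gaussian_filter1d
        dt = 0.1
        t = np.arange(0, 400, dt)
        y = np.where((t >= 100) & (t < 200), 5.0, 0.0)
        y = gaussian_filter1d(y, 10)  # 1-ms smoothing: band-limited edges
        m = burst_metrics(Trace("rect", dt, dt, y), baseline=0.0)
        assert m.integral == pytest.approx(500.0, rel=0.03)
        assert m.peak_amplitude == pytest.approx(5.0, rel=0.02)

    def test_baseline_offset_invariance(self):
        dt = 0.1
        t = np.arange(0, 300, dt)
        y = np.exp(-((t - 100) / 30.0) ** 2) * 8.0
        m0 = burst_metrics(Trace("a", dt, dt, y), baseline=0.0)
        m1 = burst_metrics(Trace("b", dt, dt, y - 70.0), baseline=-70.0)
        assert m1.integral == pytest.approx(m0.integral, rel=1e-9)

    def test_ap_removal_reduces_integral(self):
        dt = 0.025
        t = np.arange(0, 300, dt)
        y = -70 + 10 * np.exp(-((t - 100) / 40.0) ** 2)
        spike = 60 * np.exp(-((t - 100) / 0.8) ** 2)  # fast AP-like transient
        tr = Trace("ap", dt, dt, y + spike)
        with_ap = burst_metrics(tr, baseline=-70.0)
        without = burst_metrics(tr, baseline=-70.0, remove_aps=True)
        assert without.integral < with_ap.integral

    def test_ap_clipping_preserves_subthreshold(self):
        dt = 0.025
        t = np.arange(0, 200, dt)
        y = -70 + 5 * np.exp(-((t - 80) / 30.0) ** 2)  # slow: max 0.3 V/s
        tr = Trace("slow", dt, dt, y)
        clipped = remove_action_potentials(tr)
        assert np.array_equal(clipped.values, y)

    def test_open_ended_response_flagged(self):
        dt = 0.1
        t = np.arange(0, 200, dt)
        y = np.where(t > 50, 5.0, 0.0)
        m = burst_metrics(Trace("open", dt, dt, y), baseline=0.0)
        assert m.open_ended


class TestNormalizedConductance:
    def test_unity_at_normalization_level(self):
        v, g = normalized_conductance(rect_iv(PROTOCOL), -70.0, 14.0)
        assert g[np.argmin(np.abs(v - 14.0))] == pytest.approx(1.0)

    def test_linear_synapse_flat(self):
        v, g = normalized_conductance(linear_iv(PROTOCOL), -70.0, 14.0)
        assert np.allclose(g, 1.0)

    def test_nmda_model_ratio_identity(self):
        holds = PROTOCOL
        i = mg_block_factor(holds) * (holds - 0.0)
        iv = IVCurve(holds, i, e_rev=0.0)
        v, g = normalized_conductance(iv, 0.0, 26.0)
        measured = g[np.argmin(np.abs(v + 70.0))]
        assert measured == pytest.approx(
            mg_block_factor(-70.0) / mg_block_factor(26.0), rel=1e-9)

    def test_missing_normalization_level_rejected(self):
        with pytest.raises(AnalysisError):
            normalized_conductance(rect_iv(PROTOCOL), -70.0, 15.0)
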