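import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gabarect.synapses as S


class TestKernel:
    def test_zero_before_onset(self):
        kp = S.KernelParams(1.0, 30.0, onset_delay=5.0)
        t = np.array([-1.0, 0.0, 4.9, 5.0])
        assert np.all(S.kernel_conductance(t, kp, 1.0) == 0.0)

    def test_peak_equals_weight(self):
        kp = S.KernelParams(1.0, 30.0)
        t = np.linspace(0, 200, 200001)
        g = S.kernel_conductance(t, kp, 0.7)
        assert g.max() == pytest.approx(0.7, rel=1e-6)

    def test_peak_time_closed_form(self):
        kp = S.KernelParams(1.0, 30.0)
        tp = S.kernel_peak_time(kp)
        assert tp == pytest.approx(30.0 / 29.0 * np.log(30.0), rel=1e-12)
        assert tp == pytest.approx(3.52, abs=0.005)

    def test_invalid_taus_rejected(self):
        with pytest.raises(S.SynapseError):
            S.KernelParams(30.0, 1.0)
        with pytest.raises(S.SynapseError):
            S.KernelParams(2.0, 2.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.1, 10.0), st.floats(1.1, 20.0))
    def test_normalization_property(self, tau_r, ratio):
        kp = S.KernelParams(tau_r, tau_r * ratio)
        t = np.linspace(0, 30 * kp.tau_decay, 50001)
        g = S.kernel_conductance(t, kp, 1.0)
        assert g.max() == pytest.approx(1.0, rel=1e-4)
        assert np.all(g >= 0)


class TestMgBlock:
    def test_no_block_without_magnesium(self):
        p = S.MgBlockParams(mg_mM=0.0)
        for v in (-100.0, -50.0, 0.0, 50.0):
            assert S.mg_block_factor(v, p) == 1.0

    def test_direct_evaluation_at_minus_ten(self):
        # exponent vanishes at v = -10 mV: factor = 1/(1 + 0.2801)
        assert S.mg_block_factor(-10.0) == pytest.approx(1 / 1.2801, rel=1e-9)

    def test_monotone_increasing_with_limit_one(self):
        v = np.linspace(-120, 120, 200)
        f = S.mg_block_factor(v)
        assert np.all(np.diff(f) > 0)
        assert np.all((f > 0) & (f <= 1))
        assert S.mg_block_factor(500.0) == pytest.approx(1.0, abs=1e-9)


class TestRectification:
    def test_midpoint(self):
        assert S.rectification_factor(-52.0) == pytest.approx(0.625)

    def test_floor(self):
        assert S.rectification_factor(-1000.0) == pytest.approx(0.25)

    def test_resting_fraction_near_quarter(self):
        # ~25 % of maximal conductance at the -70 mV resting potential
        f = S.rectification_factor(-70.0)
        assert f == pytest.approx(0.252, abs=0.001)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-150, 100))
    def test_bounded_in_floor_one(self, v):
        f = S.rectification_factor(v)
        assert 0.25 <= f <= 1.0


class TestCompositeGaba:
    def test_unit_synapse_resting_conductance(self):
        spec = S.preset("gabaA_nonlinear_unit")
        assert S.gaba_peak_conductance(spec, -70.0) == pytest.approx(0.40, abs=0.005)

    def test_branch_synapse_rest_and_max(self):
        spec = S.preset("gabaA_nonlinear_branch")
        assert S.gaba_peak_conductance(spec, -70.0) == pytest.approx(0.28, abs=0.005)
        assert S.gaba_peak_conductance(spec, 30.0) == pytest.approx(0.70, abs=0.005)

    def test_nam_variant_rest_and_max(self):
        spec = S.make_nam_variant(S.preset("gabaA_nonlinear_branch"))
        assert S.gaba_peak_conductance(spec, -70.0) == pytest.approx(0.21, abs=0.005)
        assert S.gaba_peak_conductance(spec, 30.0) == pytest.approx(0.42, abs=0.005)

    def test_rectifying_only_variant(self):
        spec = S.make_rectifying_only(S.preset("gabaA_nonlinear_branch"))
        assert S.gaba_peak_conductance(spec, -70.0) == pytest.approx(0.14, abs=0.005)
        assert S.gaba_peak_conductance(spec, 30.0) == pytest.approx(0.56, abs=0.005)

    def test_linear_variant_is_constant(self):
        spec = S.make_linear_variant(S.preset("gabaA_nonlinear_unit"))
        g = [S.gaba_peak_conductance(spec, v) for v in (-90.0, -70.0, -30.0, 0.0)]
        assert np.allclose(g, g[0])
        assert g[0] == pytest.approx(0.40, abs=0.005)

    def test_mixed_peak_rectification_near_two_and_half(self):
        spec = S.preset("gabaA_nonlinear_unit")
        ratio = (S.gaba_peak_conductance(spec, 30.0)
                 / S.gaba_peak_conductance(spec, -70.0))
        assert ratio == pytest.approx(2.5, rel=0.02)

    def test_rectifying_component_ratio_near_four(self):
        spec = S.make_rectifying_only(S.preset("gabaA_nonlinear_unit"))
        ratio = (S.gaba_peak_conductance(spec, 30.0)
                 / S.gaba_peak_conductance(spec, -70.0))
        assert ratio == pytest.approx(4.0, rel=0.02)

    def test_non_gaba_kind_rejected(self):
        with pytest.raises(S.SynapseError):
            S.gaba_peak_conductance(S.preset("nmda"), -70.0)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(S.SynapseError):
            S.SynapseSpec("AMPA", 1.0, 0.0,
                          (S.SynapseComponent(0.5, S.KernelParams(0.2, 2.0)),))


class TestFastVariants:
    def test_amplitude_scaled_weight(self):
        fast = S.make_fast_variant(S.preset("gabaA_nonlinear_branch"), 5.0,
                                   "amplitude_scaled")
        assert fast.weight_nS == pytest.approx(3.5)
        assert all(c.kernel.tau_decay == pytest.approx(6.0) for c in fast.components)
        assert all(c.kernel.tau_rise == pytest.approx(0.2) for c in fast.components)

    def test_charge_preserving_weight(self):
        fast = S.make_fast_variant(S.preset("gabaA_nonlinear_unit"), 5.0,
                                   "charge_preserving")
        # 0.2 * (15/6) + 0.8 * (30/6) nS
        assert fast.weight_nS == pytest.approx(4.5)

    def test_identity_at_factor_one(self):
        spec = S.preset("gabaA_nonlinear_unit")
        assert S.make_fast_variant(spec, 1.0, "amplitude_scaled") is spec

    def test_unknown_mode_rejected(self):
        with pytest.raises(S.SynapseError):
            S.make_fast_variant(S.preset("gabaA_nonlinear_unit"), 5.0, "bogus")

    def test_charge_preserving_integral_within_one_percent(self):
        spec = S.preset("gabaA_nonlinear_unit")
        fast = S.make_fast_variant(spec, 5.0, "charge_preserving")
        t = np.linspace(0, 400, 400001)
        v = -20.0
        def total_g(s):
            return sum(S.kernel_conductance(t, c.kernel, c.fraction * s.weight_nS)
                       * c.factor(v) for c in s.components)
        q_slow = np.trapezoid(total_g(spec), t)
        q_fast = np.trapezoid(total_g(fast), t)
        assert q_fast == pytest.approx(q_slow, rel=0.01)


class TestSTP:
    @pytest.mark.parametrize("sid,expected", [
        ("glut_5at50", (1.0, 1.5, 1.8, 1.9, 2.0)),
        ("glut_branch", (1.0, 1.5, 2.0, 2.0, 2.0)),
        ("glut_3at200", (1.0, 1.5, 1.8)),
        ("gaba_SR", (1.0, 0.7, 0.7, 0.7, 0.7)),
        ("gaba_SLM", (1.0, 0.6, 0.5, 0.4, 0.4)),
    ])
    def test_schedules(self, sid, expected):
        assert S.stp_schedule(sid) == expected

    def test_none_is_all_ones(self):
        assert S.stp_schedule("none", 4) == (1.0, 1.0, 1.0, 1.0)

    def test_unknown_schedule_rejected(self):
        with pytest.raises(S.SynapseError):
            S.stp_schedule("bogus")

    def test_stim_train_monotone_times(self):
        with pytest.raises(S.SynapseError):
            S.StimTrain((0.0, 10.0, 10.0))
        tr = S.StimTrain.burst(5, 50.0)
        assert tr.times_ms == (0.0, 20.0, 40.0, 60.0, 80.0)


class TestRelease:
    def test_probability_one_all_active(self):
        act = S.sample_release(20, [1.0, 1.0], "bernoulli", seed=3)
        assert act.all()

    def test_expected_count_is_exact(self):
        act = S.sample_release(150, [0.1, 0.15, 0.18], "expected_count", seed=0)
        assert list(act.sum(axis=0)) == [15, 22, 27]

    def test_bernoulli_mean_within_three_standard_errors(self):
        n, p, reps = 150, 0.1, 200
        counts = [S.sample_release(n, [p], "bernoulli", seed=s).sum()
                  for s in range(reps)]
        se = np.sqrt(n * p * (1 - p) / reps)
        assert abs(np.mean(counts) - n * p) < 3 * se

    def test_seeded_reproducibility(self):
        a = S.sample_release(50, [0.3, 0.5], "bernoulli", seed=11)
        b = S.sample_release(50, [0.3, 0.5], "bernoulli", seed=11)
        assert np.array_equal(a, b)
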