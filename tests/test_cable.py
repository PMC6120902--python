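import numpy as np
import pytest

import gabarect.biophysics as bp
from gabarect.cable import (SimConfig, SolverError, SynapticInput, assemble,
                            simulate, single_compartment_grid, voltage_clamp)
from gabarect.morphology import Location, build_single_branch
from gabarect.synapses import (LINEAR_KERNEL, RECT_KERNEL, kernel_conductance,
                               preset, rectification_factor)

PATCH_R_OHM = 60000 / 1e-5  # Rm / (1000 um^2) = 6 GOhm


class TestAssembly:
    def test_single_compartment_no_axial(self, leak_channels, passive):
        g = single_compartment_grid(1000.0, leak_channels, passive)
        assert g.n == 1 and g.g_axial[0] == 0.0

    def test_tree_has_n_minus_one_couplings(self, leak_channels):
        m = build_single_branch(100.0, 2.0, 11)
        g = assemble(m, leak_channels)
        assert np.count_nonzero(g.g_axial) == g.n - 1
        # the 11 branch compartments form a path: 10 couplings among them
        branch = g.section_id == 1
        assert branch.sum() == 11

    def test_area_conservation(self, leak_channels, ca1_morph):
        g = assemble(ca1_morph, leak_channels)
        assert g.total_area_cm2() == pytest.approx(
            ca1_morph.total_area_um2() * 1e-8, rel=1e-9)

    def test_kdr_deleted_beyond_100um(self, ca1_morph, passive):
        chans = bp.default_channels(passive)
        g = assemble(ca1_morph, chans)
        kdr = next(gbar for spec, gbar in g.channels if spec.kind == "KDR")
        dend = g.section_id != 0
        assert np.all(kdr[dend & (g.dist_um > 100.0)] == 0.0)
        assert np.any(kdr[g.dist_um <= 100.0] > 0.0)

    def test_density_ramp_applied_per_compartment(self, ca1_morph, passive):
        g = assemble(ca1_morph, bp.default_channels(passive))
        ka_spec, ka = next((s, gb) for s, gb in g.channels if s.kind == "KA")
        i = int(np.argmax(g.dist_um))
        expected = bp.density_at(ka_spec.rule, g.dist_um[i]) * g.area_cm2[i] * 1e9
        assert ka[i] == pytest.approx(expected, rel=1e-12)

    def test_empty_morphology_rejected(self, leak_channels):
        from gabarect.morphology import Morphology
        with pytest.raises(Exception):
            assemble(Morphology.__new__(Morphology), leak_channels)


class TestEquilibrium:
    def test_rest_is_stationary(self, branch_grid):
        res = simulate(branch_grid, config=SimConfig(t_stop=500.0, settle=200.0),
                       record=[Location(1, 0.5)])
        assert np.max(np.abs(res["v0"].values + 70.0)) < 0.1

    def test_rc_step_response_closed_form(self, patch_grid):
        cfg = SimConfig(dt=0.025, t_stop=400.0, settle=300.0)
        res = simulate(patch_grid, config=cfg,
                       injections=[(Location(0, 0.5), 10.0, 0.0, 400.0)])
        t = res["v0"].time()
        step_mV = 10e-12 * PATCH_R_OHM * 1e3
        pred = -70 + step_mV * (1 - np.exp(-t / 60.0))
        dev = np.max(np.abs(res["v0"].values - pred))
        assert dev < 0.01 * step_mV


class TestConvergence:
    def _burst_peak(self, dt, scheme="backward_euler"):
        m = build_single_branch(100.0, 2.0, 11)
        g = assemble(m, [bp.ChannelSpec("leak", bp.DensityRule(1 / 60000), -70.0)])
        center = Location(1, 0.5)
        events = [(10.0 + 20 * k, f) for k, f in enumerate((1, 1.5, 2, 2, 2))]
        inputs = [SynapticInput(preset("ampa_branch", weight=0.42), center, events),
                  SynapticInput(preset("nmda", weight=0.42), center, events),
                  SynapticInput(preset("gabaA_nonlinear_branch"), center,
                                [(10.0 + 20 * k, 1.0) for k in range(5)])]
        res = simulate(g, inputs, SimConfig(dt=dt, t_stop=200.0, settle=300.0,
                                            scheme=scheme), record=[center])
        return res["v0"].values.max()

    def test_halving_dt_changes_peak_below_half_percent(self):
        p1 = self._burst_peak(0.025)
        p2 = self._burst_peak(0.0125)
        assert abs(p2 - p1) / abs(p2 + 70.0) < 0.005

    def test_crank_nicolson_second_order_backward_euler_first(self, patch_grid):
        def err(dt, scheme):
            cfg = SimConfig(dt=dt, t_stop=40.0, settle=100.0, scheme=scheme)
            res = simulate(patch_grid, config=cfg,
                           injections=[(Location(0, 0.5), 10.0, 0.0, 40.0)])
            t = res["v0"].time()
            k = np.argmin(np.abs(t - 30.0))
            exact = -70 + 10e-12 * PATCH_R_OHM * 1e3 * (1 - np.exp(-t[k] / 60.0))
            return abs(res["v0"].values[k] - exact)

        be = [err(dt, "backward_euler") for dt in (0.4, 0.2, 0.1)]
        cn = [err(dt, "crank_nicolson") for dt in (0.4, 0.2, 0.1)]
        for a, b in zip(be, be[1:]):
            assert a / b == pytest.approx(2.0, rel=0.15)   # first order
        for a, b in zip(cn, cn[1:]):
            assert a / b == pytest.approx(4.0, rel=0.25)   # second order


class TestVoltageClamp:
    def test_zero_driving_force_at_reversal(self, patch_grid, quick_cfg):
        spec = preset("gabaA_nonlinear_unit")
        inp = SynapticInput(spec, Location(0, 0.5), [(10.0, 1.0)])
        tr = voltage_clamp(patch_grid, spec.reversal, Location(0, 0.5), [inp],
                           quick_cfg)
        i = tr.values
        base = i[tr.time() < 9.0].mean()
        # zero up to the clamp penalty's pA-scale quantization
        assert np.max(np.abs(i - base)) < 1e-3

    def test_isopotential_clamp_current_identity(self, patch_grid, quick_cfg):
        # synaptic clamp current equals g(t, V_hold) * (V_hold - E) with the
        # event applied at the start of its step (one-step offset)
        spec = preset("gabaA_nonlinear_unit")
        inp = SynapticInput(spec, Location(0, 0.5), [(10.0, 1.0)])
        tr = voltage_clamp(patch_grid, -40.0, Location(0, 0.5), [inp], quick_cfg)
        t = tr.time()
        base = tr.values[t < 9.0].mean()
        elapsed = t - 10.0 - quick_cfg.dt
        g = (kernel_conductance(elapsed, RECT_KERNEL, 0.8)
             * rectification_factor(-40.0)
             + kernel_conductance(elapsed, LINEAR_KERNEL, 0.2))
        pred = g * (-40.0 - spec.reversal)
        assert np.max(np.abs(tr.values - base - pred)) < 1e-3

    def test_leak_only_ohmic_difference(self, patch_grid, quick_cfg):
        i1 = voltage_clamp(patch_grid, -60.0, Location(0, 0.5), [], quick_cfg)
        i2 = voltage_clamp(patch_grid, -50.0, Location(0, 0.5), [], quick_cfg)
        g_leak_nS = 1e9 / PATCH_R_OHM
        diff = i2.values[-1] - i1.values[-1]
        assert diff == pytest.approx(g_leak_nS * 10.0, rel=1e-4)

    def test_command_shorter_than_t_stop_rejected(self, patch_grid):
        cfg = SimConfig(t_stop=100.0, settle=50.0)
        with pytest.raises(SolverError):
            simulate(patch_grid, config=cfg,
                     clamp=(Location(0, 0.5), np.full(10, -70.0)))


class TestChargeConservation:
    def test_axial_current_antisymmetry(self, leak_channels):
        m = build_single_branch(50.0, 2.0, 1)
        g = assemble(m, leak_channels)
        assert g.n == 2
        cfg = SimConfig(dt=0.05, t_stop=50.0, settle=100.0)
        res = simulate(g, config=cfg,
                       record=[Location(0, 0.5), Location(1, 0.5)],
                       injections=[(Location(1, 0.5), 20.0, 0.0, 50.0)])
        v0, v1 = res["v0"].values, res["v1"].values
        ga = g.g_axial[1]
        i_01 = ga * (v0 - v1)
        i_10 = ga * (v1 - v0)
        assert np.max(np.abs(i_01 + i_10)) < 1e-12

    def test_sealed_cable_input_resistance(self, branch_grid):
        cfg = SimConfig(dt=0.05, t_stop=2500.0, settle=2000.0)
        res = simulate(branch_grid, config=cfg, record=[Location(1, 0.5)],
                       injections=[(Location(1, 0.5), 1.0, 0.0, 2500.0)])
        r_gohm = (res["v0"].values[-1] + 70.0) / 1.0  # mV/pA = GOhm
        iso = 60000 / (np.pi * 2e-4 * 100e-4) / 1e9
        assert r_gohm == pytest.approx(iso, rel=0.02)


class TestReproducibility:
    def test_bitwise_identical_reruns(self, branch_grid, quick_cfg):
        inp = [SynapticInput(preset("gabaA_nonlinear_branch"), Location(1, 0.5),
                             [(10.0, 1.0)])]
        a = simulate(branch_grid, inp, quick_cfg, record=[Location(1, 0.5)])
        b = simulate(branch_grid, inp, quick_cfg, record=[Location(1, 0.5)])
        assert np.array_equal(a["v0"].values, b["v0"].values)

    def test_unknown_location_rejected(self, branch_grid, quick_cfg):
        with pytest.raises(SolverError):
            simulate(branch_grid, config=quick_cfg, record=[Location(77, 0.5)])
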