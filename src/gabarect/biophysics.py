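"""Distributed membrane mechanisms and their density rules.

Channels are described by a density rule (S/cm^2 as a function of path
distance), a reversal potential, and — for gated channels — one or two
Hodgkin–Huxley-style gates with Boltzmann steady states and bell-shaped
voltage-dependent time constants.  The tonic inhibitory conductance is a
stateless, outward-rectifying conductance sharing the sigmoid voltage
dependence of the rectifying synaptic GABA-A component (floor 0.25 of maximum
at hyperpolarized potentials, half activation at -52 mV with a 3 mV slope).

Units: voltages mV, time ms, densities S/cm^2, current densities mA/cm^2
(S/cm^2 times mV is exactly mA/cm^2).

The HCN, A-type and delayed-rectifier gate parameters are generic textbook
forms exposed through configuration; only their density rules and reversal
potentials carry quantitative weight here (HCN reversal -30 mV, E_K -95 mV,
deletion of the delayed rectifier from dendrites beyond 100 um, the 1 %/um
A-type ramp between 50 and 300 um, and the 3 %/um HCN ramp up to 500 um).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .synapses import RectificationParams, rectification_factor

__all__ = [
    "PassiveConstants",
    "DensityRule",
    "GateParams",
    "ChannelSpec",
    "ChannelError",
    "density_at",
    "channel_current",
    "tonic_current",
    "default_channels",
    "CHANNEL_KINDS",
]

CHANNEL_KINDS = ("leak", "HCN", "KA", "KDR", "tonicGABA")


class ChannelError(ValueError):
    pass


@dataclass(frozen=True)
class PassiveConstants:
    """Cable constants of the pyramidal-cell membrane."""

    c_m: float = 1.0       # uF/cm^2
    r_i: float = 200.0     # Ohm*cm
    r_m: float = 60_000.0  # Ohm*cm^2 (60 kOhm*cm^2)
    e_leak: float = -90.0  # mV
    e_na: float = 55.0     # mV
    e_k: float = -95.0     # mV

    def __post_init__(self):
        if min(self.c_m, self.r_i, self.r_m) <= 0:
            raise ChannelError("passive constants must be positive")

    @property
    def tau_m_ms(self) -> float:
        """Membrane time constant R_m * C_m of an isopotential patch (ms)."""
        return self.r_m * self.c_m * 1e-3  # Ohm*cm^2 * uF/cm^2 = us*1e3 = ms


@dataclass(frozen=True)
class DensityRule:
    """Linear distance ramp: constant base below ``start_um``, rising by
    ``slope_per_um`` (fraction of base per um) up to ``end_um``, clamped
    beyond."""

    base: float                 # S/cm^2
    slope_per_um: float = 0.0   # e.g. 0.01 for 1 %/um
    start_um: float = 0.0
    end_um: float = float("inf")
    region: tuple[str, ...] = ()  # type labels; empty = everywhere

    def __post_init__(self):
        if self.base < 0 or self.slope_per_um < 0:
            raise ChannelError("density and slope must be non-negative")
        if self.start_um > self.end_um:
            raise ChannelError("ramp start beyond ramp end")


def density_at(rule: DensityRule, distance_um: float) -> float:
    """Channel density (S/cm^2) at a path distance from the soma."""
    d = np.asarray(distance_um, dtype=float)
    if np.any(d < 0):
        raise ChannelError("negative path distance")
    ramp = np.clip(d, rule.start_um, rule.end_um) - rule.start_um
    out = rule.base * (1.0 + rule.slope_per_um * ramp)
    return float(out) if np.isscalar(distance_um) else out


@dataclass(frozen=True)
class GateParams:
    """Boltzmann steady state with a bell-shaped time constant.

    inf(v) = 1 / (1 + exp((v_half - v) / k));  k < 0 yields a gate that closes
    with depolarization (used for HCN activation and K-channel inactivation).
    tau(v) = tau_base + tau_amp / cosh((v - tau_vhalf) / tau_width).
    """

    v_half: float
    k: float
    tau_base: float = 1.0
    tau_amp: float = 0.0
    tau_vhalf: float = 0.0
    tau_width: float = 20.0
    power: int = 1

    def inf(self, v):
        return 1.0 / (1.0 + np.exp((self.v_half - np.asarray(v, float)) / self.k))

    def tau(self, v):
        return self.tau_base + self.tau_amp / np.cosh(
            (np.asarray(v, float) - self.tau_vhalf) / self.tau_width)


@dataclass(frozen=True)
class ChannelSpec:
    kind: str
    rule: DensityRule
    reversal: float
    gate: GateParams | None = None
    gate2: GateParams | None = None      # optional inactivation gate
    rect: RectificationParams | None = None  # tonicGABA only

    def __post_init__(self):
        if self.kind not in CHANNEL_KINDS:
            raise ChannelError(f"unknown channel kind {self.kind!r}")
        if self.kind in ("HCN", "KA", "KDR") and self.gate is None:
            raise ChannelError(f"{self.kind} requires gate parameters")
        if self.kind == "tonicGABA" and self.rect is None:
            raise ChannelError("tonicGABA requires rectification parameters")


def init_gate_state(spec: ChannelSpec, v_mV: float) -> tuple[float, ...] | None:
    """Steady-state gate values at the given voltage (None for stateless)."""
    if spec.gate is None:
        return None
    state = [float(spec.gate.inf(v_mV))]
    if spec.gate2 is not None:
        state.append(float(spec.gate2.inf(v_mV)))
    return tuple(state)


def channel_current(spec: ChannelSpec, v_mV: float, state, dt_ms: float,
                    density: float | None = None):
    """One implicit gating step; returns (current density mA/cm^2, new state).

    ``density`` overrides the rule's base density (callers evaluating a ramp
    pass the local value); the leak and tonic conductances are stateless.
    """
    g = spec.rule.base if density is None else density
    if spec.kind == "leak":
        return g * (v_mV - spec.reversal), None
    if spec.kind == "tonicGABA":
        return tonic_current(g, v_mV, spec.rect, spec.reversal), None
    if state is None:
        raise ChannelError(f"{spec.kind}: gate state not initialized")
    m = _implicit_gate(spec.gate, state[0], v_mV, dt_ms)
    new_state = [m]
    gv = g * m ** spec.gate.power
    if spec.gate2 is not None:
        h = _implicit_gate(spec.gate2, state[1], v_mV, dt_ms)
        new_state.append(h)
        gv *= h
    return gv * (v_mV - spec.reversal), tuple(new_state)


def _implicit_gate(gate: GateParams, m: float, v: float, dt: float) -> float:
    tau = float(gate.tau(v))
    inf = float(gate.inf(v))
    return (m + dt * inf / tau) / (1.0 + dt / tau)


def tonic_current(density: float, v_mV: float, rect: RectificationParams,
                  e_rev: float) -> float:
    """Outward-rectifying tonic GABA current density (mA/cm^2).

    Conductance scales linearly in ``density`` and multiplicatively with the
    rectification sigmoid evaluated at the local voltage.
    """
    if density < 0:
        raise ChannelError("tonic density must be non-negative")
    return density * rectification_factor(v_mV, rect) * (v_mV - e_rev)


# ---------------------------------------------------------------------------
# Standard channel set of the full-cell model
# ---------------------------------------------------------------------------

# Half-activation chosen so the leak/HCN/K balance of the full-cell model
# rests near -70 mV; tau spans the 20-60 ms range.
HCN_GATE = GateParams(v_half=-90.0, k=-6.0, tau_base=20.0, tau_amp=40.0,
                      tau_vhalf=-90.0, tau_width=20.0)
KA_GATE = GateParams(v_half=-30.0, k=10.0, tau_base=1.0, tau_amp=4.0,
                     tau_vhalf=-40.0, tau_width=25.0)
KA_INACT = GateParams(v_half=-60.0, k=-8.0, tau_base=20.0, tau_amp=0.0)
KDR_GATE = GateParams(v_half=-5.0, k=9.0, tau_base=1.5, tau_amp=4.0,
                      tau_vhalf=-20.0, tau_width=25.0)

TONIC_RECT = RectificationParams(v50=-52.0, v_slope=3.0)


def default_channels(passive: PassiveConstants | None = None,
                     with_hcn: bool = True,
                     with_k: bool = True,
                     tonic_density: float = 0.0,
                     e_gaba: float = -70.0,
                     e_leak: float | None = None) -> list[ChannelSpec]:
    """Channel set of the full-cell model.

    Leak everywhere at 1/R_m; HCN at 0.2 mS/cm^2 in soma and basal dendrites
    and ramping at 3 %/um along the apical tree up to 500 um; A-type K at
    1 mS/cm^2 ramping 1 %/um between 50 and 300 um; delayed rectifier in the
    soma and proximal dendrites only (deleted beyond 100 um by the assembler);
    optional tonic inhibition ramping 3 %/um between 50 and 300 um.
    """
    p = passive or PassiveConstants()
    el = p.e_leak if e_leak is None else e_leak
    chans = [ChannelSpec("leak", DensityRule(1.0 / p.r_m), el)]
    if with_hcn:
        chans.append(ChannelSpec("HCN", DensityRule(2e-4, region=("soma", "basal")),
                                 -30.0, gate=HCN_GATE))
        chans.append(ChannelSpec(
            "HCN", DensityRule(2e-4, slope_per_um=0.03, start_um=0.0, end_um=500.0,
                               region=("apical_trunk", "apical_oblique", "tuft")),
            -30.0, gate=HCN_GATE))
    if with_k:
        chans.append(ChannelSpec(
            "KA", DensityRule(1e-3, slope_per_um=0.01, start_um=50.0, end_um=300.0),
            p.e_k, gate=KA_GATE, gate2=KA_INACT))
        chans.append(ChannelSpec("KDR", DensityRule(5e-3), p.e_k, gate=KDR_GATE))
    if tonic_density > 0:
        chans.append(ChannelSpec(
            "tonicGABA",
            DensityRule(tonic_density, slope_per_um=0.03, start_um=50.0, end_um=300.0),
            e_gaba, rect=TONIC_RECT))
    return chans
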