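"""Synaptic conductance models.

The conductance time course of every receptor type is a peak-normalized
difference of exponentials (rise/decay), multiplied for voltage-dependent
receptors by an instantaneous factor evaluated at the local membrane
potential:

* NMDA receptors carry the magnesium-block factor
  ``1 / (1 + 0.2801 [Mg] exp(-0.087 (v + 10)))`` with [Mg] = 1 mM, an
  increasing sigmoid that releases the block with depolarization.

* The slow dendritic GABA-A component carried by alpha5-subunit receptors is
  outward rectifying:
  ``0.25 + 0.75 / (1 + exp(-(v - V50)/Vslope))`` with V50 = -52 mV and
  Vslope = 3 mV, i.e. a floor of 25 % of the maximal conductance at rest and
  a four-fold increase above -50 mV.

A composite dendritic GABA-A synapse mixes a fast linear component (20 % of
the total weight, rise/decay 0.5/15 ms) with the slow rectifying component
(80 %, rise/decay 1/30 ms).  At -70 mV this composite delivers 40 % of its
total weight (0.4 nS for a 1 nS synapse), and its depolarized-to-rest peak
conductance ratio is ~2.5.

Short-term plasticity is implemented as per-pulse schedules (weight factors
for facilitating glutamatergic bursts, release-probability factors for
stochastic protocols), exactly as specified, not as a dynamic resource model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "KernelParams",
    "MgBlockParams",
    "RectificationParams",
    "SynapseComponent",
    "SynapseSpec",
    "StimTrain",
    "SynapseError",
    "kernel_conductance",
    "kernel_peak_time",
    "mg_block_factor",
    "rectification_factor",
    "gaba_peak_conductance",
    "make_linear_variant",
    "make_rectifying_only",
    "make_nam_variant",
    "make_fast_variant",
    "stp_schedule",
    "sample_release",
    "preset",
    "PRESETS",
]


class SynapseError(ValueError):
    pass


@dataclass(frozen=True)
class KernelParams:
    tau_rise: float        # ms
    tau_decay: float       # ms
    onset_delay: float = 0.0  # ms

    def __post_init__(self):
        if not 0 < self.tau_rise < self.tau_decay:
            raise SynapseError(
                f"need 0 < tau_rise < tau_decay, got {self.tau_rise}/{self.tau_decay}")


@dataclass(frozen=True)
class MgBlockParams:
    coefficient: float = 0.2801
    voltage_slope: float = 0.087   # 1/mV
    offset: float = 10.0           # mV
    mg_mM: float = 1.0

    def __post_init__(self):
        if min(self.coefficient, self.voltage_slope) <= 0 or self.mg_mM < 0:
            raise SynapseError("Mg-block parameters must be positive")


@dataclass(frozen=True)
class RectificationParams:
    v50: float                 # mV
    v_slope: float             # mV
    floor: float = 0.25
    span: float = 0.75

    def __post_init__(self):
        if self.v_slope <= 0:
            raise SynapseError("V_slope must be positive")
        if abs(self.floor + self.span - 1.0) > 1e-12:
            raise SynapseError("floor + span must equal 1")


#: default rectification of the slow dendritic (alpha5-like) component
RECT_DEFAULT = RectificationParams(v50=-52.0, v_slope=3.0)
#: whole-cell average used for mixed dendritic inhibition in the full model
RECT_FULLCELL = RectificationParams(v50=-60.0, v_slope=4.0)


@dataclass(frozen=True)
class SynapseComponent:
    fraction: float
    kernel: KernelParams
    rect: RectificationParams | None = None
    mg: MgBlockParams | None = None

    def factor(self, v_mV):
        f = 1.0
        if self.rect is not None:
            f = rectification_factor(v_mV, self.rect)
        if self.mg is not None:
            f = f * mg_block_factor(v_mV, self.mg)
        return f


GABA_KINDS = ("GABA_A_nonlinear", "GABA_A_linear", "GABA_A_PVlike", "GABA_B")
KINDS = ("AMPA", "NMDA") + GABA_KINDS


@dataclass(frozen=True)
class SynapseSpec:
    kind: str
    weight_nS: float
    reversal: float
    components: tuple[SynapseComponent, ...]
    location: object = None  # morphology.Location when placed on a tree
    stp_id: str = "none"
    p0: float = 1.0
    label: str = ""

    def __post_init__(self):
        if self.kind not in KINDS:
            raise SynapseError(f"unknown synapse kind {self.kind!r}")
        if self.weight_nS < 0:
            raise SynapseError("weight must be non-negative")
        if not 0 <= self.p0 <= 1:
            raise SynapseError("release probability outside [0, 1]")
        total = sum(c.fraction for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise SynapseError(f"component fractions sum to {total}, expected 1")

    def peak_conductance(self, v_mV: float) -> float:
        """Summed peak conductance (nS) at a fixed voltage."""
        return sum(c.fraction * self.weight_nS * c.factor(v_mV)
                   for c in self.components)


@dataclass(frozen=True)
class StimTrain:
    times_ms: tuple[float, ...]
    weight_factors: tuple[float, ...] | None = None
    p_factors: tuple[float, ...] | None = None

    def __post_init__(self):
        t = np.asarray(self.times_ms)
        if len(t) and np.any(np.diff(t) <= 0):
            raise SynapseError("pulse times must be strictly increasing")
        for fac in (self.weight_factors, self.p_factors):
            if fac is not None:
                if len(fac) != len(t):
                    raise SynapseError("per-pulse factor length mismatch")
                if np.any(np.asarray(fac) <= 0):
                    raise SynapseError("per-pulse factors must be positive")

    @staticmethod
    def burst(n: int, freq_hz: float, start_ms: float = 0.0, **kw) -> "StimTrain":
        dt = 1000.0 / freq_hz
        return StimTrain(tuple(start_ms + i * dt for i in range(n)), **kw)


# ---------------------------------------------------------------------------
# Elementary factors
# ---------------------------------------------------------------------------

def kernel_peak_time(kp: KernelParams) -> float:
    """Time of the kernel maximum after onset (closed form)."""
    tr, td = kp.tau_rise, kp.tau_decay
    return tr * td / (td - tr) * math.log(td / tr)


def kernel_norm(kp: KernelParams) -> float:
    """Value of exp(-t/tau_d) - exp(-t/tau_r) at its maximum."""
    tp = kernel_peak_time(kp)
    return math.exp(-tp / kp.tau_decay) - math.exp(-tp / kp.tau_rise)


def kernel_conductance(t_ms, kp: KernelParams, weight_nS: float = 1.0):
    """Difference-of-exponentials conductance, normalized so max == weight."""
    if weight_nS < 0:
        raise SynapseError("weight must be non-negative")
    t = np.asarray(t_ms, dtype=float) - kp.onset_delay
    g = np.where(t <= 0, 0.0,
                 (np.exp(-np.maximum(t, 0) / kp.tau_decay)
                  - np.exp(-np.maximum(t, 0) / kp.tau_rise)) / kernel_norm(kp))
    out = weight_nS * g
    return float(out) if np.isscalar(t_ms) else out


def mg_block_factor(v_mV, p: MgBlockParams = MgBlockParams()):
    """Fraction of NMDA conductance unblocked by Mg2+ at voltage v (in (0, 1])."""
    v = np.asarray(v_mV, dtype=float)
    out = 1.0 / (1.0 + p.coefficient * p.mg_mM
                 * np.exp(-p.voltage_slope * (v + p.offset)))
    return float(out) if np.isscalar(v_mV) else out


def rectification_factor(v_mV, p: RectificationParams = RECT_DEFAULT):
    """Outward-rectification factor of the slow GABA-A component, in
    [floor, 1]."""
    v = np.asarray(v_mV, dtype=float)
    out = p.floor + p.span / (1.0 + np.exp(-(v - p.v50) / p.v_slope))
    return float(out) if np.isscalar(v_mV) else out


# ---------------------------------------------------------------------------
# Composite GABA synapse and its variants
# ---------------------------------------------------------------------------

LINEAR_KERNEL = KernelParams(0.5, 15.0)
RECT_KERNEL = KernelParams(1.0, 30.0)


def make_gaba_nonlinear(weight_nS: float = 1.0, rect: RectificationParams = RECT_DEFAULT,
                        e_rev: float = -70.0, label: str = "gabaA_nonlinear",
                        **kw) -> SynapseSpec:
    """The composite dendritic GABA-A synapse: 20 % fast linear + 80 % slow
    rectifying component."""
    return SynapseSpec(
        "GABA_A_nonlinear", weight_nS, e_rev,
        (SynapseComponent(0.2, LINEAR_KERNEL),
         SynapseComponent(0.8, RECT_KERNEL, rect=rect)),
        label=label, **kw)


def gaba_peak_conductance(spec: SynapseSpec, v_mV: float) -> float:
    """Peak conductance (nS) of a GABA-A synapse at a fixed voltage."""
    if spec.kind not in GABA_KINDS:
        raise SynapseError(f"not a GABA synapse: {spec.kind}")
    return spec.peak_conductance(v_mV)


def make_linear_variant(spec: SynapseSpec) -> SynapseSpec:
    """Turn off the voltage dependence: each rectifying component is replaced
    by a linear one at its resting (floor) conductance, making the total a
    constant 40 % of the original weight for the standard 20/80 mix."""
    new = []
    total = 0.0
    for c in spec.components:
        w = c.fraction * spec.weight_nS * (c.rect.floor if c.rect else 1.0)
        new.append((w, SynapseComponent(0.0, c.kernel, rect=None, mg=c.mg)))
        total += w
    comps = tuple(replace(c, fraction=w / total) for w, c in new)
    return replace(spec, kind="GABA_A_linear", weight_nS=total, components=comps,
                   label=spec.label + "_linear")


def make_rectifying_only(spec: SynapseSpec) -> SynapseSpec:
    """Silence the linear component, keeping only rectifying components."""
    keep = [c for c in spec.components if c.rect is not None]
    if not keep:
        raise SynapseError("no rectifying component present")
    total = sum(c.fraction for c in keep) * spec.weight_nS
    comps = tuple(replace(c, fraction=c.fraction * spec.weight_nS / total) for c in keep)
    return replace(spec, weight_nS=total, components=comps,
                   label=spec.label + "_rectonly")


def make_nam_variant(spec: SynapseSpec, block: float = 0.5) -> SynapseSpec:
    """Negative allosteric modulation of the alpha5 component: the rectifying
    weight is reduced by ``block`` (default 50 %), the linear part untouched."""
    ws = [c.fraction * spec.weight_nS * (1.0 - block if c.rect is not None else 1.0)
          for c in spec.components]
    total = sum(ws)
    comps = tuple(replace(c, fraction=w / total) for c, w in zip(spec.components, ws))
    return replace(spec, weight_nS=total, components=comps,
                   label=spec.label + "_nam")


def make_fast_variant(spec: SynapseSpec, speed_factor: float,
                      mode: str = "amplitude_scaled") -> SynapseSpec:
    """PV-basket-cell-like rescaling of a slow GABA synapse.

    All components adopt the slow (rectifying) kernel sped up by
    ``speed_factor`` (1/30 ms -> 0.2/6 ms at factor 5).  ``amplitude_scaled``
    multiplies the total weight by the same factor; ``charge_preserving``
    multiplies each component weight by old-decay/new-decay so the conductance
    time integral at fixed voltage is unchanged (1 nS -> 4.5 nS at factor 5).
    """
    if speed_factor <= 0:
        raise SynapseError("speed factor must be positive")
    if mode not in ("amplitude_scaled", "charge_preserving"):
        raise SynapseError(f"unknown mode {mode!r}")
    if speed_factor == 1.0:
        return spec
    base = next((c.kernel for c in spec.components if c.rect is not None),
                spec.components[-1].kernel)
    fast = KernelParams(base.tau_rise / speed_factor, base.tau_decay / speed_factor,
                        base.onset_delay)
    if mode == "amplitude_scaled":
        ws = [c.fraction * spec.weight_nS * speed_factor for c in spec.components]
    else:
        ws = [c.fraction * spec.weight_nS * (c.kernel.tau_decay / fast.tau_decay)
              for c in spec.components]
    total = sum(ws)
    comps = tuple(replace(c, fraction=w / total, kernel=fast)
                  for c, w in zip(spec.components, ws))
    return replace(spec, kind="GABA_A_PVlike", weight_nS=total, components=comps,
                   label=spec.label + f"_fast{mode[0]}")


# ---------------------------------------------------------------------------
# Short-term plasticity schedules and release sampling
# ---------------------------------------------------------------------------

_STP = {
    # measured facilitation of Schaffer-collateral EPSCs during 5@50 Hz
    "glut_5at50": ("weight", (1.0, 1.5, 1.8, 1.9, 2.0)),
    # rounded schedule used for the single-branch burst simulations
    "glut_branch": ("weight", (1.0, 1.5, 2.0, 2.0, 2.0)),
    # release-probability facilitation during 3@200 Hz tuft bursts
    "glut_3at200": ("probability", (1.0, 1.5, 1.8)),
    # measured depression of mixed GABAergic inputs during 5@50 Hz
    "gaba_SR": ("probability", (1.0, 0.7, 0.7, 0.7, 0.7)),
    "gaba_SLM": ("probability", (1.0, 0.6, 0.5, 0.4, 0.4)),
}


def stp_schedule(schedule_id: str, n_pulses: int | None = None) -> tuple[float, ...]:
    """Per-pulse scaling factors for the named short-term-plasticity schedule."""
    if schedule_id == "none":
        return tuple([1.0] * (n_pulses if n_pulses else 1))
    if schedule_id not in _STP:
        raise SynapseError(f"unknown STP schedule {schedule_id!r}")
    factors = _STP[schedule_id][1]
    if n_pulses is not None:
        if n_pulses > len(factors):
            factors = factors + (factors[-1],) * (n_pulses - len(factors))
        factors = factors[:n_pulses]
    return factors


def stp_mode(schedule_id: str) -> str:
    return _STP.get(schedule_id, ("weight",))[0] if schedule_id != "none" else "weight"


def sample_release(n_synapses: int, p_schedule, mode: str = "bernoulli",
                   seed: int = 0) -> np.ndarray:
    """Boolean activation matrix (synapse x pulse).

    ``bernoulli`` draws independently per synapse and pulse; ``expected_count``
    activates exactly round(n*p) synapses per pulse via a seeded shuffle.
    Probabilities are clipped to [0, 1].
    """
    p = np.clip(np.atleast_1d(np.asarray(p_schedule, dtype=float)), 0.0, 1.0)
    rng = np.random.default_rng(seed)
    if mode == "bernoulli":
        return rng.random((n_synapses, len(p))) < p[None, :]
    if mode == "expected_count":
        out = np.zeros((n_synapses, len(p)), dtype=bool)
        for j, pj in enumerate(p):
            k = int(round(n_synapses * pj))
            idx = rng.permutation(n_synapses)[:k]
            out[idx, j] = True
        return out
    raise SynapseError(f"unknown release mode {mode!r}")


# ---------------------------------------------------------------------------
# Named presets
# ---------------------------------------------------------------------------

def _ampa(decay):
    def build(weight=0.14, e_rev=0.0):
        return SynapseSpec("AMPA", weight, e_rev,
                           (SynapseComponent(1.0, KernelParams(0.2, decay)),),
                           label="ampa")
    return build


def _nmda(weight=0.14, e_rev=0.0):
    return SynapseSpec("NMDA", weight, e_rev,
                       (SynapseComponent(1.0, KernelParams(3.0, 35.0),
                                         mg=MgBlockParams()),),
                       label="nmda")


def _gabab(weight=0.4, e_rev=-95.0):
    return SynapseSpec("GABA_B", weight, e_rev,
                       (SynapseComponent(1.0, KernelParams(50.0, 200.0)),),
                       label="gabab")


PRESETS = {
    "ampa_branch": _ampa(2.0),
    "ampa_fullcell": _ampa(3.0),
    "nmda": _nmda,
    # unitary dendritic synapse of the tuft-burst model (1 nS -> 0.4 nS at rest)
    "gabaA_nonlinear_unit": lambda weight=1.0: make_gaba_nonlinear(weight),
    # SOM-like synapse of the single-branch model (0.7 nS -> 0.28 nS at rest)
    "gabaA_nonlinear_branch": lambda weight=0.7: make_gaba_nonlinear(weight),
    # whole-tree mixed inhibition of the full-cell model (V50 -60, slope 4)
    "gabaA_nonlinear_fullcell": lambda weight=0.7: make_gaba_nonlinear(
        weight, rect=RECT_FULLCELL),
    "gabaA_linear": lambda weight=1.0: make_linear_variant(make_gaba_nonlinear(weight)),
    "gabaA_rectifying_only": lambda weight=1.0: make_rectifying_only(
        make_gaba_nonlinear(weight)),
    "gabaA_nam": lambda weight=0.7: make_nam_variant(make_gaba_nonlinear(weight)),
    "gabaA_pvlike": lambda weight=1.0: make_fast_variant(
        make_gaba_nonlinear(weight), 5.0, "charge_preserving"),
    "gabab": _gabab,
}


def preset(name: str, **kw) -> SynapseSpec:
    if name not in PRESETS:
        raise SynapseError(f"unknown synapse preset {name!r}")
    return PRESETS[name](**kw)
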