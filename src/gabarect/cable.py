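"""Compartmental cable-equation solver.

A morphology is discretized into cylindrical compartments (an odd number per
section, so the section midpoint x = 0.5 always falls on a compartment
center).  The coupled compartment system is integrated implicitly: the linear
tree system (capacitive, axial, and all membrane conductances evaluated for
the step) is solved exactly per time step with a Hines-ordered O(N)
elimination; gating variables advance by an implicit exponential-Euler update,
and the voltage-dependent synaptic factors (Mg block, outward rectification)
are evaluated at the previous step's voltage, which keeps the per-step solve
linear.  Backward Euler is the default; a Crank–Nicolson option solves the
half-step system and extrapolates.

Voltage clamp is ideal (no series resistance) and implemented as a stiff
penalty conductance at the clamped node; the clamp current is recovered
exactly from the penalty residual.

Internal unit system: mV, ms, nS, pF, pA (nS*mV = pA and pF*mV/ms = pA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import biophysics as bp
from .morphology import Location, Morphology, path_distance
from .synapses import SynapseSpec, kernel_norm

try:  # the compiled kernel is optional but installed in practice
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]

__all__ = [
    "SegmentGrid",
    "SimConfig",
    "SynapticInput",
    "Trace",
    "SolverError",
    "assemble",
    "single_compartment_grid",
    "simulate",
    "voltage_clamp",
]


class SolverError(RuntimeError):
    pass


@dataclass
class Trace:
    """Uniformly sampled time series."""

    label: str
    dt: float
    t0: float
    values: np.ndarray

    def time(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.values))

    def __len__(self):
        return len(self.values)


@dataclass(frozen=True)
class SimConfig:
    dt: float = 0.025            # ms
    t_stop: float = 200.0        # ms
    v_init: float = -70.0        # mV
    scheme: str = "backward_euler"   # or "crank_nicolson"
    settle: float = 500.0        # ms of stimulus-free settling before t = 0
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0 or self.settle < 0 or self.t_stop <= 0:
            raise SolverError("dt and t_stop must be positive, settle non-negative")
        if self.scheme not in ("backward_euler", "crank_nicolson"):
            raise SolverError(f"unknown scheme {self.scheme!r}")


@dataclass
class SynapticInput:
    """A synapse placed on the grid with its activation events.

    ``events`` is a list of (time_ms, weight_factor); each event injects the
    synapse's kernel scaled by factor (short-term plasticity enters here).
    """

    spec: SynapseSpec
    location: Location
    events: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class SegmentGrid:
    """Discretized morphology with per-compartment membrane machinery."""

    parent: np.ndarray        # (n,) int64; -1 for root
    g_axial: np.ndarray       # (n,) nS coupling to parent
    cap: np.ndarray           # (n,) pF
    area_cm2: np.ndarray      # (n,)
    dist_um: np.ndarray       # (n,) path distance of compartment centers
    section_id: np.ndarray    # (n,) int64
    x: np.ndarray             # (n,) center position on the section
    channels: list            # list of (ChannelSpec, gbar_nS array)
    morph: Morphology | None = None

    @property
    def n(self) -> int:
        return len(self.parent)

    def locate(self, loc: Location) -> int:
        """Index of the compartment whose center is closest to ``loc``."""
        mask = self.section_id == loc.section_id
        if not mask.any():
            raise SolverError(f"location on unknown section {loc.section_id}")
        idx = np.where(mask)[0]
        return int(idx[np.argmin(np.abs(self.x[idx] - loc.x))])

    def total_area_cm2(self) -> float:
        return float(self.area_cm2.sum())


def _default_nseg(length_um: float, max_um: float = 20.0) -> int:
    n = max(1, math.ceil(length_um / max_um))
    return n if n % 2 == 1 else n + 1


def assemble(morph: Morphology, channels: list[bp.ChannelSpec],
             passive: bp.PassiveConstants | None = None,
             nseg_max_um: float = 20.0) -> SegmentGrid:
    """Discretize a morphology and evaluate channel densities per compartment.

    The delayed-rectifier deletion rule is applied here: KDR conductance is
    zeroed on every dendritic compartment whose center lies more than 100 um
    from the soma.
    """
    if not morph.sections:
        raise SolverError("empty morphology")
    p = passive or bp.PassiveConstants()

    parent, g_ax, cap, area, dist, sec_id, xs = [], [], [], [], [], [], []
    first_comp: dict[int, tuple[int, int, float]] = {}  # sec -> (first idx, nseg, l_um)
    types: list[str] = []

    def r_half(l_um, diam_um):
        # ohms from compartment center to its end
        r_cm = diam_um / 2 * 1e-4
        return p.r_i * (l_um / 2 * 1e-4) / (math.pi * r_cm ** 2)

    def visit(sec, parent_attach_idx=None, r_attach=0.0):
        n = sec.nseg or _default_nseg(sec.length_um, nseg_max_um)
        l = sec.length_um / n
        base_dist = (path_distance(morph, Location(sec.id, 0.0))
                     if sec.parent_id is not None else 0.0)
        first = len(parent)
        for j in range(n):
            if j == 0:
                if parent_attach_idx is None:
                    parent.append(-1)
                    g_ax.append(0.0)
                else:
                    parent.append(parent_attach_idx)
                    g_ax.append(1e9 / (r_half(l, sec.diam_um) + r_attach))
            else:
                parent.append(len(parent) - 1)
                g_ax.append(1e9 / (2 * r_half(l, sec.diam_um)))
            a_um2 = math.pi * sec.diam_um * l
            area.append(a_um2 * 1e-8)
            cap.append(a_um2 * 1e-8 * p.c_m * 1e6)  # cm^2 * uF/cm^2 -> pF
            center = (j + 0.5) / n
            dist.append(0.0 if sec.parent_id is None
                        else base_dist + center * sec.length_um)
            sec_id.append(sec.id)
            xs.append(center)
            types.append(sec.type_label)
        first_comp[sec.id] = (first, n, l)
        for ch in morph.children(sec.id):
            fi, np_, lp = first_comp[sec.id]
            jp = min(int(ch.attach * np_), np_ - 1)
            center_um = (jp + 0.5) * lp
            offset = abs(ch.attach * sec.length_um - center_um)
            r_off = p.r_i * (offset * 1e-4) / (math.pi * (sec.diam_um / 2 * 1e-4) ** 2)
            visit(ch, fi + jp, r_off)

    visit(morph.root)
    parent = np.asarray(parent, dtype=np.int64)
    dist = np.asarray(dist)
    types = np.asarray(types)

    chan_list = []
    for spec in channels:
        g = bp.density_at(spec.rule, dist) * np.asarray(area) * 1e9  # S -> nS
        if spec.rule.region:
            g = np.where(np.isin(types, list(spec.rule.region)), g, 0.0)
        if spec.kind == "KDR":
            g = np.where((types != "soma") & (dist > 100.0), 0.0, g)
        chan_list.append((spec, np.ascontiguousarray(g)))

    return SegmentGrid(parent, np.asarray(g_ax, dtype=float),
                       np.asarray(cap), np.asarray(area), dist,
                       np.asarray(sec_id, dtype=np.int64), np.asarray(xs),
                       chan_list, morph)


def single_compartment_grid(area_um2: float, channels: list[bp.ChannelSpec],
                            passive: bp.PassiveConstants | None = None) -> SegmentGrid:
    """An isopotential patch of the given membrane area (no morphology)."""
    p = passive or bp.PassiveConstants()
    area_cm2 = area_um2 * 1e-8
    chan_list = [(spec, np.array([bp.density_at(spec.rule, 0.0) * area_cm2 * 1e9]))
                 for spec in channels]
    return SegmentGrid(np.array([-1], dtype=np.int64), np.zeros(1),
                       np.array([area_cm2 * p.c_m * 1e6]), np.array([area_cm2]),
                       np.zeros(1), np.zeros(1, dtype=np.int64), np.full(1, 0.5),
                       chan_list, None)


# ---------------------------------------------------------------------------
# Compiled time-stepping kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _integrate(n_steps, dt, cn, v, parent, g_ax, static_diag, cap,
               ch_mode, ch_E, ch_gbar, ch_gate, ch_gate2_on, ch_gate2, ch_rect,
               gate_state, gate2_state,
               sc_comp, sc_dr, sc_dd, sc_norm, sc_E, sc_vmode, sc_par,
               ev_step, ev_sc, ev_amt,
               inj_comp, inj_amp, inj_on, inj_off,
               clamp_comp, clamp_wave, gpen,
               rec_comp, rec_start, rec_v, rec_clamp, rec_gsyn):
    n = v.shape[0]
    nch = ch_mode.shape[0]
    nsc = sc_comp.shape[0]
    A = np.zeros(nsc)
    B = np.zeros(nsc)
    d = np.empty(n)
    r = np.empty(n)
    ev_ptr = 0
    dt_solve = dt * 0.5 if cn == 1 else dt

    for s in range(n_steps):
        # synaptic state decay and event application
        for k in range(nsc):
            A[k] *= sc_dr[k]
            B[k] *= sc_dd[k]
        while ev_ptr < ev_step.shape[0] and ev_step[ev_ptr] == s:
            k = ev_sc[ev_ptr]
            A[k] += ev_amt[ev_ptr]
            B[k] += ev_amt[ev_ptr]
            ev_ptr += 1

        for i in range(n):
            d[i] = cap[i] / dt_solve + static_diag[i]
            r[i] = cap[i] / dt_solve * v[i]

        # membrane channels
        for c in range(nch):
            mode = ch_mode[c]
            if mode == 0:  # leak
                for i in range(n):
                    g = ch_gbar[c, i]
                    if g > 0.0:
                        d[i] += g
                        r[i] += g * ch_E[c]
            elif mode == 1:  # gated
                vh = ch_gate[c, 0]; kk = ch_gate[c, 1]
                tb = ch_gate[c, 2]; ta = ch_gate[c, 3]
                tvh = ch_gate[c, 4]; tw = ch_gate[c, 5]
                pw = ch_gate[c, 6]
                for i in range(n):
                    gb = ch_gbar[c, i]
                    if gb <= 0.0:
                        continue
                    tau = tb + ta / math.cosh((v[i] - tvh) / tw)
                    inf = 1.0 / (1.0 + math.exp((vh - v[i]) / kk))
                    m = (gate_state[c, i] + dt * inf / tau) / (1.0 + dt / tau)
                    gate_state[c, i] = m
                    g = gb * m ** pw
                    if ch_gate2_on[c] == 1:
                        tau2 = ch_gate2[c, 2] + ch_gate2[c, 3] / math.cosh(
                            (v[i] - ch_gate2[c, 4]) / ch_gate2[c, 5])
                        inf2 = 1.0 / (1.0 + math.exp((ch_gate2[c, 0] - v[i]) / ch_gate2[c, 1]))
                        h = (gate2_state[c, i] + dt * inf2 / tau2) / (1.0 + dt / tau2)
                        gate2_state[c, i] = h
                        g *= h
                    d[i] += g
                    r[i] += g * ch_E[c]
            else:  # tonic outward-rectifying conductance
                fl = ch_rect[c, 0]; sp = ch_rect[c, 1]
                v50 = ch_rect[c, 2]; vs = ch_rect[c, 3]
                for i in range(n):
                    gb = ch_gbar[c, i]
                    if gb <= 0.0:
                        continue
                    g = gb * (fl + sp / (1.0 + math.exp(-(v[i] - v50) / vs)))
                    d[i] += g
                    r[i] += g * ch_E[c]

        # synapses (voltage factors lagged one step)
        for k in range(nsc):
            g = (B[k] - A[k]) / sc_norm[k]
            if g <= 0.0:
                rec_gsyn[k] = 0.0
                continue
            i = sc_comp[k]
            vm = sc_vmode[k]
            if vm == 1:
                g *= sc_par[k, 0] + sc_par[k, 1] / (
                    1.0 + math.exp(-(v[i] - sc_par[k, 2]) / sc_par[k, 3]))
            elif vm == 2:
                g *= 1.0 / (1.0 + sc_par[k, 0]
                            * math.exp(-sc_par[k, 1] * (v[i] + sc_par[k, 2])))
            rec_gsyn[k] = g
            d[i] += g
            r[i] += g * sc_E[k]

        # current injections
        for q in range(inj_comp.shape[0]):
            if inj_on[q] <= s < inj_off[q]:
                r[inj_comp[q]] += inj_amp[q]

        # voltage clamp via penalty
        if clamp_comp >= 0:
            d[clamp_comp] += gpen
            r[clamp_comp] += gpen * clamp_wave[s]

        # Hines elimination (children stored after parents)
        for i in range(n - 1, 0, -1):
            f = g_ax[i] / d[i]
            pidx = parent[i]
            d[pidx] -= f * g_ax[i]
            r[pidx] += f * r[i]
        # forward substitution; solved values overwrite r
        r[0] = r[0] / d[0]
        for i in range(1, n):
            r[i] = (r[i] + g_ax[i] * r[parent[i]]) / d[i]

        iclamp = 0.0
        if clamp_comp >= 0:
            iclamp = gpen * (clamp_wave[s] - r[clamp_comp])

        if cn == 1:
            for i in range(n):
                v[i] = 2.0 * r[i] - v[i]
        else:
            for i in range(n):
                v[i] = r[i]

        if s >= rec_start:
            j = s - rec_start
            for q in range(rec_comp.shape[0]):
                rec_v[q, j] = v[rec_comp[q]]
            if rec_clamp.shape[0] > 0:
                rec_clamp[j] = iclamp

        # divergence guard (cheap check on the root)
        if not np.isfinite(v[0]):
            return s
    return -1


# ---------------------------------------------------------------------------
# Python-level drivers
# ---------------------------------------------------------------------------

def _pack_channels(grid: SegmentGrid, v_init: float):
    nch = len(grid.channels)
    n = grid.n
    ch_mode = np.zeros(nch, dtype=np.int64)
    ch_E = np.zeros(nch)
    ch_gbar = np.zeros((nch, n))
    ch_gate = np.zeros((nch, 7))
    ch_gate2_on = np.zeros(nch, dtype=np.int64)
    ch_gate2 = np.ones((nch, 6))
    ch_rect = np.zeros((nch, 4))
    gate_state = np.zeros((nch, n))
    gate2_state = np.zeros((nch, n))
    for c, (spec, gbar) in enumerate(grid.channels):
        ch_E[c] = spec.reversal
        ch_gbar[c] = gbar
        if spec.kind == "leak":
            ch_mode[c] = 0
        elif spec.kind == "tonicGABA":
            ch_mode[c] = 2
            ch_rect[c] = (spec.rect.floor, spec.rect.span, spec.rect.v50,
                          spec.rect.v_slope)
        else:
            ch_mode[c] = 1
            g = spec.gate
            ch_gate[c] = (g.v_half, g.k, g.tau_base, g.tau_amp, g.tau_vhalf,
                          g.tau_width, float(g.power))
            gate_state[c] = float(g.inf(v_init))
            if spec.gate2 is not None:
                ch_gate2_on[c] = 1
                g2 = spec.gate2
                ch_gate2[c] = (g2.v_half, g2.k, g2.tau_base, g2.tau_amp,
                               g2.tau_vhalf, g2.tau_width)
                gate2_state[c] = float(g2.inf(v_init))
    return (ch_mode, ch_E, ch_gbar, ch_gate, ch_gate2_on, ch_gate2, ch_rect,
            gate_state, gate2_state)


def _pack_synapses(grid: SegmentGrid, inputs: list[SynapticInput],
                   dt: float, settle_steps: int):
    comp, dr, dd, norm, E, vmode, par = [], [], [], [], [], [], []
    ev = []  # (step, component index, amount)
    for inp in inputs:
        ci = grid.locate(inp.location)
        for c in inp.spec.components:
            k = len(comp)
            comp.append(ci)
            dr.append(math.exp(-dt / c.kernel.tau_rise))
            dd.append(math.exp(-dt / c.kernel.tau_decay))
            norm.append(kernel_norm(c.kernel))
            E.append(inp.spec.reversal)
            if c.rect is not None:
                vmode.append(1)
                par.append((c.rect.floor, c.rect.span, c.rect.v50, c.rect.v_slope))
            elif c.mg is not None:
                vmode.append(2)
                par.append((c.mg.coefficient * c.mg.mg_mM, c.mg.voltage_slope,
                            c.mg.offset, 0.0))
            else:
                vmode.append(0)
                par.append((0.0, 0.0, 0.0, 1.0))
            w = c.fraction * inp.spec.weight_nS
            for t_ev, factor in inp.events:
                step = settle_steps + int(round((t_ev + c.kernel.onset_delay) / dt))
                ev.append((step, k, w * factor))
    ev.sort()
    if comp:
        arrs = (np.asarray(comp, dtype=np.int64), np.asarray(dr), np.asarray(dd),
                np.asarray(norm), np.asarray(E), np.asarray(vmode, dtype=np.int64),
                np.asarray(par))
    else:
        arrs = (np.zeros(0, dtype=np.int64), np.zeros(0), np.zeros(0),
                np.ones(0), np.zeros(0), np.zeros(0, dtype=np.int64),
                np.zeros((0, 4)))
    if ev:
        ev_step = np.asarray([e[0] for e in ev], dtype=np.int64)
        ev_sc = np.asarray([e[1] for e in ev], dtype=np.int64)
        ev_amt = np.asarray([e[2] for e in ev])
    else:
        ev_step = np.zeros(0, dtype=np.int64)
        ev_sc = np.zeros(0, dtype=np.int64)
        ev_amt = np.zeros(0)
    return arrs, (ev_step, ev_sc, ev_amt)


def simulate(grid: SegmentGrid, inputs: list[SynapticInput] | None = None,
             config: SimConfig | None = None,
             record: list[Location] | None = None,
             injections: list[tuple[Location, float, float, float]] | None = None,
             clamp: tuple[Location, np.ndarray | float] | None = None,
             v_init_map: np.ndarray | None = None) -> dict[str, Trace]:
    """Integrate the compartment system.

    ``record`` lists voltage recording sites (defaults to the root).
    ``injections`` are (location, amplitude_pA, t_on_ms, t_off_ms) steps.
    ``clamp`` pins one location to a command: a constant (mV) or an array
    sampled at ``dt`` over [0, t_stop); during settle the first value holds.
    Returns traces keyed ``"v0", "v1", ...`` in record order, plus
    ``"i_clamp"`` (pA) when clamped.  Bit-reproducible for fixed inputs.
    """
    cfg = config or SimConfig()
    inputs = inputs or []
    record = record or [Location(int(grid.section_id[0]), 0.5)]
    settle_steps = int(round(cfg.settle / cfg.dt))
    n_steps = settle_steps + int(round(cfg.t_stop / cfg.dt))

    v = np.full(grid.n, cfg.v_init, dtype=float)
    if v_init_map is not None:
        v[:] = v_init_map

    static_diag = np.zeros(grid.n)
    for i in range(1, grid.n):
        static_diag[i] += grid.g_axial[i]
        static_diag[grid.parent[i]] += grid.g_axial[i]

    chans = _pack_channels(grid, cfg.v_init)
    syn_arrs, ev_arrs = _pack_synapses(grid, inputs, cfg.dt, settle_steps)

    if injections:
        inj_comp = np.asarray([grid.locate(l) for l, *_ in injections], dtype=np.int64)
        inj_amp = np.asarray([a for _, a, *_ in injections])
        inj_on = np.asarray([settle_steps + int(round(t / cfg.dt))
                             for *_x, t, _ in injections], dtype=np.int64)
        inj_off = np.asarray([settle_steps + int(round(t / cfg.dt))
                              for *_x, t in injections], dtype=np.int64)
    else:
        inj_comp = np.zeros(0, dtype=np.int64)
        inj_amp = np.zeros(0)
        inj_on = np.zeros(0, dtype=np.int64)
        inj_off = np.zeros(0, dtype=np.int64)

    if clamp is not None:
        loc, cmd = clamp
        clamp_comp = grid.locate(loc)
        wave = np.empty(n_steps)
        if np.isscalar(cmd):
            wave[:] = cmd
        else:
            cmd = np.asarray(cmd, dtype=float)
            if len(cmd) < n_steps - settle_steps:
                raise SolverError("clamp command shorter than t_stop")
            wave[:settle_steps] = cmd[0]
            wave[settle_steps:] = cmd[:n_steps - settle_steps]
        rec_clamp = np.zeros(n_steps - settle_steps)
    else:
        clamp_comp = -1
        wave = np.zeros(1)
        rec_clamp = np.zeros(0)

    rec_comp = np.asarray([grid.locate(l) for l in record], dtype=np.int64)
    rec_v = np.zeros((len(rec_comp), n_steps - settle_steps))
    rec_gsyn = np.zeros(max(1, len(syn_arrs[0])))

    bad = _integrate(n_steps, cfg.dt, 1 if cfg.scheme == "crank_nicolson" else 0,
                     v, grid.parent, grid.g_axial, static_diag, grid.cap,
                     *chans, *syn_arrs, *ev_arrs,
                     inj_comp, inj_amp, inj_on, inj_off,
                     clamp_comp, wave, 1e9,
                     rec_comp, settle_steps, rec_v, rec_clamp, rec_gsyn)
    if bad >= 0:
        t_bad = (bad - settle_steps) * cfg.dt
        where = np.where(~np.isfinite(v))[0]
        comp = int(where[0]) if len(where) else 0
        raise SolverError(
            f"solver divergence: non-finite voltage in compartment {comp} "
            f"(section {int(grid.section_id[comp])}) near t = {t_bad:.3f} ms")

    out = {f"v{q}": Trace(f"v{q}", cfg.dt, cfg.dt, rec_v[q])
           for q in range(len(rec_comp))}
    if clamp is not None:
        out["i_clamp"] = Trace("i_clamp", cfg.dt, cfg.dt, rec_clamp)
    return out


def voltage_clamp(grid: SegmentGrid, command, clamp_loc: Location,
                  inputs: list[SynapticInput] | None = None,
                  config: SimConfig | None = None) -> Trace:
    """Ideal voltage clamp; returns the clamp-current trace (pA)."""
    cfg = config or SimConfig()
    hold = command if np.isscalar(command) else float(np.asarray(command)[0])
    cfg = SimConfig(cfg.dt, cfg.t_stop, hold, cfg.scheme, cfg.settle, cfg.seed)
    res = simulate(grid, inputs, cfg, record=[clamp_loc], clamp=(clamp_loc, command))
    return res["i_clamp"]
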