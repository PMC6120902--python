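"""Quantification of simulated or recorded postsynaptic currents and potentials.

Implements the standard IPSC statistics used for dendritic inhibition:

* a sigmoidal conductance fit to current–voltage data,
  ``I(v) = (v - E_rev) * (g_min + (g_max - g_min) / (1 + exp((V50 - v)/Slope)))``,
  with the slope constrained from below by the holding-level spacing;
* the rectification index (RI): the conductance of a straight-line fit to the
  outward currents above -40 mV divided by the conductance near rest
  (-82 mV); RI = 1 means a linear synapse;
* biexponential kinetics: the decay tau is the amplitude-weighted average of a
  two-exponential fit restricted to the decay phase starting where the
  current has fallen to 95 % of its peak;
* burst metrics: the response window is bounded by the baseline crossings of
  a third-order 100-Hz low-pass Butterworth-filtered copy of the trace, and
  the integral/peak are measured on the raw trace inside that window.
  Action potentials can be removed by clipping the trace at the voltage
  reached when dV/dt first exceeds 10 V/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .cable import Trace

__all__ = [
    "IVCurve",
    "SigmoidFit",
    "BiexpFitResult",
    "BurstMetrics",
    "AnalysisError",
    "fit_sigmoid_iv",
    "rectification_index",
    "fit_biexp",
    "burst_metrics",
    "normalized_conductance",
]


class AnalysisError(ValueError):
    pass


@dataclass
class IVCurve:
    """Peak and tail current amplitudes across holding potentials."""

    v_hold: np.ndarray       # mV
    i_peak: np.ndarray       # pA
    i_tail: np.ndarray | None = None  # pA at tail_time after stimulus onset
    tail_time_ms: float = 30.0
    e_rev: float | None = None        # estimated reversal potential, mV

    def __post_init__(self):
        self.v_hold = np.asarray(self.v_hold, dtype=float)
        self.i_peak = np.asarray(self.i_peak, dtype=float)
        if len(np.unique(self.v_hold)) != len(self.v_hold):
            raise AnalysisError("duplicate holding levels")
        if self.i_tail is not None:
            self.i_tail = np.asarray(self.i_tail, dtype=float)

    def estimate_reversal(self) -> float:
        """Linear-interpolated zero crossing of the peak-current relation."""
        order = np.argsort(self.v_hold)
        v, i = self.v_hold[order], self.i_peak[order]
        sign = np.sign(i)
        idx = np.where(np.diff(sign) != 0)[0]
        if len(idx) == 0:
            raise AnalysisError("no zero crossing in IV data")
        k = idx[0]
        return float(v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k]))


@dataclass
class SigmoidFit:
    e_rev: float
    g_min: float
    g_max: float
    v50: float
    slope: float
    residual_norm: float
    slope_at_bound: bool = False

    def conductance(self, v):
        v = np.asarray(v, dtype=float)
        return self.g_min + (self.g_max - self.g_min) / (
            1.0 + np.exp((self.v50 - v) / self.slope))

    def current(self, v):
        v = np.asarray(v, dtype=float)
        return (v - self.e_rev) * self.conductance(v)


@dataclass
class BiexpFitResult:
    amplitude: float
    tau_rise: float | None
    a1: float
    tau1: float
    a2: float
    tau2: float
    window_start_fraction: float

    @property
    def weighted_tau(self) -> float:
        return (self.a1 * self.tau1 + self.a2 * self.tau2) / (self.a1 + self.a2)


@dataclass
class BurstMetrics:
    peak_amplitude: float
    integral: float          # value*ms between the detected bounds
    t_start: float | None
    t_end: float | None
    open_ended: bool = False


# ---------------------------------------------------------------------------

def fit_sigmoid_iv(iv: IVCurve, normalize_at: float | None = None) -> SigmoidFit:
    """Least-squares fit of the sigmoidal voltage-dependent conductance.

    ``normalize_at`` divides all currents by the value at that holding level
    before fitting (the conventional -70 mV normalization).  Trust-region
    least squares with multiple V50 starts avoids local minima; the Slope
    parameter is bounded below by the holding-level spacing.
    """
    v = np.asarray(iv.v_hold, dtype=float)
    i = np.asarray(iv.i_peak, dtype=float)
    if len(v) < 5:
        raise AnalysisError("need at least 5 holding levels")
    if v.min() > -50.0 or v.max() < -50.0:
        raise AnalysisError("holding levels must span both sides of -50 mV")
    if normalize_at is not None:
        k = int(np.argmin(np.abs(v - normalize_at)))
        ref = i[k]
        if ref == 0:
            raise AnalysisError("zero current at the normalization level")
        i = i / abs(ref)
    min_slope = float(np.min(np.diff(np.sort(v))))
    scale = max(np.abs(i).max(), 1e-12)
    e0 = iv.e_rev if iv.e_rev is not None else -70.0

    def resid(p):
        e, gmin, gmax, v50, sl = p
        return (v - e) * (gmin + (gmax - gmin) / (1 + np.exp((v50 - v) / sl))) - i

    best = None
    for v50_0 in (-70.0, -50.0, -30.0):
        p0 = [e0, 0.25 * scale / 100, scale / 100, v50_0, max(3.0, min_slope)]
        try:
            sol = optimize.least_squares(
                resid, p0,
                bounds=([-120, 0, 0, -120, min_slope],
                        [40, np.inf, np.inf, 40, 60.0]))
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise AnalysisError("sigmoid fit failed from all starts")
    e, gmin, gmax, v50, sl = best.x
    if gmax < gmin:  # degenerate flat fits may land either way
        gmin, gmax = gmax, gmin
    return SigmoidFit(float(e), float(gmin), float(gmax), float(v50), float(sl),
                      float(np.linalg.norm(best.fun)),
                      slope_at_bound=bool(abs(sl - min_slope) < 1e-9))


def rectification_index(iv: IVCurve, rest_mV: float = -82.0,
                        outward_above_mV: float = -40.0,
                        interpolate_with_fit: bool = False) -> float:
    """Ratio of the linear outward-fit conductance to the conductance at rest.

    The rest conductance uses the measured hold when one lies within 1 mV of
    ``rest_mV``; otherwise (or when ``interpolate_with_fit``) it is
    interpolated by the sigmoid fit.  The outward line is an unconstrained
    two-parameter fit to I vs V above ``outward_above_mV``.
    """
    v = np.asarray(iv.v_hold, dtype=float)
    i = np.asarray(iv.i_peak, dtype=float)
    mask = v > outward_above_mV
    if mask.sum() < 2:
        raise AnalysisError(f"need >= 2 holds above {outward_above_mV} mV")
    slope = float(np.polyfit(v[mask], i[mask], 1)[0])  # nS if pA/mV

    nearest = int(np.argmin(np.abs(v - rest_mV)))
    if not interpolate_with_fit and abs(v[nearest] - rest_mV) <= 1.0:
        e = iv.e_rev if iv.e_rev is not None else iv.estimate_reversal()
        if abs(v[nearest] - e) < 1e-9:
            raise AnalysisError("rest hold coincides with the reversal potential")
        g_rest = i[nearest] / (v[nearest] - e)
    else:
        fit = fit_sigmoid_iv(iv)
        g_rest = float(fit.conductance(rest_mV))
    if g_rest == 0:
        raise AnalysisError("zero conductance at rest")
    return slope / g_rest


# ---------------------------------------------------------------------------

def _single_psc_window(t, y):
    """Peak index of the dominant deflection from the initial baseline."""
    base = y[0]
    dev = y - base
    k = int(np.argmax(np.abs(dev)))
    if k == 0 or k == len(y) - 1:
        raise AnalysisError("peak at trace edge; not a complete PSC")
    return k, base, dev


def fit_biexp(trace: Trace, window_start_fraction: float = 0.95) -> BiexpFitResult:
    """Biexponential decay fit of a single PSC, weighted decay tau.

    The decay window begins where the decaying limb first falls to
    ``window_start_fraction`` of the peak amplitude.  A rise time constant is
    additionally estimated from a difference-of-exponentials fit over the
    whole waveform.
    """
    t = trace.time()
    y = np.asarray(trace.values, dtype=float)
    k, base, dev = _single_psc_window(t, y)
    amp = dev[k]
    sgn = np.sign(amp)
    z = sgn * dev  # positive-going PSC
    peak = z[k]
    after = np.where(z[k:] <= window_start_fraction * peak)[0]
    if len(after) == 0:
        raise AnalysisError("decay never falls below the fit-window threshold")
    k0 = k + after[0]
    td = t[k0:] - t[k0]
    zd = z[k0:]

    # a free baseline offset absorbs residual noise bias, and each tau is
    # bounded by the window span — slower components are unresolvable and
    # would otherwise inflate the weighted tau on noisy traces
    def dec(p):
        a1, tau1, a2, tau2, c = p
        return a1 * np.exp(-td / tau1) + a2 * np.exp(-td / tau2) + c - zd

    z0 = zd[0]
    span = max(td[-1], 1.0)
    guess_tau = max(td[np.searchsorted(-zd, -z0 / math.e)] if zd[-1] < z0 / math.e
                    else span / 2, trace.dt)
    sol = optimize.least_squares(
        dec, [0.7 * z0, guess_tau, 0.3 * z0, min(guess_tau * 4, span), 0.0],
        bounds=([0, trace.dt / 10, 0, trace.dt / 10, -0.2 * peak],
                [2 * z0 + 1e-12, span, 2 * z0 + 1e-12, span, 0.2 * peak]))
    a1, tau1, a2, tau2 = sol.x[:4]
    if a1 + a2 <= 0:
        raise AnalysisError("degenerate biexponential fit")

    # rise tau from a difference-of-exponentials fit over the whole PSC
    tw = t - t[0]
    tau_w = (a1 * tau1 + a2 * tau2) / (a1 + a2)

    def full(p):
        a, tr_, td_, t_on = p
        u = tw - t_on
        return a * np.where(u <= 0, 0.0,
                            np.exp(-np.maximum(u, 0) / td_)
                            - np.exp(-np.maximum(u, 0) / tr_)) - z

    t_on0 = max(t[k] - t[0] - 3 * tau_w, 0.0)
    try:
        solf = optimize.least_squares(
            full, [peak, max(0.3 * (t[k] - t[0] - t_on0), trace.dt), tau_w, t_on0],
            bounds=([0, trace.dt / 10, trace.dt / 10, 0],
                    [10 * peak + 1e-12, span, 10 * span, tw[-1]]))
        tau_rise = float(min(solf.x[1], solf.x[2]))
    except Exception:
        tau_rise = None
    return BiexpFitResult(float(sgn * peak), tau_rise, float(a1), float(tau1),
                          float(a2), float(tau2), window_start_fraction)


# ---------------------------------------------------------------------------

def remove_action_potentials(trace: Trace, slope_threshold_V_per_s: float = 10.0) -> Trace:
    """Clip spikes at the AP threshold defined by the voltage slope (10 V/s)."""
    y = np.asarray(trace.values, dtype=float).copy()
    dvdt = np.gradient(y, trace.dt)  # mV/ms == V/s
    fast = dvdt > slope_threshold_V_per_s
    if not fast.any():
        return Trace(trace.label, trace.dt, trace.t0, y)
    k = int(np.argmax(fast))  # first threshold crossing
    thresh = y[k]
    y = np.minimum(y, thresh)
    return Trace(trace.label + "_noAP", trace.dt, trace.t0, y)


def burst_metrics(trace: Trace, baseline: float | None = None,
                  cutoff_hz: float = 100.0, order: int = 3,
                  remove_aps: bool = False,
                  baseline_window_ms: float | None = None) -> BurstMetrics:
    """Peak and integral of a burst response between baseline crossings.

    The window bounds come from the low-pass-filtered trace; the integral and
    peak are evaluated on the raw (or AP-clipped) trace inside the window.
    If the filtered trace never returns to baseline the window is flagged
    open-ended and closed at the end of the trace.
    """
    if remove_aps:
        trace = remove_action_potentials(trace)
    y = np.asarray(trace.values, dtype=float)
    t = trace.time()
    if baseline is None:
        if baseline_window_ms is not None:
            baseline = float(y[t < t[0] + baseline_window_ms].mean())
        else:
            baseline = float(y[0])
    fs = 1000.0 / trace.dt  # Hz
    if fs <= 2 * cutoff_hz:
        raise AnalysisError("sampling rate too low for the requested cutoff")
    b, a = signal.butter(order, cutoff_hz / (fs / 2))
    smooth = signal.filtfilt(b, a, y - baseline)

    k = int(np.argmax(np.abs(smooth)))
    if abs(smooth[k]) < 1e-12:
        return BurstMetrics(0.0, 0.0, None, None)
    sgn = np.sign(smooth[k])
    z = sgn * smooth
    below_before = np.where(z[:k] <= 0)[0]
    start = int(below_before[-1] + 1) if len(below_before) else 0
    below_after = np.where(z[k:] <= 0)[0]
    if len(below_after):
        end = int(k + below_after[0])
        open_ended = False
    else:
        end = len(z) - 1
        open_ended = True
    raw = y[start:end + 1] - baseline
    integral = float(np.sum(raw) * trace.dt)
    peak = float(raw[np.argmax(np.abs(raw))])
    return BurstMetrics(peak, integral, float(t[start]), float(t[end]), open_ended)


def normalized_conductance(iv: IVCurve, e_rev: float, v_norm: float,
                           use_tail: bool = False, guard_mV: float = 2.0):
    """Conductance–voltage curve g(v)/g(v_norm) from an IV relation.

    Holds within ``guard_mV`` of the reversal potential are excluded; the
    normalization hold must be present and retained.
    """
    v = np.asarray(iv.v_hold, dtype=float)
    i = np.asarray(iv.i_tail if use_tail else iv.i_peak, dtype=float)
    if not np.any(np.isclose(v, v_norm)):
        raise AnalysisError(f"normalization level {v_norm} mV not in the curve")
    keep = np.abs(v - e_rev) > guard_mV
    if not keep[np.argmin(np.abs(v - v_norm))]:
        raise AnalysisError("normalization level too close to the reversal")
    g = i[keep] / (v[keep] - e_rev)
    g_ref = g[np.argmin(np.abs(v[keep] - v_norm))]
    if g_ref == 0:
        raise AnalysisError("zero conductance at the normalization level")
    return v[keep], g / g_ref
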