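"""Synthetic inputs for the analysis pipeline.

Generates families of noisy postsynaptic-current traces across holding
potentials from known kernel and rectification/Mg-block parameters, so the
fitting and rectification statistics can be validated against ground truth
without any recorded data.  The noise model is additive white Gaussian with a
standard deviation expressed as a fraction of the absolute peak current;
electrode artifacts, series-resistance filtering, and stimulus artifacts are
deliberately not emulated.

Every generated dataset is reproducible bit-for-bit from its
:class:`GroundTruth` (which embeds the seed); the metadata returned alongside
the traces suffices to regenerate them.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .cable import Trace
from .morphology import Location, Morphology
from .synapses import SynapseSpec, kernel_conductance, preset

__all__ = ["GroundTruth", "generate_psc_set", "place_synapses", "CapacityError"]


class CapacityError(ValueError):
    pass


@dataclass(frozen=True)
class GroundTruth:
    """Complete generative description of a synthetic PSC dataset."""

    spec_name: str = "gabaA_nonlinear_unit"
    weight_nS: float = 1.0
    holds_mV: tuple[float, ...] = tuple(np.arange(-94.0, 27.0, 12.0))
    noise_sigma: float = 0.0        # fraction of the absolute peak current
    seed: int = 0
    dt_ms: float = 0.05
    t_stop_ms: float = 150.0
    onset_ms: float = 10.0

    def spec(self) -> SynapseSpec:
        return preset(self.spec_name, weight=self.weight_nS)


def generate_psc_set(gt: GroundTruth) -> tuple[dict[float, Trace], dict]:
    """Noisy model PSCs per holding level plus regeneration metadata.

    The noiseless current at hold v is the synapse's summed component
    conductance (voltage factors evaluated at v, as under ideal clamp) times
    the driving force, in pA.
    """
    if gt.noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    spec = gt.spec()
    rng = np.random.default_rng(gt.seed)
    t = np.arange(gt.dt_ms, gt.t_stop_ms + gt.dt_ms / 2, gt.dt_ms)
    traces: dict[float, Trace] = {}
    for v in gt.holds_mV:
        g = np.zeros_like(t)
        for c in spec.components:
            g += kernel_conductance(t - gt.onset_ms, c.kernel,
                                    c.fraction * spec.weight_nS) * c.factor(v)
        i = g * (v - spec.reversal)  # nS * mV = pA
        if gt.noise_sigma > 0:
            peak = np.abs(i).max()
            i = i + rng.normal(0.0, gt.noise_sigma * max(peak, 1e-12), i.shape)
        traces[float(v)] = Trace(f"psc_{v:+.0f}mV", gt.dt_ms, gt.dt_ms, i)
    meta = {"ground_truth": asdict(gt), "e_rev": spec.reversal,
            "onset_ms": gt.onset_ms}
    return traces, meta


def place_synapses(morph: Morphology, layer: str, n: int, seed: int = 0,
                   fixed_set: list[Location] | None = None,
                   kind: str = "glut") -> list[Location]:
    """Uniform seeded sampling of ``n`` placement slots without replacement.

    ``fixed_set`` bypasses sampling entirely (used for GABA synapses whose
    locations are held constant across sweeps).
    """
    if fixed_set is not None:
        return list(fixed_set)
    slots = morph.slots.get((layer, kind))
    if slots is None:
        raise CapacityError(f"no declared capacity for layer {layer!r}, kind {kind!r}")
    if n > len(slots):
        raise CapacityError(f"requested {n} synapses exceeds capacity {len(slots)} "
                            f"in {layer}/{kind}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(slots), size=n, replace=False)
    return [slots[int(i)] for i in idx]
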