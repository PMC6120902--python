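# gabarect

Compartmental modelling and IPSC analysis of **outward-rectifying dendritic
GABA<sub>A</sub> inhibition** and its interaction with NMDA receptors in
hippocampal CA1 pyramidal cells.

Dendrite-targeting interneurons (somatostatin- and NOS-expressing classes)
recruit α5-subunit-containing GABA<sub>A</sub> receptors that behave very
differently from the fast, linear perisomatic synapses made by parvalbumin
basket cells: they gate slowly (decay τ ≈ 30 ms) and their conductance is
strongly *outward rectifying* — only about 25 % of the maximal conductance is
available at the resting potential, rising steeply above −50 mV.  Because
voltage-gated NMDA receptors have almost the same activation profile
(Mg²⁺-block relief above −50 mV, decay τ ≈ 35 ms), these synapses deliver
shunting inhibition exactly when and where dendritic NMDA electrogenesis
threatens to become regenerative.  This package implements that model end to
end — membrane biophysics, synapse kinetics, cable solver, stimulation
protocols, and the analysis statistics used to quantify rectification — so
every claim can be recomputed from scratch on synthetic inputs.

## The model

Synaptic conductances are peak-normalized differences of exponentials scaled
by instantaneous voltage-dependent factors:

* NMDA Mg²⁺ block:
  `g(v) = g_max / (1 + 0.2801·[Mg²⁺]·exp(−0.087·(v + 10)))`, [Mg²⁺] = 1 mM;
* α5-type outward rectification:
  `g(v) = g_max·(0.25 + 0.75 / (1 + exp(−(v − V50)/Vslope)))`,
  V50 = −52 mV, Vslope = 3 mV (whole-tree variant: −60 mV / 4 mV).

A composite dendritic GABA synapse mixes 20 % fast linear (rise/decay
0.5/15 ms) with 80 % slow rectifying conductance (1/30 ms).  At −70 mV it
delivers 40 % of its total weight — 0.4 nS for a 1 nS synapse — and its
depolarized-to-rest peak-conductance ratio is ≈ 2.5, with the rectifying
component alone at ≈ 4 (the rectification index, RI).

The simulator discretizes branched morphologies into cylindrical compartments
and integrates the cable equation implicitly (Hines-ordered O(N) solve per
step, backward Euler by default, Crank–Nicolson optional), with distance-ruled
leak/HCN/K<sub>A</sub>/K<sub>DR</sub> channels, an outward-rectifying tonic
GABA conductance, ideal voltage clamp, per-pulse short-term plasticity, and
stochastic release.  Two model cells are built in: a passive single branch
(100 µm × 2 µm) and a synthetic CA1-like tree with layer-tagged synapse
capacities (≈6000 glutamatergic slots in stratum radiatum; 1464 glutamatergic
and 280 GABAergic slots in the tuft).

## Worked example

Simulate the full voltage-clamp IV protocol of the composite dendritic GABA
synapse (holds −94…+26 mV in 12-mV steps) and quantify its rectification:

```bash
gabarect iv --out iv_demo --set protocol.synapse=gabaA_nonlinear_unit
# RI = 2.53; sigmoid V50 = -63.4 mV, slope = 12.0 mV
```

The rectification index of 2.53 is the mixed synapse's depolarized-to-rest
conductance ratio (the 20/80 linear/rectifying composition predicts 2.5); the
fitted sigmoid slope sits at its lower bound of 12 mV because the slope
constraint cannot go below the holding-level spacing.  The same protocol on
the pure rectifying component (`protocol.synapse=gabaA_rectifying_only`)
yields RI = 4.

Characterize the synthetic full cell:

```bash
gabarect characterize --out char_demo --set model.preset=fullcell
# R_in = 65.6 MOhm, sag = 2.65 mV, tau = 83.0 ms, V_rest = -69.9 mV
```

The resting potential near −70 mV emerges from the balance of the −90 mV leak
against HCN; the sag at −100 pA is HCN-mediated.  (Absolute passive values are
properties of the synthetic stand-in morphology, not of any reconstructed
cell.)

In Python, the same machinery is a library:

```python
from gabarect import preset, gaba_peak_conductance, make_fast_variant

unit = preset("gabaA_nonlinear_unit")          # 1 nS, 20 % linear + 80 % rectifying
gaba_peak_conductance(unit, -70.0)             # 0.4015 nS at rest
make_fast_variant(unit, 5.0, "charge_preserving").weight_nS   # 4.5 nS
```

Other protocols: `gabarect branch-burst` (glutamatergic burst families against
one GABA synapse on the single branch), `gabarect tuft-burst` (3@200 Hz NMDA
spikes in tuft branches against 10 fixed GABA synapses), `gabarect fullcell`
(whole-tree 5@50 Hz bursts with stochastic release), `gabarect synth` /
`gabarect fit` (synthetic PSC families and kinetics fitting).

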