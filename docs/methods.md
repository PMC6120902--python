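# Methods

## Model overview

The package models dendritic inhibition in CA1 pyramidal cells as the
interaction of three voltage-dependent conductance families on passive or
weakly active cable:

1. **Glutamatergic synapses** — an AMPA conductance (rise 0.2 ms; decay 2 ms
   on the single branch, 3 ms in the full cell) plus an NMDA conductance
   (rise 3 ms, decay 35 ms) multiplied by the instantaneous Mg²⁺-block factor
   `1/(1 + 0.2801·[Mg]·e^(−0.087(v+10)))` with [Mg] = 1 mM.  Both reverse at
   0 mV and default to 0.14 nS per input.
2. **Dendritic GABA_A synapses** — a composite of 20 % fast linear (0.5/15 ms)
   and 80 % slow outward-rectifying conductance (1/30 ms) whose factor is
   `0.25 + 0.75/(1 + e^(−(v−V50)/Vslope))`.  The synaptic default is
   V50 = −52 mV, Vslope = 3 mV; the whole-tree population in the full-cell
   protocol uses V50 = −60 mV, Vslope = 4 mV.  Model variants transform this
   composite: *linear* (rectification frozen at its resting value, total
   conductance a constant 40 % of the weight), *rectifying-only* (linear
   component silenced), *α5-NAM* (rectifying weight halved), and *PV-like
   fast* (all kinetics set to the rectifying kernel sped up 5-fold, weight
   either ×5 or rescaled per component by old/new decay τ so the conductance
   time integral is preserved — 1 nS → 4.5 nS).
3. **Distributed channels** — leak (1/R_m, E as configured), HCN (E = −30 mV),
   A-type and delayed-rectifier potassium (E_K = −95 mV), and an
   outward-rectifying tonic GABA conductance sharing the synaptic rectification
   sigmoid.

Passive constants: C_m = 1 µF/cm², R_i = 200 Ω·cm, R_m = 60 kΩ·cm² (τ_m =
60 ms), E_leak = −90 mV, E_Na = 55 mV, E_K = −95 mV.

Density rules are linear distance ramps clamped at both ends: A-type K starts
at 1 mS/cm² and rises 1 %/µm between 50 and 300 µm; HCN is 0.2 mS/cm² in soma
and basal dendrites and rises 3 %/µm along the apical tree to 500 µm; the
delayed rectifier is deleted from all dendritic compartments beyond 100 µm;
tonic inhibition ramps 3 %/µm between 50 and 300 µm.  Sodium channels are
deliberately absent, so action-potential phenomena are out of model scope.

## Parameters chosen where the design was open

* **HCN gating** detail is not constrained by the quantities this model is
  built to reproduce — only its density rule and reversal carry quantitative
  weight.  We use a single Boltzmann gate; its half-activation (−90 mV, slope
  6 mV, τ between 20 and 60 ms) was set so that the full-cell leak/HCN/K
  balance rests near −70 mV,
  the physiologically observed resting potential.  Nothing quantitative is
  asserted about HCN beyond monotone activation by hyperpolarization and the
  presence of sag.
* **K_A / K_DR gates** are generic HH-style Boltzmann gates (K_A with an
  inactivation gate so it does not clamp dendritic plateaus at rest); only
  their density rules are constrained.
* **E_GABA_A = −70 mV** — unspecified by the source; chosen equal to the
  resting potential so phasic inhibition is shunting at rest, which is the
  regime the rectification mechanism exploits.  Config-exposed.
* **GABA_B** is simplified to a single slow difference-of-exponentials
  conductance (rise 50 ms, decay 200 ms, E = E_K, maximum 0.4 nS) paired 1:1
  with each GABA_A synapse in the full-cell protocol.  Each partner activates
  once per burst at an efficacy fraction (default 0.05) of its maximum: the
  metabotropic cascade approaches its ceiling only under prolonged
  high-frequency activation, and driving all ~145 partners at their maximum
  would add ~58 nS against a ~15 nS resting cell conductance and swamp every
  phasic effect.
* **Tonic density** is a calibration output, not a constant:
  `calibrate_tonic_density` finds the density at which a 50 % block changes
  the somatic resting conductance by a target (default 0.30 nS), mirroring
  the experimental calibration procedure.

## Morphologies

`build_single_branch` gives the 100 µm × 2 µm passive dendrite (resting at
−70 mV in the branch protocol).  `generate_synthetic_ca1` builds a
parameterized CA1-like stand-in: a 20 µm soma, four basal dendrites, a 400 µm
apical trunk carrying 20 obliques (attachment 50–290 µm, stratum radiatum),
and a tuft subtree spanning 400–700 µm path distance (stratum
lacunosum-moleculare), with small seeded length jitter.  Synapse capacities
are declared as explicit placement slots — 6000 glutamatergic in SR, 1464
glutamatergic and 280 GABAergic in the tuft, 147 GABAergic in SR — allocated
along sections by largest-remainder proportional to length.  The morphology
is labelled synthetic in its metadata; absolute passive numbers measured on
it (R_in, τ, sag) are properties of the stand-in, not of any reconstructed
cell, and are never asserted quantitatively.

Standard 7-column SWC is read and written.  Sections are split at branch
points; the cable segment from a branch point to a child's first sample
belongs to the child (except across the soma boundary, a point attachment),
and the writer places child attachment samples exactly on parent samples so
round trips preserve topology and total cable length.

## Numerics

Morphologies are discretized into an odd number of compartments per section
(so x = 0.5 is a compartment center; default compartment length ≤ 20 µm).
Each time step solves the full linear tree system — capacitance, axial
coupling, and all membrane conductances — exactly with a Hines-ordered O(N)
elimination.  Gates advance by an implicit exponential-Euler update.  The
*nonlinear* synaptic factors (Mg block, rectification, tonic rectification)
are evaluated at the previous step's voltage, which keeps the per-step system
linear; the residual first-order error is controlled by the self-convergence
property (halving dt changes burst peaks by < 0.5 % at the default
dt = 0.025 ms).  Backward Euler is the default; Crank–Nicolson solves the
half-step system and extrapolates (verified second-order on smooth passive
inputs).  Voltage clamp is ideal (no series resistance) via a stiff penalty
conductance; the clamp current is the penalty residual, exact up to ~10⁻⁵ pA
quantization.  Synaptic kernels are event-driven two-state exponentials, so
cost is independent of event count.  A settling period (default 500 ms)
precedes every stimulus.  All protocols are bit-reproducible given (seed,
config); in the tuft protocol the GABA placement uses its own fixed seed so
changing the glutamate seed never moves the inhibition.

## Analysis statistics

* **Sigmoidal IV fit**: `I(v) = (v−E_rev)·(g_min + (g_max−g_min)/(1+e^((V50−v)/Slope)))`
  by trust-region least squares with V50 multi-starts (−70/−50/−30 mV) and
  Slope bounded below by the holding-level spacing (flagged when pinned).
  With the standard 12-mV protocol this bound necessarily pins a 3-mV slope;
  parameter-recovery checks therefore use 2-mV spacing.  Monte-Carlo
  calibration (200 seeded replicates, 2-mV holds): V50 recovered within
  2.4 mV (95th percentile) at 2 % noise and within ~14 mV at 5 % noise.
* **Rectification index**: slope of an unconstrained line fit to peak currents
  above −40 mV divided by the conductance at −82 mV — the measured hold when
  one lies within 1 mV, otherwise the sigmoid-fit interpolation.  On noisy
  single IVs the −82 mV signal is only ~3 % of the maximal current, so
  per-replicate RI spreads widely at 2 % noise; the seeded median stays in
  [3.8, 4.2] and noiseless data give RI = 4.00.
* **Biexponential kinetics**: decay fit starts where the decaying limb falls
  to 95 % of peak; the reported decay τ is the amplitude-weighted mean
  (a₁τ₁+a₂τ₂)/(a₁+a₂).  A free baseline offset and a τ ≤ window-span bound
  keep noise from being absorbed into a spurious ultra-slow component
  (calibrated: decay τ within 5 % in ≥95 % of replicates at 2 % noise).
* **Burst metrics**: window bounds are the baseline crossings of a 3rd-order
  100-Hz Butterworth-filtered copy (zero-phase filtering); integral and peak
  come from the raw trace inside the window.  Optional AP removal clips the
  trace at the voltage where dV/dt first exceeds 10 V/s.
* **Normalized conductance**: g(v) = I/(v−E_rev), normalized at a chosen hold
  (+14 mV GABA, +26 mV NMDA conventions), with a guard excluding holds near
  the reversal.

## Protocol problem sizes

The turnkey protocols default to the study conditions: branch bursts sweep
1–7 (or 9) inputs at 5@50 Hz with facilitation ×(1, 1.5, 2, 2, 2); the tuft
protocol sweeps 15–165 first-pulse-active synapses (per-pulse active counts
round(n·[1, 1.5, 1.8]) drawn from the 1464-slot capacity), 10 fixed 1-nS GABA
synapses, 5 repeats; the full-cell protocol activates 200·r SR + 50·r SLM
glutamatergic synapses at p = 0.1 against 50 + 95 GABAergic synapses at
p₀ = 0.5 with layer-specific depression.  The test suite exercises scaled-down
sweeps (two input counts, two repeats) of the same protocols; the orderings
they assert (inhibited ≤ uninhibited branch; linear > nonlinear burst peaks;
PV-like inhibition failing at high input counts; NAM > control somatic
bursts) are insensitive to sweep size.

## What the synthetic data do and do not show

The synthetic PSC generator produces exactly the waveform family the model
assumes (noiseless kernel plus additive white Gaussian noise as a fraction of
peak).  Passing recovery tests therefore demonstrates correctness and
calibration of the estimators under the model's own assumptions — not
robustness to electrode artifacts, series-resistance filtering, correlated
noise, or overlapping spontaneous events, none of which are emulated.
Likewise the full-cell protocol on the synthetic morphology reproduces
conductance bookkeeping, E/I ratios, and orderings between variants; absolute
somatic millivolt values depend on the true reconstructed morphology and are
reported but not asserted.

## Known limitations

No sodium channels (no AP generation); no receptor desensitization, GABA
spillover, or release saturation; short-term plasticity is a fixed per-pulse
schedule, not a resource model; GABA_B is a placeholder conductance with a
single efficacy parameter; ideal voltage clamp only; no calcium dynamics or
temperature dependence.
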