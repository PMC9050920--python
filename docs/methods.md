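# Model and methods

## Overview

`astrogamma` simulates a three-layer model of gamma-band rhythm generation
in hippocampal area CA1 and the astrocytic modulation of that rhythm:

1. **Interneuron layer** — 200 fast-spiking basket cells on a virtual ring,
   each randomly connected to its 100 nearest neighbors (50 per side) by
   directed inhibitory synapses with probability 0.5 (expected in-degree 50).
2. **Pyramidal layer** — 200 pyramidal cells, one per interneuron, each
   receiving an independent Poisson train of rectangular current pulses and
   projecting a single excitatory synapse onto its paired interneuron.
   Pyramidal cells receive no synapses (drive-only layer).
3. **Astrocyte layer** — 200 astrocytes on a ring with nearest-neighbor gap
   junctions (Ca2+ and IP3 diffusion), astrocyte *i* sensing the glutamate
   released by pyramidal cell *i* and modulating the incoming synapses of
   interneuron *i*.

All cells use the Mainen-kinetics Hodgkin-Huxley model (Na m^3 h, single-
gate delayed-rectifier K), the astrocytes the classic CICR description of
IP3-receptor-mediated Ca2+ release with PLC-delta and glutamate-driven IP3
production.  Synchrony is quantified by the binarized pairwise coherence
k(tau) at bin width tau = 0.1/Omega in 500-ms epochs, with Omega the
inverse mean interspike interval.

## Neuron model

    C dV/dt = g_Na m^3 h (E_Na - V) + g_K n (E_K - V)
              + g_Leak (E_Leak - V) + I_app + I_P + I_syn
    dx/dt   = alpha_x(V) (1 - x) - beta_x(V) x,  x = m, n, h

Defaults: C = 1 uF/cm^2, g_Na = 40, g_K = 35, g_Leak = 0.3 mS/cm^2,
E_Na = 55, E_K = -77 mV, I_app = 0.7 uA/cm^2.  The rate functions have
removable singularities at V = -35 mV (m) and V = +25 mV (n); within
1e-6 mV of those points the analytic limits are used.

**Leak reversal.**  The package defaults to E_Leak = -64.4 mV.  With the
classic squid value -54.4 mV these kinetics leave no subthreshold current
to balance the depolarizing leak (the single-gate K channel only activates
near +4 mV), and the cell fires intrinsically at ~48 Hz for any shift
current — which abolishes the drive-gated architecture this model is built
around (quiescence without input, an action-potential threshold in the
excitatory weight, astrocytes silent until pyramidal firing).  At
-64.4 mV the isolated cell at I_app = 0.7 has a stable resting focus
(eigenvalues -0.036 +/- 0.087i ms^-1) coexisting with a ~19-Hz spiking
limit cycle (a bistable regime), and a Hopf bifurcation near
I_app ~ 0.85 uA/cm^2 separates rest from tonic spiking.  Every simulation
starts all cells in the rest basin; activity is input-driven.  The squid
value remains selectable through `NeuronParams(E_Leak=-54.4)`.

## Synapses

    I_syn_i = sum_j  g~_syn (E_syn_j - V_i) / (1 + exp(-V_j / k_syn))

with E_syn = -90 mV (inhibitory), 0 mV (excitatory) and k_syn = 0.2 mV.
The steep gate makes transmission effectively instantaneous: current flows
only while the presynaptic cell is above ~0 mV (about 1 ms per spike).
There are no rise/decay kinetics — this is a deliberate scope boundary, and
its dynamical consequences are discussed under Limitations.

The driving force is written (E_syn - V), matching the (E - V) channel
convention, so inhibition hyperpolarizes; the opposite sign convention
(V - E_syn), which appears in some descriptions of this model, is available
via `ModulationConfig(corrected_sign=False)`.

**Astrocytic modulation.**  When the Ca2+ of the astrocyte paired with the
postsynaptic interneuron exceeds 0.3 uM, the weights of that interneuron's
incoming synapses of the targeted kind scale as

    g~_syn = g_syn (1 + g_astro [Ca2+]_i)

(g_astro > 0 facilitation, < 0 depression).  A negative scaled weight —
possible under strong depression — is clamped at 0 by default, since a
negative conductance is unphysical; the clamp is configurable.

## Drive and glutamate

Each pyramidal cell receives a Poisson train (mean rate F_in, 0-400 s^-1)
of rectangular 2-ms pulses with amplitudes i.i.d. uniform on
[0, 2.5] uA/cm^2 (coefficient of variation 1/sqrt(3) ~ 57.7%).  Pulse
windows are half-open [onset, onset + 2 ms); overlapping pulses superpose.
Trains of distinct cells come from independent counter-keyed RNG streams
(`SeedSequence(master, spawn_key=...)`), so cell i's train does not depend
on the network size.  Glutamate follows dG/dt = -25 G + 500 sigma(V/0.5)
(rates s^-1), giving G* = 20 under sustained depolarization.

## Astrocytes

Standard CICR flux balance per cell (all rates s^-1 or uM/s; parameter
values in `AstrocyteParams`):

    d[Ca]/dt = J_ER - J_pump + J_leak + J_in - J_out + J_Cadiff
    dIP3/dt  = (IP3* - IP3)/tau_IP3 + J_PLC + J_IP3diff + J_Glu
    dz/dt    = a2 (d2 (IP3+d1)/(IP3+d3) (1-z) - [Ca] z)

J_Glu switches on sharply at G = 0.25 (slope 0.01).  Gap-junction terms are
discrete ring Laplacians (indices mod N), so diffusion vanishes on uniform
rings and conserves the ring totals exactly.  The glutamate-free rest state
(Ca ~ 0.070 uM, IP3 ~ 0.69 uM, z ~ 0.88) sits well below the 0.3-uM
gliotransmission threshold; sustained G > 0.25 produces Ca2+ pulses
crossing that threshold.  Astrocyte/glutamate derivatives are multiplied by
1e-3 when integrated on the millisecond grid (time-unit rescaling).

## Integration

Classical fixed-step RK4 at dt = 5e-3 ms over the whole coupled state
(2400 variables at n = 200).  The Poisson drive is held piecewise-constant
within a step (onsets snapped down to the grid; error <= dt, far below the
2-ms pulse width).  Initial conditions: neurons at the resting potential
(found by root-finding on the V-nullcline with gates at steady state) plus
uniform +/-1 mV seeded jitter to break symmetry; glutamate 0; astrocytes at
the G = 0 fixed point.  The discarded transient (default 1 s desk-scale,
15 s at study scale) makes results insensitive to these choices.

States with hard bounds (gates, z in [0,1]; G, Ca, IP3 >= 0) may overshoot
by integrator error; excursions below 1e-6 are clipped after each step,
larger ones abort the run with a diagnostic (they indicate dt too large).
A spike is an upward crossing of 0 mV, recorded at full dt resolution.

For speed the inner loop (numba) samples the six gating rates and the two
sigmoidal gates from a shared lookup table (linear interpolation on a
0.005-mV grid over [-150, 80] mV; relative error ~1e-7) and accumulates
synaptic input by scattering only the active presynaptic gates (a gate
below 1e-30 is stored as exact zero).  An exact-exponential mode
(`SimConfig(exact_rates=True)`) backs the oracle tests: over 200 ms the two
modes agree spike for spike.  With both modes the full run is a
deterministic function of (config, seed), bit-identical across repeats.

## Coherence measures

Per 500-ms epoch: Omega = 1000/mean(ISI) with ISIs pooled across neurons
(a per-neuron-averaged variant is available; pooled is the default), bins
of width tau = 0.1/Omega (L = floor(epoch/tau), trailing partial bin
dropped), a bin is 1 if it contains a spike, and

    k_ij = sum_l X(l) Y(l) / sqrt(sum_l X(l) sum_l Y(l))

averaged over all unordered pairs.  k_ij is defined as 0 when either train
is empty (the asynchrony limit of the 0/0 case); an epoch with Omega = 0
has k = 0.  F_gamma is the mean Omega over epochs with k > 0.2, else 0.
k_astro: within each maximal interval where the astrocytic Ca2+ summary
(network mean by default) exceeds 0.3 uM, take max(k) under facilitation or
min(k) under depression over the overlapping epochs, then average over
intervals; it is an absent value (None), never a number, when no Ca2+
pulse occurs in the analysis window.

## Parameter sweeps

`run_sweep` evaluates 1D/2D grids over g_syn, g_syn_P, F_in or g_astro with
per-pixel seeds derived as `SeedSequence(master, spawn_key=(i1, i2, rep))`,
making sweeps embarrassingly parallel and reproducible.  Diverged runs are
recorded with their reason in the output table, not dropped.
`region_bounds` extracts the parameter bounds of {k >= level} regions from
the resulting maps.

## Problem sizes used by the shipped tests and acceptance script

Unit and property tests use 20-cell networks and sub-second runs; the
acceptance computations use the full 200-cell network with 5-s runs (1 s
discarded, 3 seeds) for the baseline gamma state, a 10-s run for the mean
excitatory-drive measurement, reduced sweep grids (4 values of g_syn,
2 seeds, 5-s runs) for the coherence-region bounds, and 100-cell,
12-s runs (3 seeds) for the directional-modulation contrast, where the
astrocytic Ca2+ pulse cycle sets the minimum useful duration.  The
full study protocol (180-s runs, 10 replicates per pixel) is available
through the same interfaces.

## Limitations

* **Instantaneous synapses.**  With the steep presynaptic gate and no
  rise/decay kinetics, synaptic charge per spike is small and brief.  At
  the nominal operating point (g_syn = 0.01, g_syn_P = 0.7, F_in = 260)
  the excitatory synapse delivers ~40 uA/cm^2 kicks lasting well under a
  millisecond, each typically triggering one interneuron spike, while
  recurrent inhibition transfers too little charge to pace the
  population.  The simulated network therefore runs in a drive-slaved,
  weakly coherent regime (k ~ 0.10, Omega ~ 31 Hz, mean |I_exc| ~ 0.44
  uA/cm^2) rather than a collectively synchronized interneuron-network
  gamma state (k ~ 0.5 at ~21 Hz with mean |I_exc| < 0.15): that regime
  requires inhibitory conductances that persist for several milliseconds
  (GABA_A-like decay), which is outside this package's scope.  The
  directional effects of astrocytic modulation remain measurable as
  k/k_astro contrasts, but they are correspondingly small.
* Single-compartment neurons; no temperature scaling or channel noise.
* Current-based (not conductance-based) external drive; uncorrelated
  inputs across cells.
* Deterministic astrocyte ODEs (no stochastic IP3R gating), one astrocyte
  per interneuron, no second gliotransmitter pathway.
* Fixed-step RK4 only; dt is the user's stability/accuracy control
  (halving dt at the operating point changes epoch coherence by < 0.02).
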