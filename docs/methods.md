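# Methods

## Abstract models

**Truth-table convention.**  Tables are indexed by the integer encoding of
the input vector with `X₁` as the most significant bit (rows 000, 001, …,
111).  Every cross-module comparison — solver targets, enumeration
representatives, induced tables from simulations — uses this order.

**Linear separability** is decided by LP feasibility (HiGHS) over the 2ⁿ
constraints `w·X ≥ Θ` (output 1) and `w·X ≤ Θ − 1` (output 0) with free real
`w, Θ`.  The unit margin on the 0-side is lossless: a finite set of 0/1
points that any real plane separates can be rescaled to satisfy it.  The
check refuses `n > 20` (constraint explosion).  An independent integer-weight
brute-force oracle (weights in [−4, 4]ⁿ) cross-checks the LP on all two-input
functions and sampled three-input functions in the test suite.

**Minimal realizations.**  "Lowest possible integer weights" is formalized
as the lexicographic objective (max weight, sum of weights, Θ): the leading
term is the synaptic resolution, the quantity of interest.  The solver scans
all weight vectors in `[0, 2ⁿ]ⁿ` (n ≤ 4), derives each vector's least
feasible integer threshold directly (one more than the largest weighted sum
over the 0-rows), and certifies minimality by the completeness of the scan;
ties break toward the lexicographically smallest weight vector.  The bound
2ⁿ is far above what these functions need (the solver's minima never exceed
n − 1), so no certificate beyond the scan is required.

**Dominant-AND resolution law.**  For arbitrary `n` the analytic path
returns `(w₁, w_min, Θ) = (n−1, 1, n)` and re-checks the two binding
constraints — all non-dominant inputs together must stay below threshold
(`(n−1)·w_min < Θ`), the dominant input plus the weakest other must reach it
(`w₁ + w_min ≥ Θ`) — which are exactly the inequalities that force
`Θ ≥ n·w_min` and `w₁ ≥ (n−1)·w_min`.  No 2ⁿ enumeration is involved;
exhaustive search confirms tightness for n ≤ 4.

**Enumeration.**  The five-class result for n = 3 counts non-constant,
positive, linearly separable functions that depend on *all* inputs, grouped
into orbits under input permutation.  Constants and projections are excluded
because they are computations of fewer variables.  The orbit representative
is the lexicographically smallest member, which places the dominant input at
`X₁`.

## Biophysical model

**Geometry.**  Spherical soma (diameter 10 µm, area πd²) and two cylindrical
dendrites (400 µm × 0.4 µm), each discretized into four 100 µm iso-potential
compartments attached to the soma at one end; 9 compartments total.
Synapses "at 350 µm" land in the distal (300–400 µm) compartment.  Axial
coupling between adjacent compartments is `πa²/(R_a·l)`; the soma, treated
as an iso-potential point, couples to the first compartment through half a
segment.

**Membrane.**  `C_m = 1 µF/cm²`; reversal potentials `E_L = −65`,
`E_Na = 50`, `E_K = −90`, `E_s = 0` mV.  The soma carries transient sodium
and delayed-rectifier potassium (ḡ_K = 30 mS/cm²; ḡ_Na = 0 for
sub-threshold experiments, 650 mS/cm² for the spiking experiments, 100 as
the bare default); dendrites carry only leak, so all dendritic
non-linearity is synaptic-driving-force saturation.  Gating uses the
V_T-shifted formulation (v = V − V_T, rates in ms⁻¹):

    α_m = 0.32(13−v)/(exp((13−v)/4)−1)    β_m = 0.28(v−40)/(exp((v−40)/5)−1)
    α_h = 0.128·exp((17−v)/18)            β_h = 4/(1+exp((40−v)/5))
    α_n = 0.032(15−v)/(exp((15−v)/5)−1)   β_n = 0.5·exp((10−v)/40)

with removable singularities evaluated by their series limits.  `V_T` is
−50 mV, lowered to −55 mV in the spike-interpretation experiment to make
single coincidences suffice.  Synapses are conductance jumps (`g_max`
per presynaptic spike, default 20 nS) decaying with τ_s = 1 ms.

**Integration.**  Gating variables advance by exponential Euler against
their instantaneous steady states; the voltage vector advances by backward
Euler — every membrane current has conductance form, so the update is one
tridiagonal solve per step (compartments ordered tip–soma–tip).  Default
dt = 0.025 ms; halving dt moves reported peaks by well under the 0.05 mV
convergence tolerance the test suite asserts.  The membrane
equation is integrated in the conventional stable form
`C_m dV/dt = −I_ion + I_axial + I_s` (the sign printed on the model's source
equations would be anti-dissipative).  Internal units are mV/ms/µS/nF
(currents in nA), a consistent system that avoids float noise from SI
prefactors; all interfaces use mV, ms, nS, µm, mS/cm², Ω·cm.

**Spike detection:** upward crossings of −20 mV with 2 ms minimum
separation, robust against plateau behaviour at high input rates.

## Parameter provenance and calibration

Two membrane parameters required judgement:

* **Leak conductance.**  The model's stated leak of 10 mS/cm² yields a
  dendritic space constant of ~26 µm; a synapse 350 µm out would be ~13
  space constants from the soma and the somatic response to every stimulus
  in the studied range stays within 0.05 mV of rest — incompatible with the
  −54/−52.5 mV somatic peaks the model is reported to produce, by orders of
  magnitude.  The package default is g_L = 0.2 mS/cm² (τ_m = 5 ms),
  chosen with R_a (below) so that the sub-threshold benchmark is matched as
  closely as possible *while the dominant-AND spiking behaviour remains
  correct and robust*; the printed value remains available through
  configuration.
* **Axial resistivity** is not stated anywhere; the default
  R_a = 48.5 Ω·cm is calibrated so that 100 nS of clustered distal input
  peaks at −54.0 mV at the soma.

This joint calibration has a documented limit: with the two defaults the
dispersed-10 nS benchmark computes to −54.5 mV rather than −52.5 mV.  The
two benchmarks together would demand a ~20 ms membrane time constant
(g_L ≈ 0.05 mS/cm², R_a ≈ 108 Ω·cm) — at which point 100 Hz rate input
summates so strongly that single inputs and the clustered pair recruit
somatic spikes and the dominant-AND truth table collapses in every seed.  No
(g_L, R_a) pair satisfies both the printed sub-threshold peaks and the
spiking logic in this model structure; the package resolves the conflict in
favour of the computation, which is the point of the model.  All *relational*
sub-threshold results are insensitive to this choice and are asserted
strictly: dispersed > clustered at every total conductance (verified for
R_a = 30–150 Ω·cm), dispersed linearity within 5 %, clustered sub-linearity,
equal single-input somatic peaks ("synaptic democracy", exact here by
symmetry of the wiring), and single-input depolarisation ≤ 10 mV.

## Stimulus generators

*Rate interpretation:* an active input fires 25 spikes placed at the starts
of 25 distinct 1-ms bins drawn uniformly from a 250 ms window (100 Hz).
*Spike interpretation:* 25 ms bins; an active input fires once at the bin
start plus uniform ±1 ms jitter clipped at the bin start; per-bin activity is
Bernoulli(½) per input.  Every train comes from a named substream
(`default_rng([seed, context…, input_index])`), so adding an input never
perturbs the other inputs' spike times.  The generators emulate stationary
Poisson-like drive and perfect coincidence structure; they do not model
rate adaptation, correlated inputs, or synaptic failure, so passing tests
demonstrate the placement mechanism under idealized drive, not robustness to
those real-data features.

**Readouts.**  Rate mode: output 1 iff ≥ 1 somatic spike in the window
(the simulated counts are bimodal: 0 spikes for every sub-threshold pattern
across all tested seeds, ≥ 2 for firing patterns, so the criterion's exact
value is uncritical).  Spike mode: output bit per 25 ms bin, 1 iff a somatic
spike falls inside.  With all three inputs active the firing rate stays
moderate — never above the 100 Hz input rate (at most 25 spikes per 250 ms
window) with inter-spike intervals bounded below by the 2 ms detector
separation; this is the operational form of the refractory-moderation
property, chosen because per-seed count ratios between the three-input and
two-input conditions fluctuate too widely under the stochastic stimulus for
a sharp multiplicative bound.

## Known limitations

* The sub-threshold dispersed-10 nS benchmark deviates by ~2 mV from its
  reference value (see calibration above); the clustered benchmark is exact.
* Dendrites are strictly passive; no axon, temperature dependence, or
  stochastic channels.  The optional integrate-and-fire variant mentioned in
  the model's source material is not implemented.
* The exhaustive minimal-weight solver covers n ≤ 4; beyond that only the
  dominant-AND family has an (analytic) solution here.
* Compartment voltages are averages; there is no sub-compartment
  interpolation, so "350 µm" is the 300–400 µm segment.
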