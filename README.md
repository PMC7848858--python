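# sltu — sub-linear dendritic computation

Point-neuron models (perceptrons / linear threshold units, LTUs) can in
principle compute any linearly separable Boolean function, but some of those
functions demand ever more precise synaptic weights as the number of inputs
grows.  This package studies one such family — the *dominant-AND*,
`f_n(X) = X₁ ∧ (X₂ ∨ … ∨ Xₙ)`, where one input is necessary but not
sufficient — at two levels of description:

1. **Abstract threshold units.**  An LTU computes `f(X) = [Σ wᵢXᵢ ≥ Θ]` with
   non-negative integer weights.  For the dominant-AND the minimal dominant
   weight is forced to `w₁ = (n−1)·w_min` with `Θ = n·w_min`: the required
   synaptic *resolution* (largest integer weight) grows linearly with the
   number of inputs, so at n = 1000 the dominant input needs 999 unit
   contacts.  A *sub-linear threshold unit* (SLTU) adds a layer of saturating
   dendritic subunits, `f(X) = [Σⱼ E(Σᵢ w_ji Xᵢ) ≥ Θ]` with `E(Y) = min(Y,1)`:
   two dendrites, all-unit weights and a fixed `Θ = 2` implement the
   dominant-AND for every `n` — the dominant input is simply the one wired to
   its own dendrite.  The package enumerates all positive threshold functions
   of three inputs (five classes up to input relabelling), finds exhaustively
   minimal integer realizations, and verifies the resolution law.

2. **A biophysical model.**  A nine-compartment conductance-based neuron —
   Hodgkin–Huxley soma, two passive 400 µm dendrites of four compartments
   each — receives three identical synapses (20 nS, 350 µm from the soma):
   inputs 2 and 3 on one dendrite, the dominant input 1 alone on the other.
   Because concurrent synapses on a thin dendrite erode each other's driving
   force (`I_s = g_s(E_s − V)`), clustered input sums sub-linearly while
   dispersed input sums linearly, and the cell spikes exactly for the
   dominant-AND patterns — under both a rate code (100 Hz trains in 250 ms
   windows) and a spike-coincidence code (jittered spikes in 25 ms bins).

## Worked example

```bash
python examples/minimal_weights.py
```

```
D-AND: minimal LTU weights (2, 1, 1), threshold 3
D-OR: minimal LTU weights (2, 1, 1), threshold 2

D-AND of n=1000 inputs, LTU: dominant weight 999 (= n-1 times the smallest weight 1), threshold 1000
Same computation, 2-dendrite SLTU: max weight 1, threshold 2, dominant input makes 1 contact
```

The first two lines are the exhaustive solver: already at three inputs a
point neuron must give the dominant input double weight, and doubling all
weights (4,2,2 with Θ = 6 or 4) changes nothing — these are the smallest
integers.  At a thousand inputs the disparity is a 999-contact synapse versus
a single binary contact on a private dendrite.

The biophysical counterpart:

```bash
python examples/subthreshold_sweep.py
```

```
 total_nS  clustered_peak_mV  dispersed_peak_mV
    10.00             -58.03             -54.48
   100.00             -54.00             -45.21
```

With somatic sodium channels disabled, 100 nS crammed onto one distal site
moves the soma to −54.0 mV, while a tenth of that conductance split across
the two dendrites already beats it — the driving-force saturation that makes
placement, not strength, carry the computation.  `examples/rate_dand.py` and
`examples/spike_dand.py` then show the spiking neuron reproducing the
dominant-AND truth table under both input codes (the clustered pair 011 stays
silent; every pattern pairing the dominant input with another fires).

A thin CLI wraps the same library calls:

```bash
sltu enumerate -n 3 --outdir out      # five-class table as CSV
sltu min-weights -n 1000 --outdir out # minimal realizations as JSON
sltu sweep --outdir out               # clustered/dispersed sweep as CSV
sltu rate-table --seed 1 --outdir out # induced truth table + spike counts
sltu spike-table --seed 1 --outdir out
```

Each run writes a `provenance.json` (canonical config, SHA-256, seed,
version); identical config and seed reproduce byte-identical artifacts.

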