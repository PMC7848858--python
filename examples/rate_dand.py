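"""The spiking neuron computes the dominant-AND under the rate interpretation.

Each Boolean 1 is a 100 Hz spike train over 250 ms.  Inputs 2 and 3 share a
dendrite; input 1 (the dominant one) has its own.  All synapses are identical
(20 nS at 350 um) -- the computation is carried entirely by placement.
"""

from sltu import run_rate_truth_table

res = run_rate_truth_table(seed=1)
print("pattern  spikes  output   (output = 1 iff at least one somatic spike)")
for pattern, count in res.spike_counts.items():
    print(f"  {pattern}    {count:4d}    {int(count >= 1)}")
print(f"\ninduced truth table: {res.function.bits}")
print(f"equals the dominant-AND: {res.matches_dand()}")
# Only patterns where the dominant input fires together with another input
# produce output spikes; the clustered pair (011) stays silent because its
# two trains saturate the shared dendrite.
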