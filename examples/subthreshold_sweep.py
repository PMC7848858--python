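"""Clustered vs dispersed synaptic input in the biophysical model.

Sodium channels are disabled; the same total synaptic conductance is placed
either on one distal dendritic site (clustered) or split across the two
dendrites (dispersed).  Dispersed input sums linearly; clustered input
saturates because concurrent synapses erode each other's driving force.
"""

from sltu import run_subthreshold_sweep

df = run_subthreshold_sweep([10, 20, 40, 60, 80, 100])
print(df.to_string(index=False, float_format=lambda v: f"{v:8.2f}"))
print(
    "\nPeak somatic voltage (mV; rest = -65).  At every total conductance the"
    "\ndispersed placement depolarises the soma more; 100 nS clustered is still"
    "\nweaker than a fraction of that dispersed -- placement beats strength."
)
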