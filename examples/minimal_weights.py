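"""How much synaptic resolution does the dominant-AND need?

Builds the dominant-AND for 3 inputs, asks the exhaustive solver for the
smallest integer-weight point neuron (LTU) that computes it, then shows the
analytic law for large n and the constant-weight dendritic (SLTU)
alternative.
"""

from sltu import (
    dand,
    dor,
    min_dand_dominant_weight,
    min_ltu_realization,
    sltu_dand_construction,
    truth_table,
)

for name, fn in (("D-AND", dand(3)), ("D-OR", dor(3))):
    real = min_ltu_realization(truth_table(fn, 3))
    print(f"{name}: minimal LTU weights {real.config.weights}, "
          f"threshold {real.config.theta}")
# The dominant input needs twice the weight of the others for the D-AND --
# heterogeneous synapses are unavoidable in a point neuron.

w1, wmin, theta = min_dand_dominant_weight(1000)
print(f"\nD-AND of n=1000 inputs, LTU: dominant weight {w1} "
      f"(= n-1 times the smallest weight {wmin}), threshold {theta}")
# i.e. one presynaptic neuron must make 999 synaptic contacts.

cfg = sltu_dand_construction(1000)
print(f"Same computation, 2-dendrite SLTU: max weight "
      f"{max(max(r) for r in cfg.weights)}, threshold {cfg.theta}, "
      f"dominant input makes {cfg.total_weights()[0]} contact")
# Placement replaces strength: a single binary synapse on a private dendrite.
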