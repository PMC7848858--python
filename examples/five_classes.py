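"""Enumerate every computation a positive-weight point neuron can do on 3 inputs.

All 256 truth tables are filtered for positivity (monotonicity), linear
separability and dependence on all three inputs, then grouped into classes
under input relabelling.  Exactly five classes survive; three of them (OR,
AND/OR, AND) are symmetric, while the dominant-AND and dominant-OR single
out one input and therefore need heterogeneous synaptic weights in a point
neuron.
"""

from sltu import enumerate_positive_threshold_classes, min_ltu_realization

classes = enumerate_positive_threshold_classes(3)
print(f"{len(classes)} classes of positive threshold functions on 3 inputs:\n")
print(f"{'name':8s} {'table':10s} {'orbit':5s} {'minimal weights':16s} theta")
for c in classes:
    real = min_ltu_realization(c.representative)
    print(f"{c.name:8s} {c.representative.bits:10s} {c.size:5d} "
          f"{str(real.config.weights):16s} {real.config.theta}")
# 'table' lists outputs for inputs 000..111; 'orbit' counts the functions in
# the class (3 for D-AND/D-OR: one per choice of the dominant input).
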