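"""Minimal trace-plot helper (matplotlib required only here)."""

from __future__ import annotations

from .biophys import SimResult


def plot_traces(result: SimResult, compartments=(0,), ax=None):
    """Plot somatic (and optionally dendritic) voltage traces.

    Returns the matplotlib axes.  Compartment 0 is the soma.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    labels = {0: "soma"}
    for c in compartments:
        ax.plot(result.t_ms, result.V_mV[:, c], label=labels.get(c, f"comp {c}"))
    for t in result.spike_times_ms:
        ax.axvline(t, color="k", alpha=0.15, lw=0.8)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("V (mV)")
    ax.legend(frameon=False, fontsize=8)
    return ax
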