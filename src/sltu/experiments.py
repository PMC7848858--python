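"""The three biophysical experiments, as reproducible protocols.

1. *Sub-threshold sweep* (sodium channels off): peak somatic voltage versus
   total synaptic conductance, for clustered (one distal site) versus
   dispersed (split across the two dendrites) activation.  Dispersed input
   sums linearly; clustered input saturates through loss of driving force.
2. *Rate-interpretation dominant-AND* (ḡ_Na = 650 mS/cm², V_T = −50 mV):
   each of the 8 input patterns drives 100 Hz trains for 250 ms; the output
   bit is "at least one somatic spike".
3. *Spike-interpretation dominant-AND* (V_T = −55 mV): random per-bin input
   bits, one jittered spike per active input per 25 ms bin; the output bit of
   a bin is "a somatic spike fell inside it".

The wiring implements dominance by placement: inputs 2..n cluster on one
dendrite, input 1 contacts the other dendrite alone, all synapses at the same
distance (350 µm) with the same conductance (20 nS) — synaptic democracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biophys import (
    MembraneParams,
    Morphology,
    NeuronModel,
    SimResult,
    Synapse,
    build_neuron,
    simulate,
)
from .boolean import BooleanFunction, dand, input_vectors, truth_table
from .stimuli import SPIKE_BIN_MS, StimulusProtocol

__all__ = [
    "WiringPlan",
    "dand_wiring",
    "boolean_readout",
    "run_subthreshold_sweep",
    "run_rate_truth_table",
    "run_spike_truth_table",
    "RateTableResult",
    "SpikeTableResult",
]

GNA_SPIKING_MS_CM2 = 650.0
SYN_DISTANCE_UM = 350.0
SYN_GMAX_NS = 20.0


@dataclass(frozen=True)
class WiringPlan:
    """Input → (dendrite, distance µm, g_max nS) mapping."""

    entries: tuple[tuple[int, float, float], ...]

    @property
    def n_inputs(self) -> int:
        return len(self.entries)

    def synapses(self) -> tuple[Synapse, ...]:
        return tuple(
            Synapse(gmax_nS=g, dendrite=d, distance_um=x) for d, x, g in self.entries
        )


def dand_wiring(
    n_inputs: int = 3,
    distance_um: float = SYN_DISTANCE_UM,
    gmax_nS: float = SYN_GMAX_NS,
) -> WiringPlan:
    """Dominant-AND wiring: input 1 alone on dendrite 1, the rest share dendrite 0."""
    if n_inputs < 2:
        raise ValueError(f"need at least 2 inputs, got {n_inputs}")
    entries = [(1, distance_um, gmax_nS)]
    entries += [(0, distance_um, gmax_nS)] * (n_inputs - 1)
    return WiringPlan(tuple(entries))


def _model(wiring: WiringPlan, params: MembraneParams) -> NeuronModel:
    return build_neuron(Morphology(), params, wiring.synapses())


def boolean_readout(
    result: SimResult,
    protocol: StimulusProtocol,
    min_spikes: int = 1,
):
    """Boolean output of a simulation under the protocol's interpretation.

    Rate (and single-shot) mode: a single bit, 1 when at least ``min_spikes``
    somatic spikes fell in the window.  Spike mode: one bit per 25 ms bin.
    """
    spikes = np.asarray(result.spike_times_ms)
    if protocol.interpretation == "spike":
        n_bins = int(round(protocol.T_ms / protocol.bin_ms))
        bits = np.zeros(n_bins, dtype=int)
        for t in spikes:
            b = min(n_bins - 1, int(t // protocol.bin_ms))
            bits[b] = 1
        return bits
    return int(len(spikes) >= min_spikes)


def run_subthreshold_sweep(
    totals_nS: list[float] | None = None,
    params: MembraneParams | None = None,
    T_ms: float = 100.0,
    onset_ms: float = 10.0,
    dt_ms: float = 0.025,
) -> pd.DataFrame:
    """Clustered vs dispersed peak somatic voltage over total conductance.

    Sodium channels are disabled.  "Clustered": the whole conductance on one
    350 µm site; "dispersed": half on each dendrite's 350 µm site, activated
    simultaneously.  Returns columns total_nS, clustered_peak_mV,
    dispersed_peak_mV.
    """
    totals = totals_nS if totals_nS is not None else [10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
    params = params or MembraneParams()
    params = _with(params, gNa_mS_per_cm2=0.0)
    rows = []
    for tot in totals:
        peaks = {}
        for mode, placement in (
            ("clustered", [(0, float(tot))]),
            ("dispersed", [(0, tot / 2.0), (1, tot / 2.0)]),
        ):
            syns = tuple(
                Synapse(gmax_nS=g, dendrite=d, distance_um=SYN_DISTANCE_UM)
                for d, g in placement
                if g > 0
            )
            model = build_neuron(Morphology(), params, syns)
            trains = [[onset_ms]] * len(syns)
            res = simulate(model, trains, T_ms=T_ms, dt_ms=dt_ms, record=False)
            peaks[mode] = float(res.V_soma.max())
        rows.append(
            {
                "total_nS": float(tot),
                "clustered_peak_mV": peaks["clustered"],
                "dispersed_peak_mV": peaks["dispersed"],
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RateTableResult:
    """Induced truth table plus per-pattern spike counts (rate interpretation)."""

    function: BooleanFunction
    spike_counts: dict[str, int]

    def matches_dand(self) -> bool:
        return self.function == truth_table(dand(self.function.n), self.function.n)


def run_rate_truth_table(
    seed: int,
    params: MembraneParams | None = None,
    wiring: WiringPlan | None = None,
    dt_ms: float = 0.025,
) -> RateTableResult:
    """Simulate all 8 input patterns with 100 Hz trains; read the induced table.

    Spiking model: ḡ_Na = 650 mS/cm², V_T = −50 mV.  The output bit of a
    pattern is 1 when the 250 ms window contains at least one somatic spike.
    """
    wiring = wiring or dand_wiring()
    params = _with(
        params or MembraneParams(), gNa_mS_per_cm2=GNA_SPIKING_MS_CM2, VT_mV=-50.0
    )
    model = _model(wiring, params)
    n = wiring.n_inputs
    bits = []
    counts: dict[str, int] = {}
    for pat_idx, pattern in enumerate(input_vectors(n)):
        proto = StimulusProtocol.rate(tuple(pattern), seed, pat_idx)
        res = simulate(model, [list(tr) for tr in proto.trains_ms],
                       T_ms=proto.T_ms, dt_ms=dt_ms, record=False)
        key = "".join(map(str, pattern))
        counts[key] = len(res.spike_times_ms)
        bits.append(boolean_readout(res, proto))
    return RateTableResult(BooleanFunction(n, tuple(bits)), counts)


@dataclass(frozen=True)
class SpikeTableResult:
    """Per-bin input bits, output bits, and the bin-wise dominant-AND target."""

    input_bits: np.ndarray  # (n_bins, n_inputs)
    output_bits: np.ndarray  # (n_bins,)
    expected_bits: np.ndarray  # (n_bins,)

    def matches_dand(self) -> bool:
        return bool(np.array_equal(self.output_bits, self.expected_bits))


def run_spike_truth_table(
    n_bins: int,
    seed: int,
    p_active: float = 0.5,
    params: MembraneParams | None = None,
    wiring: WiringPlan | None = None,
    dt_ms: float = 0.025,
) -> SpikeTableResult:
    """Random per-bin activations under the spike interpretation.

    Spiking model with a lowered activation threshold (V_T = −55 mV).  Each
    input is active in each 25 ms bin with probability ``p_active`` (drawn
    from its own substream); the output bit of a bin is 1 when a somatic
    spike falls inside it.
    """
    wiring = wiring or dand_wiring()
    params = _with(
        params or MembraneParams(), gNa_mS_per_cm2=GNA_SPIKING_MS_CM2, VT_mV=-55.0
    )
    model = _model(wiring, params)
    n = wiring.n_inputs
    bits = np.empty((n_bins, n), dtype=int)
    for i in range(n):
        rng = np.random.default_rng([int(seed), 1000, i])
        bits[:, i] = (rng.random(n_bins) < p_active).astype(int)
    proto = StimulusProtocol.spike(bits, seed)
    res = simulate(model, [list(tr) for tr in proto.trains_ms],
                   T_ms=proto.T_ms, dt_ms=dt_ms, record=False)
    out = boolean_readout(res, proto)
    expected = np.array([dand(n, tuple(row)) for row in bits], dtype=int)
    return SpikeTableResult(bits, np.asarray(out), expected)


def _with(params: MembraneParams, **kw) -> MembraneParams:
    from dataclasses import replace

    return replace(params, **kw)
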