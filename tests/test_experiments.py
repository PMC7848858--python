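"""Experiment protocols: wiring, readout, sweep, truth tables (small runs).

The full 20-seed robustness runs live in the acceptance suite; here the
protocols are exercised on a couple of seeds to keep the unit suite fast.
"""

import numpy as np
import pytest

from sltu import (
    MembraneParams,
    StimulusProtocol,
    boolean_readout,
    dand,
    dand_wiring,
    run_rate_truth_table,
    run_spike_truth_table,
    run_subthreshold_sweep,
    truth_table,
)
from sltu.biophys import SimResult


def _fake_result(spikes):
    t = np.arange(0, 250.25, 0.25)
    v = np.full((len(t), 1), -65.0)
    return SimResult(t_ms=t, V_mV=v, spike_times_ms=tuple(spikes), rest_mV=-65.0)


def test_dand_wiring_layout():
    plan = dand_wiring(3)
    assert plan.entries[0][0] == 1  # dominant input alone on dendrite 1
    assert plan.entries[1][0] == 0 and plan.entries[2][0] == 0
    assert all(x == 350.0 and g == 20.0 for _, x, g in plan.entries)
    with pytest.raises(ValueError):
        dand_wiring(1)


def test_boolean_readout_rate_mode():
    proto = StimulusProtocol.rate((1, 1, 1), seed=0)
    assert boolean_readout(_fake_result([]), proto) == 0
    assert boolean_readout(_fake_result([100.0]), proto) == 1


def test_boolean_readout_spike_mode_bins():
    bits = np.zeros((4, 3), dtype=int)
    proto = StimulusProtocol.spike(bits, seed=0)
    out = boolean_readout(_fake_result([10.0, 60.0]), proto)
    assert out.tolist() == [1, 0, 1, 0]


def test_sweep_table_layout_and_trivia():
    df = run_subthreshold_sweep([0.0, 10.0, 100.0], T_ms=60.0)
    assert list(df.columns) == ["total_nS", "clustered_peak_mV", "dispersed_peak_mV"]
    row0 = df.iloc[0]
    assert row0.clustered_peak_mV == pytest.approx(-65.0, abs=1e-6)
    assert row0.dispersed_peak_mV == pytest.approx(-65.0, abs=1e-6)
    # dispersed exceeds clustered at every non-zero total
    tail = df.iloc[1:]
    assert (tail.dispersed_peak_mV > tail.clustered_peak_mV).all()


def test_sweep_ordering_holds_for_other_axial_resistivities():
    """Dispersed > clustered is driven by saturation, not by the R_a choice."""
    for ra in (30.0, 150.0):
        params = MembraneParams(Ra_ohm_cm=ra)
        df = run_subthreshold_sweep([10.0, 50.0, 100.0], params=params, T_ms=60.0)
        assert (df.dispersed_peak_mV > df.clustered_peak_mV).all(), ra


def test_rate_truth_table_one_seed():
    res = run_rate_truth_table(seed=0)
    assert res.matches_dand()
    assert res.spike_counts["000"] == 0
    assert res.spike_counts["011"] == 0  # clustered pair stays silent
    assert res.spike_counts["101"] >= 1 and res.spike_counts["110"] >= 1


def test_spike_truth_table_one_seed():
    res = run_spike_truth_table(n_bins=12, seed=0)
    assert res.matches_dand()
    assert res.input_bits.shape == (12, 3)
    # empty bins are silent
    empty = ~res.input_bits.any(axis=1)
    assert not res.output_bits[empty].any()


def test_firing_stays_moderate_with_all_inputs_active():
    """Refractoriness keeps the all-on output rate at or below the input rate."""
    for seed in (0, 1):
        res = run_rate_truth_table(seed=seed)
        c111 = res.spike_counts["111"]
        assert 1 <= c111 <= 25  # never exceeds the per-input spike count
    # ISI floor from the detector's refractory separation


def test_synaptic_democracy_individual_peaks_equal():
    """Each input alone produces the same somatic depolarisation within 1%."""
    from sltu.biophys import build_neuron, simulate
    from sltu.experiments import _model, _with

    params = _with(MembraneParams(), gNa_mS_per_cm2=0.0)
    model = _model(dand_wiring(3), params)
    peaks = []
    for i in range(3):
        trains = [[10.0] if k == i else [] for k in range(3)]
        res = simulate(model, trains, T_ms=100.0)
        peaks.append(res.V_soma.max() - res.rest_mV)
    assert max(peaks) <= min(peaks) * 1.01
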