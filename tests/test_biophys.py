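"""Compartmental model: geometry, gating, integration, sub-linear summation."""

import numpy as np
import pytest

from sltu import (
    MembraneParams,
    Morphology,
    SimulationDiverged,
    Synapse,
    build_neuron,
    hh_rates,
    max_somatic_depolarisation,
    simulate,
)
from sltu.biophys import detect_spikes


def test_default_morphology_has_nine_compartments():
    m = build_neuron()
    assert m.n_compartments == 9
    # soma couples to exactly the first compartment of each dendrite
    coupled = np.flatnonzero(m.axial_uS[0] > 0)
    assert coupled.tolist() == [1, 5]


def test_synapse_placement_350um_is_distal_compartment():
    morph = Morphology()
    assert Synapse(gmax_nS=1, dendrite=0, distance_um=350).resolve(morph) == 4
    assert Synapse(gmax_nS=1, dendrite=1, distance_um=350).resolve(morph) == 8
    assert Synapse(gmax_nS=1, dendrite=0, distance_um=0).resolve(morph) == 1
    assert Synapse(gmax_nS=1, dendrite=0, distance_um=400).resolve(morph) == 4


def test_bad_geometry_and_placement_rejected():
    with pytest.raises(ValueError):
        Morphology(dendrite_diameter_um=0.0)
    with pytest.raises(ValueError):
        Synapse(gmax_nS=1, dendrite=0, distance_um=500).resolve(Morphology())
    with pytest.raises(ValueError):
        Synapse(gmax_nS=-1, dendrite=0, distance_um=10)


def test_hh_rates_finite_everywhere_including_singularities():
    VT = -50.0
    # alpha_m singular at v=13, alpha_n at v=15, beta_m at v=40
    for v_off in (13.0, 15.0, 40.0):
        r = hh_rates(VT + v_off, VT)
        assert all(np.isfinite(val) and val >= 0 for val in r.values())
    grid = np.linspace(-100, 50, 301)
    r = hh_rates(grid, VT)
    for val in r.values():
        assert np.all(np.isfinite(val)) and np.all(np.asarray(val) >= 0)


def test_m_steady_state_monotone_in_voltage():
    grid = np.linspace(-100, 50, 601)
    r = hh_rates(grid, -50.0)
    minf = r["alpha_m"] / (r["alpha_m"] + r["beta_m"])
    assert np.all(np.diff(minf) > 0)


def test_rates_at_vt_match_closed_forms():
    r = hh_rates(-50.0, -50.0)  # v = 0
    assert r["alpha_m"] == pytest.approx(0.32 * 13 / (np.exp(13 / 4) - 1))
    assert r["beta_m"] == pytest.approx(0.28 * (-40) / np.expm1(-8))
    assert r["alpha_h"] == pytest.approx(0.128 * np.exp(17 / 18))
    assert r["beta_h"] == pytest.approx(4 / (1 + np.exp(8)))
    assert r["alpha_n"] == pytest.approx(0.032 * 15 / (np.exp(3) - 1))
    assert r["beta_n"] == pytest.approx(0.5 * np.exp(0.25))


def test_passive_equilibrium_stays_at_rest(passive_params):
    model = build_neuron(Morphology(), passive_params, ())
    res = simulate(model, [], T_ms=50.0)
    assert np.all(np.abs(res.V_mV - passive_params.EL_mV) < 1e-6)


def test_active_model_rests_quietly_without_input():
    model = build_neuron(Morphology(), MembraneParams(gNa_mS_per_cm2=650.0), ())
    res = simulate(model, [], T_ms=50.0)
    assert res.spike_times_ms == ()
    assert abs(res.V_soma[-1] - res.rest_mV) < 1.0


def test_single_distal_input_bounded_depolarisation(single_distal_model):
    """A 20 nS distal synapse depolarises the soma by well under 10 mV."""
    res = simulate(single_distal_model, [[10.0]], T_ms=100.0)
    depol = max_somatic_depolarisation(res)
    assert 0 < depol <= 10.0


def test_dt_convergence_on_peak(single_distal_model):
    res1 = simulate(single_distal_model, [[10.0]], T_ms=100.0, dt_ms=0.025)
    res2 = simulate(single_distal_model, [[10.0]], T_ms=100.0, dt_ms=0.0125)
    assert abs(res1.V_soma.max() - res2.V_soma.max()) < 0.05


def test_clustered_summation_sublinear(passive_na_only_off):
    """Two co-located 20 nS groups: joint peak < sum of individual peaks."""
    syn = (
        Synapse(gmax_nS=20, dendrite=0, distance_um=350),
        Synapse(gmax_nS=20, dendrite=0, distance_um=350),
    )
    model = build_neuron(Morphology(), passive_na_only_off, syn)
    rest = passive_na_only_off.EL_mV
    single = simulate(model, [[10.0], []], T_ms=100.0).V_soma.max() - rest
    joint = simulate(model, [[10.0], [10.0]], T_ms=100.0).V_soma.max() - rest
    assert joint < 2 * single * 0.99


def test_dispersed_summation_linear_within_5pc(passive_na_only_off):
    syn = (
        Synapse(gmax_nS=20, dendrite=0, distance_um=350),
        Synapse(gmax_nS=20, dendrite=1, distance_um=350),
    )
    model = build_neuron(Morphology(), passive_na_only_off, syn)
    rest = passive_na_only_off.EL_mV
    a = simulate(model, [[10.0], []], T_ms=100.0).V_soma.max() - rest
    b = simulate(model, [[], [10.0]], T_ms=100.0).V_soma.max() - rest
    joint = simulate(model, [[10.0], [10.0]], T_ms=100.0).V_soma.max() - rest
    assert joint == pytest.approx(a + b, rel=0.05)


def test_driving_force_shrinks_with_local_depolarisation(passive_na_only_off):
    """Per-unit-conductance synaptic current falls as local V approaches E_s."""
    syn = (Synapse(gmax_nS=100, dendrite=0, distance_um=350),)
    model = build_neuron(Morphology(), passive_na_only_off, syn)
    res = simulate(model, [[10.0]], T_ms=30.0)
    comp = model.synapse_compartments()[0]
    v_local = res.V_mV[:, comp]
    drive = passive_na_only_off.Es_mV - v_local  # current per unit conductance
    assert drive[np.argmax(v_local)] < drive[0]
    order = np.argsort(v_local)
    assert np.all(np.diff(drive[order]) <= 1e-9)


def test_divergence_reported_with_location():
    """An unphysical parameter set must fail loudly, naming the culprit."""
    params = MembraneParams(Cm_uF_per_cm2=1e-9, gNa_mS_per_cm2=650.0)
    syn = (Synapse(gmax_nS=500, dendrite=0, distance_um=50),)
    model = build_neuron(Morphology(), params, syn)
    try:
        res = simulate(model, [[1.0]], T_ms=20.0, dt_ms=5.0)
    except SimulationDiverged as err:
        assert "compartment" in str(err) and "ms" in str(err)
    else:  # tiny capacitance may integrate stably; accept finite output
        assert np.all(np.isfinite(res.V_mV))


def test_spike_detector_threshold_and_refractory():
    t = np.arange(0, 10, 0.1)
    v = np.full_like(t, -65.0)
    v[(t > 2) & (t < 2.4)] = 0.0
    v[(t > 2.9) & (t < 3.3)] = 0.0  # within 2 ms of the first: ignored
    v[(t > 7) & (t < 7.4)] = 0.0
    spikes = detect_spikes(t, v)
    assert len(spikes) == 2
    assert spikes[0] == pytest.approx(2.1, abs=0.1)
    assert spikes[1] == pytest.approx(7.1, abs=0.1)


def test_spike_times_strictly_increasing_in_sim():
    from sltu import dand_wiring
    from sltu.experiments import GNA_SPIKING_MS_CM2, _model, _with

    params = _with(MembraneParams(), gNa_mS_per_cm2=GNA_SPIKING_MS_CM2, VT_mV=-55.0)
    model = _model(dand_wiring(), params)
    trains = [[50.0], [50.0], [50.5]]
    res = simulate(model, trains, T_ms=100.0)
    assert len(res.spike_times_ms) >= 1
    assert np.all(np.diff(res.spike_times_ms) > 0)
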