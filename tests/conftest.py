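import numpy as np
import pytest

from sltu import MembraneParams, Morphology, Synapse, build_neuron


@pytest.fixture(scope="session")
def passive_params():
    """Membrane parameters with active channels disabled."""
    return MembraneParams(gNa_mS_per_cm2=0.0, gK_mS_per_cm2=0.0)


@pytest.fixture(scope="session")
def passive_na_only_off():
    """Sodium disabled, potassium left in place (sub-threshold experiments)."""
    return MembraneParams(gNa_mS_per_cm2=0.0)


def distal_synapse(dendrite: int, gmax_nS: float) -> Synapse:
    return Synapse(gmax_nS=gmax_nS, dendrite=dendrite, distance_um=350.0)


@pytest.fixture(scope="session")
def single_distal_model(passive_na_only_off):
    """One 20 nS synapse at 350 µm on dendrite 0, sodium off."""
    return build_neuron(
        Morphology(), passive_na_only_off, (distal_synapse(0, 20.0),)
    )
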