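import numpy as np
import pytest

from recarch.config import CortexParams
from recarch.cortex import CortexState, LayerWiring
from recarch.stimgen import Presentation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# Plasticity constants chosen dyadic so that every weight and potential is
# exactly representable and float summation order cannot matter.
MICRO_PARAMS = dict(
    n_columns=3, l1_neurons=3, l1_branches=2, l1_branch_synapses=12,
    l2_neurons=2, l2_branches=1, l2_branch_synapses=2,
    l3_branches=1, l3_branch_synapses=2,
    p_bias=0.5, w_init=(1.0, 1.0, 1.0), w_max=(4.0, 2.0, 2.0),
    theta_branch=(3.0, 1.0, 1.0), theta_neuron=(1, 1, 1),
    delta_pot=(0.125, 0.25, 0.25), delta_dep=(0.0625, 0.125, 0.125),
    miss_min=(4, 4, 4), rho_max=(10, 10, 10), s_homeo=0.75,
)


@pytest.fixture
def micro_params():
    return CortexParams(**MICRO_PARAMS)


def manual_state(params: CortexParams, K1, K2, K3, n_inputs: int) -> CortexState:
    """Assemble a CortexState from explicit multiplicity matrices."""
    w1 = LayerWiring(K=np.asarray(K1, dtype=np.uint8),
                     n_neurons=params.n_columns * params.l1_neurons,
                     branches_per_neuron=params.l1_branches)
    w2 = LayerWiring(K=np.asarray(K2, dtype=np.uint8),
                     n_neurons=params.n_columns * params.l2_neurons,
                     branches_per_neuron=params.l2_branches)
    w3 = LayerWiring(K=np.asarray(K3, dtype=np.uint8),
                     n_neurons=params.n_columns,
                     branches_per_neuron=params.l3_branches)
    W = [w.K.astype(np.float32) * np.float32(params.w_init[i])
         for i, w in enumerate((w1, w2, w3))]
    return CortexState(params=params, n_inputs=n_inputs,
                       wiring=(w1, w2, w3), W=W)


def presentation_from(spikes: np.ndarray, labels=(0,),
                      segments=None) -> Presentation:
    spikes = np.asarray(spikes, dtype=np.uint8)
    if segments is None:
        segments = np.zeros(spikes.shape[0], dtype=np.int64)
    return Presentation(spikes=spikes, labels=tuple(labels),
                        segments=np.asarray(segments))
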