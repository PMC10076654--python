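"""Columnar three-layer cortex with temporal-correlation plasticity.

Topology.  Each column holds 10 layer-1 neurons, 10 layer-2 neurons and one
layer-3 neuron (all counts configurable).  Layer-1 branches sample external
afferents — with probability ``p_bias`` from the column's hippocampal
co-activation group — while layers 2 and 3 wire strictly within the column.
A neuron fires in a timeslot when enough of its branches reach their
threshold; branch potential is the weighted sum of that slot's afferent
spikes.  Spikes travel between layers with a one-timeslot delay.

Plasticity.  Four consequence-free rules run once per 200 ms window:

* potentiation — a synapse whose afferent spiked in the same or the
  immediately preceding timeslot of a fire of its neuron at least
  ``pair_min`` times in the window gains ``delta_pot`` (fewer pairings and
  the tentative increase is reversed, i.e. the weight is untouched);
* depression — a synapse whose branch fired ``miss_min`` or more times
  without that synapse's afferent spiking loses ``delta_dep`` (floored at 0);
* homeostasis — a neuron firing more than ``rho_max`` times in the window
  has all its weights scaled by ``s_homeo``, preserving their ratios;
* ceiling — weights never exceed ``w_max``.

Weights are constant within a window; all changes commit at the window end.
Because of this the within-window dynamics are exactly feed-forward and are
evaluated with one matrix product per layer over the whole window; the
incremental ``step_timeslot`` path produces identical spikes and weights.

Multiple synapses from the same afferent onto the same branch are collapsed
into an integer multiplicity ``K``; a weight matrix entry is the summed
weight of those ``K`` identical synapses and every rule scales accordingly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import CortexParams
from .errors import ConfigError, StateError
from .stimgen import Presentation

__all__ = ["LayerWiring", "CortexState", "init_cortex", "step_timeslot",
           "begin_window", "end_window_plasticity", "run_presentation",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class LayerWiring:
    """Immutable connection multiplicities of one layer.

    ``K[b, s]`` counts synapses from source ``s`` onto branch ``b``; branch
    ``b`` belongs to neuron ``b // branches_per_neuron``.
    """

    K: np.ndarray                 # (n_branches_total, n_sources) uint8
    n_neurons: int
    branches_per_neuron: int

    @property
    def neuron_of_branch(self) -> np.ndarray:
        return np.arange(self.K.shape[0]) // self.branches_per_neuron


@dataclass
class CortexState:
    params: CortexParams
    n_inputs: int
    wiring: Tuple[LayerWiring, LayerWiring, LayerWiring]
    W: List[np.ndarray]           # per-layer float32 weights, same shape as K
    clock: int = 0
    # window bookkeeping (internal)
    _expected_slots: int = 0
    _slot: int = 0
    _prev_f1: Optional[np.ndarray] = None
    _prev_f2: Optional[np.ndarray] = None
    _hist: dict = field(default_factory=dict)

    @property
    def in_window(self) -> bool:
        return self._expected_slots > 0

    @property
    def n_columns(self) -> int:
        return self.params.n_columns


# ---------------------------------------------------------------------------
# initialisation

def init_cortex(params: CortexParams,
                bias_groups: Sequence[Sequence[int]],
                rng: np.random.Generator,
                n_inputs: int = 400) -> CortexState:
    """Wire a cortex, biasing layer-1 sources toward per-column input groups.

    Each layer-1 synapse slot independently draws its source from the
    column's bias group with probability ``p_bias`` (uniform within the
    group) and uniformly from all afferents otherwise.  Layer-2/3 branches
    partition the previous layer of their own column when the synapse count
    allows full coverage, and sample without replacement otherwise.  All
    weights start at ``w_init`` per synapse.
    """
    p = params
    if len(bias_groups) != p.n_columns:
        raise ConfigError("need exactly one bias group per column")
    if any(len(g) == 0 for g in bias_groups):
        raise ConfigError("bias groups must be non-empty")

    C = p.n_columns
    nb1 = C * p.l1_neurons * p.l1_branches
    K1 = np.zeros((nb1, n_inputs), dtype=np.uint8)
    per_col_br = p.l1_neurons * p.l1_branches
    for col in range(C):
        group = np.asarray(bias_groups[col], dtype=np.int64)
        slots = per_col_br * p.l1_branch_synapses
        use_bias = rng.random(slots) < p.p_bias
        bias_src = group[rng.integers(0, len(group), size=slots)]
        unif_src = rng.integers(0, n_inputs, size=slots)
        src = np.where(use_bias, bias_src, unif_src)
        branch_ids = np.repeat(
            np.arange(col * per_col_br, (col + 1) * per_col_br),
            p.l1_branch_synapses)
        np.add.at(K1, (branch_ids, src), 1)
    w1 = LayerWiring(K=K1, n_neurons=C * p.l1_neurons,
                     branches_per_neuron=p.l1_branches)

    def _within_column(n_post: int, n_branches: int, spb: int, n_pre: int,
                       pre_per_col: int) -> LayerWiring:
        K = np.zeros((C * n_post * n_branches, C * pre_per_col), dtype=np.uint8)
        if spb > pre_per_col:
            raise ConfigError("branch synapse count exceeds previous layer size")
        for col in range(C):
            base_pre = col * pre_per_col
            for n in range(n_post):
                if n_branches * spb == pre_per_col:
                    order = rng.permutation(pre_per_col)
                    chunks = order.reshape(n_branches, spb)
                else:
                    chunks = np.stack([
                        rng.choice(pre_per_col, size=spb, replace=False)
                        for _ in range(n_branches)])
                for b in range(n_branches):
                    gb = (col * n_post + n) * n_branches + b
                    K[gb, base_pre + chunks[b]] += 1
        return LayerWiring(K=K, n_neurons=C * n_post,
                           branches_per_neuron=n_branches)

    w2 = _within_column(p.l2_neurons, p.l2_branches, p.l2_branch_synapses,
                        C * p.l1_neurons, p.l1_neurons)
    w3 = _within_column(1, p.l3_branches, p.l3_branch_synapses,
                        C * p.l2_neurons, p.l2_neurons)

    W = [w.K.astype(np.float32) * np.float32(p.w_init[i])
         for i, w in enumerate((w1, w2, w3))]
    return CortexState(params=p, n_inputs=n_inputs, wiring=(w1, w2, w3), W=W)


# ---------------------------------------------------------------------------
# forward dynamics

def _layer_forward(W: np.ndarray, wiring: LayerWiring, inp: np.ndarray,
                   theta_b: float, theta_n: int):
    """Branch-then-neuron integration for a batch of timeslots.

    ``inp`` is (T, n_sources) float32; returns (fires (T, n_neurons) bool,
    branch_fires (T, n_branches) bool).
    """
    pot = inp @ W.T
    B = pot >= theta_b
    T = inp.shape[0]
    F = B.reshape(T, wiring.n_neurons, wiring.branches_per_neuron).sum(axis=2) \
        >= theta_n
    return F, B


def begin_window(state: CortexState, n_timeslots: int) -> None:
    """Open a plasticity window of ``n_timeslots`` (one 200 ms presentation)."""
    if state.in_window:
        raise StateError("previous window not closed")
    if n_timeslots < 1:
        raise ConfigError("window must contain at least one timeslot")
    state._expected_slots = n_timeslots
    state._slot = 0
    state._prev_f1 = np.zeros(state.wiring[0].n_neurons, dtype=bool)
    state._prev_f2 = np.zeros(state.wiring[1].n_neurons, dtype=bool)
    state._hist = {k: [] for k in ("x", "b1", "f1", "f1d", "b2", "f2",
                                   "f2d", "b3", "f3")}


def step_timeslot(state: CortexState, input_spikes: np.ndarray):
    """Advance the cortex one timeslot; returns (f1, f2, f3) firing vectors.

    Layer outputs feed the next layer with a one-timeslot delay, so the
    layer-3 response to an input pattern appears two slots later.
    """
    if not state.in_window:
        raise StateError("call begin_window before stepping")
    x = np.asarray(input_spikes)
    if x.shape != (state.n_inputs,):
        raise ConfigError(f"input must have length {state.n_inputs}")
    p = state.params
    xf = x.astype(np.float32)[None, :]
    f1, b1 = _layer_forward(state.W[0], state.wiring[0], xf,
                            p.theta_branch[0], p.theta_neuron[0])
    f1d = state._prev_f1
    f2, b2 = _layer_forward(state.W[1], state.wiring[1],
                            f1d.astype(np.float32)[None, :],
                            p.theta_branch[1], p.theta_neuron[1])
    f2d = state._prev_f2
    f3, b3 = _layer_forward(state.W[2], state.wiring[2],
                            f2d.astype(np.float32)[None, :],
                            p.theta_branch[2], p.theta_neuron[2])
    h = state._hist
    h["x"].append(x.astype(bool))
    h["b1"].append(b1[0]); h["f1"].append(f1[0]); h["f1d"].append(f1d.copy())
    h["b2"].append(b2[0]); h["f2"].append(f2[0]); h["f2d"].append(f2d.copy())
    h["b3"].append(b3[0]); h["f3"].append(f3[0])
    state._prev_f1 = f1[0]
    state._prev_f2 = f2[0]
    state._slot += 1
    state.clock += 1
    return f1[0], f2[0], f3[0]


def _window_forward(state: CortexState, X: np.ndarray):
    """Evaluate a whole window at once (weights are fixed within a window)."""
    p = state.params
    T = X.shape[0]
    Xf = X.astype(np.float32)
    f1, b1 = _layer_forward(state.W[0], state.wiring[0], Xf,
                            p.theta_branch[0], p.theta_neuron[0])
    f1d = np.zeros_like(f1)
    f1d[1:] = f1[:-1]
    f2, b2 = _layer_forward(state.W[1], state.wiring[1],
                            f1d.astype(np.float32),
                            p.theta_branch[1], p.theta_neuron[1])
    f2d = np.zeros_like(f2)
    f2d[1:] = f2[:-1]
    f3, b3 = _layer_forward(state.W[2], state.wiring[2],
                            f2d.astype(np.float32),
                            p.theta_branch[2], p.theta_neuron[2])
    return dict(x=X.astype(bool), b1=b1, f1=f1, f1d=f1d,
                b2=b2, f2=f2, f2d=f2d, b3=b3, f3=f3)


# ---------------------------------------------------------------------------
# plasticity

def _pair_counts(F: np.ndarray, inp: np.ndarray) -> np.ndarray:
    """Per (neuron, source): fires with the source active at t or t-1."""
    pre = inp.copy()
    pre[1:] |= inp[:-1]
    return F.astype(np.float32).T @ pre.astype(np.float32)


def _miss_counts(B: np.ndarray, inp: np.ndarray) -> np.ndarray:
    """Per (branch, source): branch fires in which the source was silent."""
    Bf = B.astype(np.float32)
    return Bf.sum(axis=0)[:, None] - Bf.T @ inp.astype(np.float32)


def _apply_layer(state: CortexState, li: int, pair_nc: np.ndarray,
                 miss_bc: np.ndarray, neuron_fires: np.ndarray) -> None:
    p = state.params
    W = state.W[li]
    wiring = state.wiring[li]
    K = wiring.K
    Kf = K.astype(np.float32)
    connected = K > 0
    nob = wiring.neuron_of_branch
    pot = (pair_nc >= p.pair_min)[nob] & connected
    W += np.float32(p.delta_pot[li]) * Kf * pot
    dep = (miss_bc >= p.miss_min[li]) & connected
    np.maximum(W - np.float32(p.delta_dep[li]) * Kf * dep, np.float32(0.0),
               out=W)
    over = neuron_fires > p.rho_max[li]
    if over.any():
        W[over[nob]] *= np.float32(p.s_homeo)
    np.minimum(W, Kf * np.float32(p.w_max[li]), out=W)


def end_window_plasticity(state: CortexState) -> CortexState:
    """Commit the window's plasticity: potentiate, depress, homeostase, cap.

    Raises if called mid-window.  Counters and histories reset afterwards.
    """
    if not state.in_window:
        raise StateError("no open window")
    if state._slot != state._expected_slots:
        raise StateError("end_window_plasticity called mid-window")
    h = state._hist
    arr = {k: (v if isinstance(v, np.ndarray) else np.asarray(v))
           for k, v in h.items()}

    pair1 = _pair_counts(arr["f1"], arr["x"])
    miss1 = _miss_counts(arr["b1"], arr["x"])
    _apply_layer(state, 0, pair1, miss1, arr["f1"].sum(axis=0))

    pair2 = _pair_counts(arr["f2"], arr["f1d"])
    miss2 = _miss_counts(arr["b2"], arr["f1d"])
    _apply_layer(state, 1, pair2, miss2, arr["f2"].sum(axis=0))

    pair3 = _pair_counts(arr["f3"], arr["f2d"])
    miss3 = _miss_counts(arr["b3"], arr["f2d"])
    _apply_layer(state, 2, pair3, miss3, arr["f3"].sum(axis=0))

    state._expected_slots = 0
    state._slot = 0
    state._hist = {}
    state._prev_f1 = None
    state._prev_f2 = None
    return state


# ---------------------------------------------------------------------------
# presentation-level driver

def run_presentation(state: CortexState, pres: Presentation) -> np.ndarray:
    """Run one 200 ms window and return layer-3 spike counts per segment.

    Returns an (n_columns, n_labels) integer matrix: layer-3 spikes of each
    column attributed to each of the presentation's category segments.  A
    layer-3 spike at timeslot t is credited to the segment active
    ``output_latency`` slots earlier, matching the interlayer delays.
    Window plasticity is applied before returning (cortical learning never
    stops, including during test phases).
    """
    if pres.spikes.shape[1] != state.n_inputs:
        raise ConfigError("presentation input width mismatch")
    p = state.params
    T = pres.n_timeslots
    begin_window(state, T)
    out = _window_forward(state, pres.spikes)
    state._hist = out
    state._slot = T
    state.clock += T

    f3 = out["f3"]                               # (T, n_columns)
    t_idx = np.arange(T)
    seg_eff = pres.segments[np.maximum(t_idx - p.output_latency, 0)]
    n_labels = len(pres.labels)
    counts = np.zeros((state.n_columns, n_labels), dtype=np.int64)
    for k in range(n_labels):
        counts[:, k] = f3[seg_eff == k].sum(axis=0)

    if p.l3_gate_min_l2 > 0:
        l2_fires = out["f2"].sum(axis=0).reshape(state.n_columns,
                                                 p.l2_neurons).sum(axis=1)
        counts[l2_fires < p.l3_gate_min_l2] = 0
    if p.l3_gate_min_count > 0:
        # a column "produces an output" for a segment only when enough
        # conditions were detected there; weaker responses are not forwarded
        counts[counts < p.l3_gate_min_count] = 0

    end_window_plasticity(state)
    return counts


# ---------------------------------------------------------------------------
# checkpointing

def save_checkpoint(state: CortexState, path: str | Path) -> None:
    """Serialise wiring, weights and clock to an .npz with a JSON header."""
    if state.in_window:
        raise StateError("cannot checkpoint mid-window")
    header = {
        "params": {k: getattr(state.params, k)
                   for k in state.params.__dataclass_fields__},
        "n_inputs": state.n_inputs,
        "clock": state.clock,
    }
    np.savez_compressed(
        Path(path),
        header=np.frombuffer(json.dumps(header, default=list).encode(),
                             dtype=np.uint8),
        K1=state.wiring[0].K, K2=state.wiring[1].K, K3=state.wiring[2].K,
        W1=state.W[0], W2=state.W[1], W3=state.W[2],
    )


def load_checkpoint(path: str | Path) -> CortexState:
    with np.load(Path(path)) as z:
        header = json.loads(bytes(z["header"]).decode())
        pd = {k: tuple(v) if isinstance(v, list) else v
              for k, v in header["params"].items()}
        params = CortexParams(**pd)
        wirings = []
        for i, key in enumerate(("K1", "K2", "K3")):
            n_neurons = (params.n_columns *
                         (params.l1_neurons, params.l2_neurons, 1)[i])
            bpn = (params.l1_branches, params.l2_branches,
                   params.l3_branches)[i]
            wirings.append(LayerWiring(K=z[key], n_neurons=n_neurons,
                                       branches_per_neuron=bpn))
        W = [z["W1"].copy(), z["W2"].copy(), z["W3"].copy()]
        return CortexState(params=params, n_inputs=header["n_inputs"],
                           wiring=tuple(wirings), W=W,
                           clock=int(header["clock"]))
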