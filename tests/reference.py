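"""Brute-force per-synapse reference cortex used as an independent oracle.

Simulates every synapse individually with explicit Python loops — including
synapses that the package collapses into multiplicity counts — and applies
the window plasticity rules one synapse at a time.  Slow, but transparent;
used only on micro cortices in tests.
"""

from __future__ import annotations

import numpy as np


class LoopCortex:
    """Expand a package CortexState into individual synapses and simulate."""

    def __init__(self, state):
        self.p = state.params
        self.n_inputs = state.n_inputs
        self.layers = []
        for li in range(3):
            wiring = state.wiring[li]
            K = wiring.K
            W = state.W[li]
            branches = []
            for b in range(K.shape[0]):
                syns = []
                for s in np.nonzero(K[b])[0]:
                    k = int(K[b, s])
                    w_each = float(W[b, s]) / k
                    for _ in range(k):
                        syns.append({"src": int(s), "w": w_each})
                branches.append(syns)
            self.layers.append({
                "branches": branches,
                "n_neurons": wiring.n_neurons,
                "bpn": wiring.branches_per_neuron,
            })

    # -- forward -----------------------------------------------------------

    def _neuron_fires(self, li, inp, branch_fired_out):
        p = self.p
        layer = self.layers[li]
        fires = []
        for n in range(layer["n_neurons"]):
            n_firing = 0
            for bi in range(layer["bpn"]):
                b = n * layer["bpn"] + bi
                pot = 0.0
                for syn in layer["branches"][b]:
                    if inp[syn["src"]]:
                        pot += syn["w"]
                fired = pot >= p.theta_branch[li]
                branch_fired_out[li].append((b, fired))
                if fired:
                    n_firing += 1
            fires.append(n_firing >= p.theta_neuron[li])
        return fires

    def run_window(self, X):
        """Step all timeslots; returns dict of rasters (lists over time)."""
        T = X.shape[0]
        f1_hist, f2_hist, f3_hist = [], [], []
        b_hist = [[], [], []]          # per layer: list over time of branch-fire lists
        prev_f1 = [False] * self.layers[0]["n_neurons"]
        prev_f2 = [False] * self.layers[1]["n_neurons"]
        x_hist, f1d_hist, f2d_hist = [], [], []
        for t in range(T):
            x = [bool(v) for v in X[t]]
            bf = {0: [], 1: [], 2: []}
            f1 = self._neuron_fires(0, x, bf)
            f2 = self._neuron_fires(1, prev_f1, bf)
            f3 = self._neuron_fires(2, prev_f2, bf)
            x_hist.append(x)
            f1d_hist.append(list(prev_f1))
            f2d_hist.append(list(prev_f2))
            f1_hist.append(f1); f2_hist.append(f2); f3_hist.append(f3)
            for li in range(3):
                b_hist[li].append(dict(bf[li]))
            prev_f1, prev_f2 = f1, f2
        self._last = dict(x=x_hist, f1=f1_hist, f2=f2_hist, f3=f3_hist,
                          f1d=f1d_hist, f2d=f2d_hist, b=b_hist)
        return self._last

    # -- plasticity --------------------------------------------------------

    def end_window(self):
        p = self.p
        h = self._last
        T = len(h["x"])
        inputs = {0: h["x"], 1: h["f1d"], 2: h["f2d"]}
        fires = {0: h["f1"], 1: h["f2"], 2: h["f3"]}
        for li in range(3):
            layer = self.layers[li]
            inp = inputs[li]
            fire = fires[li]
            for n in range(layer["n_neurons"]):
                n_fires = sum(1 for t in range(T) if fire[t][n])
                for bi in range(layer["bpn"]):
                    b = n * layer["bpn"] + bi
                    b_fires = [t for t in range(T) if h["b"][li][t][b]]
                    for syn in layer["branches"][b]:
                        s = syn["src"]
                        pairs = 0
                        for t in range(T):
                            if fire[t][n]:
                                active = inp[t][s] or (t > 0 and inp[t - 1][s])
                                if active:
                                    pairs += 1
                        if pairs >= p.pair_min:
                            syn["w"] += p.delta_pot[li]
                        misses = sum(1 for t in b_fires if not inp[t][s])
                        if misses >= p.miss_min[li]:
                            syn["w"] = max(syn["w"] - p.delta_dep[li], 0.0)
                        if n_fires > p.rho_max[li]:
                            syn["w"] *= p.s_homeo
                        syn["w"] = min(syn["w"], p.w_max[li])

    def weight_matrix(self, li, shape):
        """Collapsed (branch, source) weight totals, for comparison."""
        W = np.zeros(shape)
        for b, syns in enumerate(self.layers[li]["branches"]):
            for syn in syns:
                W[b, syn["src"]] += syn["w"]
        return W
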