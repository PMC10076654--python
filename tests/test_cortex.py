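"""Cortex: wiring, integration thresholds, plasticity rules, oracle equality."""

import copy

import numpy as np
import pytest

from recarch.config import CortexParams
from recarch.cortex import (begin_window, end_window_plasticity, init_cortex,
                            load_checkpoint, run_presentation, save_checkpoint,
                            step_timeslot)
from recarch.errors import ConfigError, StateError

from conftest import MICRO_PARAMS, manual_state, presentation_from
from reference import LoopCortex


def micro_groups(n_columns, n_inputs, rng):
    idx = rng.permutation(n_inputs)
    return [g.tolist() for g in np.array_split(idx, n_columns)]


class TestInitCortex:
    def test_default_neuron_counts(self, rng):
        params = CortexParams()
        groups = micro_groups(15, 400, rng)
        state = init_cortex(params, groups, rng)
        assert state.wiring[0].n_neurons == 150
        assert state.wiring[1].n_neurons == 150
        assert state.wiring[2].n_neurons == 15     # one layer-3 neuron per column
        assert params.neurons_per_column * 15 == 315
        # ~1,200 synapses per layer-1 neuron
        per_neuron = state.wiring[0].K.reshape(150, 10, 400).sum(axis=(1, 2))
        assert np.all(per_neuron == 1200)

    def test_unbiased_wiring_is_uniform(self, rng):
        params = CortexParams(n_columns=4, p_bias=0.0)
        state = init_cortex(params, micro_groups(4, 400, rng), rng)
        hist = state.wiring[0].K.sum(axis=0)
        expected = state.wiring[0].K.sum() / 400
        assert hist.min() > 0.5 * expected and hist.max() < 1.5 * expected

    def test_saturated_bias_only_uses_group(self, rng):
        params = CortexParams(n_columns=4, p_bias=1.0)
        groups = micro_groups(4, 400, rng)
        state = init_cortex(params, groups, rng)
        per_col = 10 * 10
        for col, group in enumerate(groups):
            K_col = state.wiring[0].K[col * per_col:(col + 1) * per_col]
            used = np.nonzero(K_col.sum(axis=0))[0]
            assert set(used) <= set(group)

    def test_interlayer_wiring_stays_within_column(self, rng):
        params = CortexParams(n_columns=3)
        state = init_cortex(params, micro_groups(3, 400, rng), rng)
        K2 = state.wiring[1].K
        for col in range(3):
            rows = slice(col * 10 * 2, (col + 1) * 10 * 2)
            outside = np.ones(30, dtype=bool)
            outside[col * 10:(col + 1) * 10] = False
            assert K2[rows][:, outside].sum() == 0

    def test_empty_bias_group_rejected(self, rng):
        params = CortexParams(n_columns=2)
        with pytest.raises(ConfigError):
            init_cortex(params, [[1, 2], []], rng)


class TestThresholdArithmetic:
    def _single_neuron_state(self, theta_branch=2.0, theta_neuron=1):
        params = CortexParams(
            n_columns=1, l1_neurons=1, l1_branches=1, l1_branch_synapses=2,
            l2_neurons=1, l2_branches=1, l2_branch_synapses=1,
            l3_branches=1, l3_branch_synapses=1,
            theta_branch=(theta_branch, 9.0, 9.0),
            theta_neuron=(theta_neuron, 1, 1),
            delta_pot=(0.125, 0.0, 0.0), delta_dep=(0.0625, 0.0, 0.0),
            miss_min=(4, 4, 4), rho_max=(99, 99, 99))
        K1 = np.zeros((1, 4)); K1[0, [0, 1]] = 1
        K2 = np.array([[1]]); K3 = np.array([[1]])
        return manual_state(params, K1, K2, K3, n_inputs=4)

    def test_coincident_inputs_cross_threshold(self):
        state = self._single_neuron_state()
        begin_window(state, 3)
        f1, _, _ = step_timeslot(state, np.array([1, 1, 0, 0]))
        assert f1[0]
        f1, _, _ = step_timeslot(state, np.array([1, 0, 0, 0]))
        assert not f1[0]                            # potential 1 < theta 2
        f1, _, _ = step_timeslot(state, np.array([0, 0, 1, 1]))
        assert not f1[0]                            # unwired inputs

    def test_silent_input_or_zero_weights_never_fire(self):
        state = self._single_neuron_state()
        state.W[0][:] = 0.0
        begin_window(state, 2)
        for x in (np.ones(4, int), np.zeros(4, int)):
            f1, f2, f3 = step_timeslot(state, x)
            assert not (f1.any() or f2.any() or f3.any())

    def test_input_length_validated(self):
        state = self._single_neuron_state()
        begin_window(state, 1)
        with pytest.raises(ConfigError):
            step_timeslot(state, np.zeros(5, int))


class TestPlasticityRules:
    def _state(self, **overrides):
        params = CortexParams(**{**dict(
            n_columns=1, l1_neurons=1, l1_branches=1, l1_branch_synapses=2,
            l2_neurons=1, l2_branches=1, l2_branch_synapses=1,
            l3_branches=1, l3_branch_synapses=1,
            theta_branch=(2.0, 9.0, 9.0), theta_neuron=(1, 1, 1),
            delta_pot=(0.125, 0.0, 0.0), delta_dep=(0.0625, 0.0, 0.0),
            miss_min=(4, 4, 4), rho_max=(99, 99, 99), s_homeo=0.75,
            w_init=(1.0, 1.0, 1.0), w_max=(4.0, 1.0, 1.0)), **overrides})
        K1 = np.zeros((1, 4)); K1[0, [0, 1]] = 1
        return manual_state(params, K1, np.array([[1]]), np.array([[1]]), 4)

    def _drive(self, state, n_pairings, T=12):
        """Make the neuron fire exactly n_pairings times (both inputs on)."""
        X = np.zeros((T, 4), dtype=np.uint8)
        X[:n_pairings, [0]] = 1
        X[:n_pairings, [1]] = 1
        begin_window(state, T)
        for t in range(T):
            step_timeslot(state, X[t])
        end_window_plasticity(state)

    def test_two_pairings_reverse_to_start_weight_exactly(self):
        state = self._state()
        w_start = state.W[0].copy()
        self._drive(state, 2)
        assert np.array_equal(state.W[0], w_start)

    def test_three_pairings_commit_potentiation(self):
        state = self._state()
        self._drive(state, 3)
        assert state.W[0][0, 0] == np.float32(1.0 + 0.125)
        assert state.W[0][0, 1] == np.float32(1.0 + 0.125)

    def test_miss_driven_depression_floors_at_zero(self):
        state = self._state(theta_branch=(1.0, 9.0, 9.0),
                            delta_dep=(2.0, 0.0, 0.0), miss_min=(3, 4, 4),
                            delta_pot=(0.0, 0.0, 0.0))
        X = np.zeros((8, 4), dtype=np.uint8)
        X[:5, 0] = 1                               # input 1 silent while branch fires
        begin_window(state, 8)
        for t in range(8):
            step_timeslot(state, X[t])
        end_window_plasticity(state)
        assert state.W[0][0, 1] == 0.0             # depressed, floored
        assert state.W[0][0, 0] > 0.0

    def test_homeostasis_preserves_weight_ratios(self):
        state = self._state(rho_max=(2, 99, 99), delta_pot=(0.0, 0.0, 0.0),
                            theta_branch=(1.0, 9.0, 9.0), miss_min=(99, 99, 99),
                            l1_branch_synapses=3, w_max=(8.0, 1.0, 1.0))
        K1 = np.zeros((1, 4)); K1[0, [0, 1, 2]] = 1
        state = manual_state(state.params, K1, np.array([[1]]), np.array([[1]]), 4)
        state.W[0][0, [0, 1, 2]] = [2.0, 4.0, 6.0]
        X = np.tile(np.array([1, 1, 1, 0], dtype=np.uint8), (5, 1))
        begin_window(state, 5)
        for t in range(5):
            step_timeslot(state, X[t])
        end_window_plasticity(state)               # fired 5 > rho_max 2
        w = state.W[0][0, [0, 1, 2]]
        assert np.array_equal(w, np.float32(0.75) * np.array([2, 4, 6],
                                                             dtype=np.float32))
        assert w[1] / w[0] == 2.0 and w[2] / w[0] == 3.0

    def test_end_window_mid_window_is_an_error(self):
        state = self._state()
        begin_window(state, 4)
        step_timeslot(state, np.zeros(4, int))
        with pytest.raises(StateError):
            end_window_plasticity(state)


class TestOracleEquivalence:
    """Vectorised simulation must equal the per-synapse loop bit for bit."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_micro_cortex_matches_loop_oracle(self, micro_params, seed):
        rng = np.random.default_rng(seed)
        n_inputs = 30
        groups = micro_groups(micro_params.n_columns, n_inputs, rng)
        state = init_cortex(micro_params, groups, rng, n_inputs=n_inputs)
        oracle = LoopCortex(state)
        T = 60
        X = (rng.random((T, n_inputs)) < 0.35).astype(np.uint8)

        ref = oracle.run_window(X)
        oracle.end_window()

        stepped = copy.deepcopy(state)
        begin_window(stepped, T)
        rasters = [step_timeslot(stepped, X[t]) for t in range(T)]
        end_window_plasticity(stepped)

        for t in range(T):
            assert rasters[t][0].tolist() == ref["f1"][t]
            assert rasters[t][1].tolist() == ref["f2"][t]
            assert rasters[t][2].tolist() == ref["f3"][t]
        for li in range(3):
            ref_W = oracle.weight_matrix(li, stepped.W[li].shape)
            assert np.array_equal(stepped.W[li].astype(np.float64), ref_W)

    def test_run_presentation_equals_stepped_path(self, micro_params, rng):
        n_inputs = 30
        groups = micro_groups(micro_params.n_columns, n_inputs, rng)
        state = init_cortex(micro_params, groups, rng, n_inputs=n_inputs)
        T = 48
        X = (rng.random((T, n_inputs)) < 0.3).astype(np.uint8)
        segments = (np.arange(T) // 8) % 3
        pres = presentation_from(X, labels=(0, 1, 2), segments=segments)

        batched = copy.deepcopy(state)
        counts = run_presentation(batched, pres)

        begin_window(state, T)
        f3s = np.array([step_timeslot(state, X[t])[2] for t in range(T)])
        end_window_plasticity(state)
        lat = micro_params.output_latency
        seg_eff = segments[np.maximum(np.arange(T) - lat, 0)]
        expected = np.stack([f3s[seg_eff == k].sum(axis=0) for k in range(3)],
                            axis=1)
        assert np.array_equal(counts, expected)
        for li in range(3):
            assert np.array_equal(batched.W[li], state.W[li])

    def test_counts_bounded_by_segment_length(self, micro_params, rng):
        n_inputs = 30
        state = init_cortex(micro_params,
                            micro_groups(micro_params.n_columns, n_inputs, rng),
                            rng, n_inputs=n_inputs)
        T = 48
        X = (rng.random((T, n_inputs)) < 0.5).astype(np.uint8)
        segments = (np.arange(T) // 8) % 3
        pres = presentation_from(X, labels=(0, 1, 2), segments=segments)
        counts = run_presentation(state, pres)
        assert np.all(counts >= 0)
        assert np.all(counts <= T)

    def test_weight_bounds_hold_after_many_windows(self, micro_params, rng):
        n_inputs = 30
        state = init_cortex(micro_params,
                            micro_groups(micro_params.n_columns, n_inputs, rng),
                            rng, n_inputs=n_inputs)
        for _ in range(10):
            X = (rng.random((24, n_inputs)) < 0.4).astype(np.uint8)
            run_presentation(state, presentation_from(X))
        for li in range(3):
            K = state.wiring[li].K
            assert np.all(state.W[li] >= 0)
            assert np.all(state.W[li] <= K * micro_params.w_max[li] + 1e-6)
            assert np.all(state.W[li][K == 0] == 0)

    def test_plasticity_continues_during_any_presentation(self, micro_params, rng):
        """Cortical weights keep changing even when no feedback is given."""
        n_inputs = 30
        state = init_cortex(micro_params,
                            micro_groups(micro_params.n_columns, n_inputs, rng),
                            rng, n_inputs=n_inputs)
        before = [W.copy() for W in state.W]
        for _ in range(5):
            X = (rng.random((24, n_inputs)) < 0.5).astype(np.uint8)
            run_presentation(state, presentation_from(X))
        assert any(not np.array_equal(b, w) for b, w in zip(before, state.W))


class TestCheckpoint:
    def test_roundtrip_is_exact(self, micro_params, rng, tmp_path):
        n_inputs = 30
        state = init_cortex(micro_params,
                            micro_groups(micro_params.n_columns, n_inputs, rng),
                            rng, n_inputs=n_inputs)
        X = (rng.random((24, n_inputs)) < 0.4).astype(np.uint8)
        run_presentation(state, presentation_from(X))
        path = tmp_path / "cortex.npz"
        save_checkpoint(state, path)
        back = load_checkpoint(path)
        assert back.clock == state.clock
        assert back.params == state.params
        for li in range(3):
            assert np.array_equal(back.W[li], state.W[li])
            assert np.array_equal(back.wiring[li].K, state.wiring[li].K)

    def test_checkpoint_mid_window_rejected(self, micro_params, rng, tmp_path):
        n_inputs = 30
        state = init_cortex(micro_params,
                            micro_groups(micro_params.n_columns, n_inputs, rng),
                            rng, n_inputs=n_inputs)
        begin_window(state, 4)
        step_timeslot(state, np.zeros(n_inputs, int))
        with pytest.raises(StateError):
            save_checkpoint(state, tmp_path / "x.npz")
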