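"""Unit and property tests of the reservoir dynamics and plasticity rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sornseq import (
    ConfigurationError,
    InputDrive,
    NetworkState,
    SornParams,
    WeightMatrices,
    init_network,
    ip_update,
    sorn_step,
    stdp_update,
    synaptic_normalize,
    update_state,
)


def _all_row_sums_one(weights):
    for w in (weights.w_ee, weights.w_ei, weights.w_ie):
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)


class TestInit:
    def test_row_normalization_and_shapes(self, tiny_net, tiny_params):
        state, weights = tiny_net
        n_e, n_i = tiny_params.n_excitatory, tiny_params.n_inhibitory
        assert weights.w_ee.shape == (n_e, n_e)
        assert weights.w_ei.shape == (n_e, n_i)
        assert weights.w_ie.shape == (n_i, n_e)
        _all_row_sums_one(weights)

    def test_no_self_connections_and_mask_support(self, tiny_net):
        _, weights = tiny_net
        assert not np.diag(weights.ee_mask).any()
        assert not np.diag(weights.w_ee).any()
        assert np.all(weights.w_ee[~weights.ee_mask] == 0)
        assert np.all(weights.w_ee >= 0)
        # every row has at least one synapse (redrawn at init if empty)
        assert weights.ee_mask.any(axis=1).all()

    def test_expected_synapse_count(self):
        params = SornParams(seed=0)
        _, weights = init_network(params, np.random.default_rng(0))
        n = weights.ee_mask.sum()
        expected = params.p_connect * 300 * 299  # ~8970, i.e. ~30 per neuron
        assert abs(n - expected) < 4 * np.sqrt(expected)

    def test_initial_state_silent_and_threshold_ranges(self, tiny_net, tiny_params):
        state, _ = tiny_net
        assert not state.x.any() and not state.y.any()
        assert state.t == 0
        assert np.all((0 <= state.thresholds_e) & (state.thresholds_e <= tiny_params.t_max_e))
        assert np.all((0 <= state.thresholds_i) & (state.thresholds_i <= tiny_params.t_max_i))

    def test_seed_reproducibility(self, tiny_params):
        a = init_network(tiny_params, np.random.default_rng(42))
        b = init_network(tiny_params, np.random.default_rng(42))
        assert np.array_equal(a[1].w_ee, b[1].w_ee)
        assert np.array_equal(a[0].thresholds_e, b[0].thresholds_e)

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            SornParams(p_connect=1.5)
        with pytest.raises(ConfigurationError):
            SornParams(n_excitatory=0)


def _two_unit_setup(thresholds, w=None):
    n = 2
    w_ee = np.array([[0.0, 1.0], [1.0, 0.0]]) if w is None else w
    weights = WeightMatrices(
        w_ee=w_ee,
        ee_mask=w_ee > 0,
        w_ei=np.zeros((n, 1)),
        w_ie=np.zeros((1, n)),
    )
    state = NetworkState(
        x=np.array([1, 0], dtype=np.int8),
        y=np.zeros(1, dtype=np.int8),
        thresholds_e=np.asarray(thresholds, dtype=float),
        thresholds_i=np.array([10.0]),
    )
    return state, weights


class TestUpdateState:
    def test_hand_evaluated_two_unit_network(self):
        # unit 2 receives drive 1 > 0.5, unit 1 receives 0 < 0.5
        state, weights = _two_unit_setup([0.5, 0.5])
        new = update_state(state, weights, InputDrive(np.zeros(2)))
        assert new.x.tolist() == [0, 1]
        assert new.t == 1

    def test_threshold_equality_means_silent(self):
        # drive exactly equal to the threshold: strict inequality keeps it off
        state, weights = _two_unit_setup([0.5, 1.0])
        new = update_state(state, weights, InputDrive(np.zeros(2)))
        assert new.x.tolist() == [0, 0]

    def test_no_drive_no_activity(self):
        state, weights = _two_unit_setup([0.5, 0.5], w=np.zeros((2, 2)))
        state.x[:] = 0
        new = update_state(state, weights, InputDrive(np.zeros(2)))
        assert not new.x.any() and not new.y.any()

    def test_inhibitory_update_uses_new_excitatory_state(self):
        state, weights = _two_unit_setup([0.5, 0.5])
        weights.w_ie = np.array([[0.0, 1.0]])
        state.thresholds_i = np.array([0.5])
        new = update_state(state, weights, InputDrive(np.zeros(2)))
        # x(t) = [1,0] would not drive the inhibitory unit; x(t+1) = [0,1] does
        assert new.x.tolist() == [0, 1]
        assert new.y.tolist() == [1]


class TestStdp:
    def _weights(self, n=3):
        mask = ~np.eye(n, dtype=bool)
        w = np.where(mask, 1.0 / (n - 1), 0.0)
        return WeightMatrices(w, mask, np.zeros((n, 1)), np.zeros((1, n)))

    def test_pre_before_post_potentiates(self):
        w = self._weights()
        x_prev = np.array([0, 1, 0])
        x_now = np.array([1, 0, 0])
        before = w.w_ee.copy()
        stdp_update(w, x_prev, x_now, 1e-4)
        assert w.w_ee[0, 1] == pytest.approx(before[0, 1] + 1e-4)
        assert w.w_ee[1, 0] == pytest.approx(before[1, 0] - 1e-4)

    def test_silent_or_coactive_pairs_unchanged(self):
        w = self._weights()
        before = w.w_ee.copy()
        stdp_update(w, np.zeros(3), np.zeros(3), 1e-4)
        np.testing.assert_array_equal(w.w_ee, before)
        stdp_update(w, np.ones(3), np.ones(3), 1e-4)  # potentiation cancels depression
        np.testing.assert_array_equal(w.w_ee, before)

    def test_masked_entries_untouched_and_clipped_at_zero(self):
        w = self._weights()
        w.w_ee[w.ee_mask] = 1e-5
        stdp_update(w, np.array([1, 0, 0]), np.array([0, 1, 1]), 1e-4)
        assert np.all(w.w_ee >= 0)         # depression clipped
        assert np.all(w.w_ee[~w.ee_mask] == 0)

    @given(st.lists(st.booleans(), min_size=3, max_size=3), st.lists(st.booleans(), min_size=3, max_size=3))
    @settings(deadline=None, max_examples=30)
    def test_antisymmetry_of_raw_update(self, a, b):
        # swapping the two time slices negates the (unclipped) weight change
        xa, xb = np.array(a, dtype=float), np.array(b, dtype=float)
        dw_fwd = np.outer(xb, xa) - np.outer(xa, xb)
        dw_rev = np.outer(xa, xb) - np.outer(xb, xa)
        np.testing.assert_array_equal(dw_fwd, -dw_rev)


class TestNormalization:
    def test_rows_divided_by_sum(self):
        w = WeightMatrices(
            np.array([[0.0, 1.0, 1.0], [2.0, 0.0, 2.0], [0.2, 0.3, 0.0]]),
            np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=bool),
            np.zeros((3, 1)),
            np.zeros((1, 3)),
        )
        synaptic_normalize(w)
        np.testing.assert_allclose(w.w_ee.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(w.w_ee[1], [0.5, 0.0, 0.5])

    def test_zero_row_left_unchanged_with_warning(self):
        w = WeightMatrices(
            np.array([[0.0, 0.0], [1.0, 0.0]]),
            np.array([[0, 1], [1, 0]], dtype=bool),
            np.zeros((2, 1)),
            np.zeros((1, 2)),
        )
        with pytest.warns(RuntimeWarning):
            synaptic_normalize(w)
        assert w.w_ee[0].tolist() == [0.0, 0.0]
        assert w.w_ee[1].tolist() == [1.0, 0.0]


class TestIntrinsicPlasticity:
    def test_direct_evaluation(self):
        t = np.array([0.5, 0.5])
        out = ip_update(t, np.array([1, 0]), eta_ip=0.002, h_ip=0.1)
        np.testing.assert_allclose(out, [0.5018, 0.4998])

    def test_zero_rate_is_identity(self):
        t = np.array([0.3, -0.2, 1.4])
        np.testing.assert_array_equal(ip_update(t, np.array([1, 0, 1]), 0.0, 0.1), t)


class TestSornStep:
    def test_unknown_flag_rejected(self, tiny_net, tiny_params):
        state, weights = tiny_net
        with pytest.raises(ConfigurationError):
            sorn_step(state, weights, InputDrive(np.zeros(20)), tiny_params, plasticity=("hebb",))

    def test_all_flags_off_freezes_weights_and_thresholds(self, tiny_net, tiny_params, rng):
        state, weights = tiny_net
        w0 = weights.w_ee.copy()
        t0 = state.thresholds_e.copy()
        drive = np.zeros(20)
        drive[:2] = 1.0
        for _ in range(200):
            state, weights = sorn_step(state, weights, InputDrive(drive), tiny_params, plasticity=())
        np.testing.assert_array_equal(weights.w_ee, w0)
        np.testing.assert_array_equal(state.thresholds_e, t0)

    def test_row_sums_conserved_every_step(self, tiny_net, tiny_params):
        state, weights = tiny_net
        drive = np.zeros(20)
        drive[:4] = 1.0
        for _ in range(300):
            state, weights = sorn_step(state, weights, InputDrive(drive), tiny_params)
            sums = weights.w_ee.sum(axis=1)
            ok = sums > 0
            np.testing.assert_allclose(sums[ok], 1.0, atol=1e-9)
            assert np.isin(state.x, (0, 1)).all() and np.isin(state.y, (0, 1)).all()

    def test_mask_never_changes(self, tiny_net, tiny_params):
        state, weights = tiny_net
        m0 = weights.ee_mask.copy()
        drive = np.zeros(20)
        drive[5:9] = 1.0
        for _ in range(200):
            state, weights = sorn_step(state, weights, InputDrive(drive), tiny_params)
        np.testing.assert_array_equal(weights.ee_mask, m0)

    def test_ip_drives_firing_rate_to_target(self):
        # homeostatic fixed point: long-run empirical rate within 0.02 of h_ip
        params = SornParams(n_excitatory=60, n_inhibitory=12, n_input_per_symbol=5, seed=5)
        rng = np.random.default_rng(5)
        state, weights = init_network(params, rng)
        drives = []
        for start in (0, 5, 10):
            v = np.zeros(60)
            v[start : start + 5] = 1.0
            drives.append(v)
        n_steps = 50_000
        counts = np.zeros(60)
        for t in range(n_steps):
            state, weights = sorn_step(
                state, weights, InputDrive(drives[t % 3]), params
            )
            counts += state.x
        rates = counts / n_steps
        assert np.all(np.abs(rates - params.h_ip) < 0.02)
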