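"""Oracle and property tests of the analysis statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import entropy

from sornseq.metrics import (
    ActivityRecord,
    WeightTrajectory,
    cluster_activity,
    direction_change,
    firing_rates_by_condition,
    joint_probability,
    mutual_information,
    pca_states,
    pca_weight_trajectories,
    selectivity_index,
    separability,
    separability_per_word,
    weight_distance_series,
)


def _record(states, positions=None, input_units=()):
    states = np.asarray(states, dtype=np.int8)
    n = states.shape[0]
    if positions is None:
        positions = np.arange(n) % 4
    positions = np.asarray(positions)
    return ActivityRecord(
        states=states,
        symbols=positions.astype(str),
        positions=positions,
        words=np.arange(n) // 4,
        tasks=np.array(["S1"] * n),
        input_units=np.asarray(input_units, dtype=int),
    )


class TestSeparability:
    def test_identical_states_zero(self):
        rec = _record(np.ones((6, 5)))
        assert separability(rec, 0, 6) == 0.0

    def test_alternating_orthogonal_one_hot(self):
        # window of 2 alternating one-hot states: 2 ordered pairs at distance sqrt(2)
        rec = _record([[1, 0], [0, 1]])
        assert separability(rec, 0, 2) == pytest.approx(2 * np.sqrt(2))

    def test_brute_force_oracle_on_random_records(self, rng):
        for _ in range(20):
            states = (rng.random((30, 12)) < 0.3).astype(np.int8)
            rec = _record(states)
            t, window = int(rng.integers(0, 10)), 20
            got = separability(rec, t, window, exclude_input_units=False)
            brute = 0.0
            for n in range(window):
                for m in range(window):
                    brute += np.linalg.norm(
                        states[t + n].astype(float) - states[t + m].astype(float)
                    )
            assert got == pytest.approx(brute)

    def test_input_units_excluded_by_default(self, rng):
        states = (rng.random((8, 6)) < 0.5).astype(np.int8)
        rec = _record(states, input_units=[0, 1])
        manual = _record(states[:, 2:])
        assert separability(rec, 0, 8) == pytest.approx(separability(manual, 0, 8))

    def test_window_beyond_record_rejected(self):
        with pytest.raises(ValueError):
            separability(_record(np.zeros((5, 3))), 0, 6)

    def test_per_word_windows(self, rng):
        states = (rng.random((12, 5)) < 0.4).astype(np.int8)
        rec = _record(states)
        vals = separability_per_word(rec, 4)
        assert len(vals) == 3
        assert vals[1] == pytest.approx(separability(rec, 4, 4))


class TestPcaStates:
    def test_rank_one_record(self):
        base = np.array([1, 1, 0, 0, 1], dtype=np.int8)
        states = np.array([base * k for k in (0, 1, 0, 1, 1, 0)], dtype=np.int8)
        _, evr, _ = pca_states(_record(states), n_components=2)
        assert evr[0] == pytest.approx(1.0)

    def test_explained_variance_properties_and_eigh_oracle(self, rng):
        states = (rng.random((40, 8)) < 0.4).astype(np.int8)
        comps, evr, coords = pca_states(_record(states), n_components=3)
        assert evr.sum() <= 1 + 1e-12
        assert np.all(np.diff(evr) <= 1e-12)
        X = states - states.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        np.testing.assert_allclose(evr, eigvals[:3] / eigvals.sum(), atol=1e-10)


class TestClustering:
    def test_perfectly_separated_duplicates(self, rng):
        protos = (rng.random((20, 15)) < 0.5).astype(np.int8)
        states = np.repeat(protos, 5, axis=0)
        positions = np.repeat(np.arange(20), 5)
        rec = _record(states, positions=positions)
        report = cluster_activity(rec, n_clusters=20, condition="position")
        assert report.mean_conditions_per_cluster == 1.0
        assert report.mean_dominant_share == 100.0

    def test_histogram_conservation(self, rng):
        states = (rng.random((60, 10)) < 0.4).astype(np.int8)
        rec = _record(states)
        report = cluster_activity(rec, n_clusters=5, condition="position")
        assert sum(sum(h.values()) for h in report.histograms) == 60

    def test_fewer_rows_than_clusters_rejected(self, rng):
        rec = _record((rng.random((4, 5)) < 0.5).astype(np.int8))
        with pytest.raises(ValueError):
            cluster_activity(rec, n_clusters=10)


class TestSelectivity:
    def test_boundary_cases(self):
        assert selectivity_index(np.full(6, 2.0)) == pytest.approx(0.0)
        one = np.zeros(6)
        one[2] = 1.3
        assert selectivity_index(one) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        assert selectivity_index(np.array([4.0, 2.0, 1.0, 1.0])) == pytest.approx(2 / 3)

    def test_all_zero_rates_flagged(self):
        assert np.isnan(selectivity_index(np.zeros(4)))

    @given(st.lists(st.floats(min_value=0, max_value=10), min_size=2, max_size=8))
    @settings(deadline=None, max_examples=50)
    def test_bounded_for_nonnegative_rates(self, rates):
        rates = np.array(rates)
        if rates.max() <= 0:
            return
        d = selectivity_index(rates)
        assert -1e-9 <= d <= 1 + 1e-9


class TestJointAndMutualInformation:
    def test_joint_probability_completeness(self, rng):
        states = (rng.random((40, 6)) < 0.4).astype(np.int8)
        rec = _record(states)
        joint, values = joint_probability(rec)
        _, counts = np.unique(rec.positions.astype(str), return_counts=True)
        p_s = counts / len(rec)
        # fire-joint plus silent-joint sums to one per neuron
        total = joint.sum(axis=1) + (p_s[None, :] - joint).sum(axis=1)
        np.testing.assert_allclose(total, 1.0)

    def test_always_firing_neuron_matches_marginals(self):
        states = np.ones((12, 2), dtype=np.int8)
        rec = _record(states)
        joint, _ = joint_probability(rec)
        np.testing.assert_allclose(joint[0], 0.25)
        silent = np.zeros((12, 1), dtype=np.int8)
        joint0, _ = joint_probability(_record(silent))
        np.testing.assert_allclose(joint0, 0.0)

    def test_independence_gives_zero_and_locked_neuron_one_bit(self):
        # two equiprobable positions; neuron 0 fires iff position 0; neuron 1 always
        positions = np.array([0, 1] * 50)
        states = np.stack([(positions == 0), np.ones(100, bool)], axis=1).astype(np.int8)
        rec = _record(states, positions=positions)
        mi = mutual_information(rec, base=2)
        assert mi[0] == pytest.approx(1.0)
        assert mi[1] == pytest.approx(0.0)

    def test_nonnegative_and_scipy_oracle(self, rng):
        states = (rng.random((60, 5)) < 0.3).astype(np.int8)
        rec = _record(states)
        mi = mutual_information(rec, base=np.e)
        assert np.all(mi >= -1e-12)
        # oracle: entropy identity I(R;S) = H(R) + H(S) - H(R,S) from counts
        conds = rec.positions
        for i in range(5):
            counts = np.zeros((2, 4))
            for r, s in zip(states[:, i], conds):
                counts[r, s] += 1
            p = counts / counts.sum()
            oracle = (
                entropy(p.sum(axis=1)) + entropy(p.sum(axis=0)) - entropy(p.ravel())
            )
            assert mi[i] == pytest.approx(oracle, abs=1e-10)

    def test_rate_based_marginal_identity(self, rng):
        # overall firing probability equals (spikes per word) / word length
        states = (rng.random((80, 4)) < 0.25).astype(np.int8)
        rec = _record(states)
        n_words, l_word = 20, 4
        p_fire = states.sum(axis=0) / len(rec)
        np.testing.assert_allclose(p_fire, (states.sum(axis=0) / n_words) / l_word)


class TestWeightTrajectories:
    def _traj(self, rng, n_snap=5, n=6):
        snaps = {0: rng.random((n, n))}
        for k in range(1, n_snap):
            snaps[k * 100] = snaps[(k - 1) * 100] + 0.01 * rng.random((n, n))
        return WeightTrajectory.from_dict(snaps)

    def test_distance_series(self, rng):
        traj = self._traj(rng)
        d = weight_distance_series(traj)
        np.testing.assert_array_equal(d[0], 0.0)
        w = traj.snapshots[0].copy()
        w[2, 3] += 0.3
        traj2 = WeightTrajectory.from_dict({0: traj.snapshots[0], 1: w})
        d2 = weight_distance_series(traj2)
        assert d2[1, 2] == pytest.approx(0.3)
        assert d2[1, 0] == 0.0

    def test_static_weights_zero_distance(self, rng):
        w = rng.random((4, 4))
        traj = WeightTrajectory.from_dict({0: w, 10: w.copy(), 20: w.copy()})
        assert weight_distance_series(traj).max() == 0.0

    def test_direction_change_hand_cases(self):
        n = 2
        w0 = np.zeros((3, n))
        u = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 0.0]])
        v = np.array([[1.0, 0.0], [-1.0, 0.0], [1.0, 1.0]])
        traj = WeightTrajectory.from_dict({0: w0, 100: w0 + u, 200: w0 + u + v})
        ang = direction_change(traj, 100, 100)
        assert ang[0] == pytest.approx(0.0)
        assert ang[1] == pytest.approx(180.0)
        assert np.isnan(ang[2])  # zero displacement before the switch -> excluded

    def test_forty_five_degrees(self):
        w0 = np.zeros((1, 2))
        u = np.array([[1.0, 0.0]])
        v = np.array([[1.0, 1.0]]) / np.sqrt(2)
        traj = WeightTrajectory.from_dict({0: w0, 1: u, 2: u + v})
        assert direction_change(traj, 1, 1)[0] == pytest.approx(45.0)

    def test_angle_invariances(self, rng):
        u = rng.normal(size=(5, 8))
        v = rng.normal(size=(5, 8))
        t1 = WeightTrajectory.from_dict({0: np.zeros((5, 8)), 1: u, 2: u + v})
        t2 = WeightTrajectory.from_dict({0: np.zeros((5, 8)), 1: v, 2: v + u})
        np.testing.assert_allclose(direction_change(t1, 1, 1), direction_change(t2, 1, 1))
        t3 = WeightTrajectory.from_dict({0: np.zeros((5, 8)), 1: 2 * u, 2: 2 * u + 0.5 * v})
        np.testing.assert_allclose(direction_change(t1, 1, 1), direction_change(t3, 1, 1))

    def test_missing_snapshot_rejected(self, rng):
        traj = self._traj(rng)
        with pytest.raises(KeyError):
            direction_change(traj, 100, 77)

    def test_pca_weight_trajectories_shapes(self, rng):
        traj = self._traj(rng, n_snap=6, n=8)
        proj, evr = pca_weight_trajectories(traj, n_components=3)
        assert proj.shape == (6, 8, 3)
        assert np.all(np.diff(evr) <= 1e-12)
        w = rng.random((4, 4))
        static = WeightTrajectory.from_dict({0: w, 1: w.copy(), 2: w.copy()})
        proj_s, _ = pca_weight_trajectories(static, n_components=2)
        assert np.allclose(proj_s.std(axis=0), 0.0)

    def test_center_on_initial_anchors_origin(self, rng):
        traj = self._traj(rng)
        proj, _ = pca_weight_trajectories(traj, n_components=2, center_on_initial=True)
        first = pca_weight_trajectories(traj, 2, True)[0][0]
        # all neurons' initial snapshots coincide at a single point (the origin
        # of the centered weight displacement space, up to the shared PCA mean)
        assert np.allclose(first.std(axis=0), 0.0, atol=1e-9)
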