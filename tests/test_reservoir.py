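"""Reservoir: construction, LIF dynamics, STDP, cluster analysis."""

import numpy as np
import pytest

from spikevalence.encoding import N_TIME_STEPS
from spikevalence.reservoir import (
    ReservoirParams,
    build_reservoir,
    propagate,
    spike_communication_clusters,
    stdp_delta,
    train_unsupervised,
)
from spikevalence.synth import FACIAL_FEATURES

from conftest import make_net, naive_lif_reference


@pytest.fixture(scope="module")
def default_net():
    return build_reservoir(ReservoirParams(seed=11))


class TestConstruction:
    def test_847_neurons_80_inputs(self, default_net):
        assert default_net.n_neurons == 11 * 11 * 7 == 847
        assert default_net.input_map.size == 80
        assert np.unique(default_net.input_map).size == 80

    def test_grid_spans_stated_extent(self, default_net):
        c = default_net.coordinates
        assert c[:, 0].min() == -50 and c[:, 0].max() == 50
        assert c[:, 2].min() == -30 and c[:, 2].max() == 30

    def test_input_lines_sit_on_the_three_layers(self, default_net):
        z = default_net.coordinates[default_net.input_map, 2]
        # 5 facial lines at z=-30, 5 at z=+30, 6 peripheral at z=0
        assert (z == -30).sum() == 25
        assert (z == 30).sum() == 25
        assert (z == 0).sum() == 30
        # within each line the five neurons are adjacent along x
        for f in range(16):
            line = default_net.coordinates[default_net.input_map[5 * f : 5 * f + 5]]
            assert np.all(np.diff(line[:, 0]) == 10)
            assert np.unique(line[:, 1]).size == 1

    def test_exact_excitatory_fraction_among_recurrent_edges(self, default_net):
        w = default_net.weights[~default_net.is_input_edge]
        n_pos = (w > 0).sum()
        assert n_pos == round(0.8 * w.size)

    def test_input_edges_positive_and_doubled_scale(self, default_net):
        w_in = default_net.weights[default_net.is_input_edge]
        assert np.all(w_in > 0)
        # |w| = mult * u / d <= 2 * 1 / 10
        assert w_in.max() <= 2.0 / 10.0 + 1e-12

    def test_all_connections_within_radius_no_self_loops(self, default_net):
        c = default_net.coordinates
        d = np.linalg.norm(c[default_net.pre] - c[default_net.post], axis=1)
        assert np.all(d <= 25.0 + 1e-9)
        assert np.all(default_net.pre != default_net.post)
        pairs = set(zip(default_net.pre.tolist(), default_net.post.tolist()))
        assert len(pairs) == default_net.n_edges  # one edge per ordered pair

    def test_zero_radius_gives_no_connections(self):
        net = build_reservoir(ReservoirParams(small_world_radius=0.0, seed=1))
        assert net.n_edges == 0

    def test_deterministic_given_seed(self):
        a = build_reservoir(ReservoirParams(seed=3))
        b = build_reservoir(ReservoirParams(seed=3))
        np.testing.assert_array_equal(a.pre, b.pre)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_modality_subset_reduces_input_lines(self):
        net = build_reservoir(ReservoirParams(seed=2), features=FACIAL_FEATURES)
        assert net.input_map.size == 50
        assert net.n_neurons == 847

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="excitatory"):
            ReservoirParams(excitatory_fraction=1.2)
        with pytest.raises(ValueError, match="threshold"):
            ReservoirParams(firing_threshold=0.0)


class TestLifDynamics:
    def test_single_suprathreshold_edge_fires_next_step(self):
        net = make_net(2, [0], [(0, 1, 0.6)])
        raster = np.zeros((1, N_TIME_STEPS), dtype=np.uint8)
        raster[0, 1] = 1
        rec = propagate(net, raster)
        # spike emitted at step 1 arrives at step 2; 0.6 >= theta=0.5
        assert rec.fired[1, 2]
        assert rec.fired[1].sum() == 1

    def test_zero_input_keeps_reservoir_silent(self):
        net = make_net(3, [0], [(0, 1, 0.6), (1, 2, 0.7)])
        rec = propagate(net, np.zeros((1, N_TIME_STEPS), dtype=np.uint8))
        assert rec.fired.sum() == 0
        assert rec.transmitted.sum() == 0

    def test_hand_stepped_trace_with_textbook_parameters(self):
        # three synapses of weight 0.1, 0.1, 0.35 onto one neuron;
        # threshold 0.5, leak 0.02 per step, refractory 3 steps
        params = ReservoirParams(
            firing_threshold=0.5, leak_per_step=0.02, refractory_steps=3
        )
        weights = [0.1, 0.1, 0.35]
        net = make_net(4, [0, 1, 2], [(0, 3, 0.1), (1, 3, 0.1), (2, 3, 0.35)],
                       params)
        T = 40
        raster = np.zeros((3, T), dtype=np.uint8)
        raster[0, [1, 3, 5, 7, 9, 11, 15, 19]] = 1
        raster[1, [2, 4, 6, 8, 10, 14, 18]] = 1
        raster[2, [5, 9, 13, 17, 21]] = 1

        # independent hand-stepped oracle for the postsynaptic neuron
        psp, refr = 0.0, 0
        psp_trace, fire_steps = [], []
        for t in range(T):
            arriving = sum(
                w for k, w in enumerate(weights) if t >= 1 and raster[k, t - 1]
            )
            if refr > 0:
                refr -= 1
            else:
                psp = max(0.0, psp - 0.02) + arriving
                if psp >= 0.5:
                    fire_steps.append(t)
                    psp = 0.0
                    refr = 3
            psp_trace.append(psp)

        rec = propagate(net, raster)
        assert list(np.nonzero(rec.fired[3])[0]) == fire_steps
        assert len(fire_steps) >= 2  # scenario actually exercises firing

    def test_refractory_blocks_consecutive_firing(self, default_net):
        rng = np.random.default_rng(0)
        raster = (rng.random((80, N_TIME_STEPS)) < 0.5).astype(np.uint8)
        rec = propagate(default_net, raster)
        non_input = np.setdiff1d(np.arange(847), default_net.input_map)
        consecutive = rec.fired[non_input, 1:] & rec.fired[non_input, :-1]
        assert not consecutive.any()

    def test_transmitted_counts_equal_presynaptic_firings(self):
        net = make_net(3, [0], [(0, 1, 0.6), (0, 2, 0.01), (1, 2, 0.2)])
        raster = np.zeros((1, N_TIME_STEPS), dtype=np.uint8)
        raster[0, 1::2] = 1
        rec = propagate(net, raster)
        fires = rec.fired
        for e in range(net.n_edges):
            assert rec.transmitted[e] == fires[net.pre[e], :-1].sum() + (
                # a spike on the last step never travels
                0
            )

    @pytest.mark.parametrize("trial", range(20))
    def test_vectorized_matches_naive_reference(self, trial):
        """Spike-for-spike equality with a per-neuron Python reference."""
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(5, 21))
        n_inputs = int(rng.integers(1, max(2, n // 2)))
        inputs = rng.choice(n, size=n_inputs, replace=False).tolist()
        edges = []
        for a in range(n):
            for b in range(n):
                if a != b and rng.random() < 0.3:
                    edges.append((a, b, float(rng.uniform(-0.5, 0.8))))
        params = ReservoirParams(
            firing_threshold=float(rng.uniform(0.2, 0.8)),
            leak_per_step=float(rng.uniform(0.0, 0.05)),
            refractory_steps=int(rng.integers(0, 4)),
        )
        net = make_net(n, inputs, edges, params)
        raster = (rng.random((n_inputs, 200)) < 0.15).astype(np.uint8)
        rec = propagate(net, raster)
        ref = naive_lif_reference(net, raster)
        np.testing.assert_array_equal(rec.fired, ref)


class TestStdp:
    @pytest.mark.parametrize(
        "dt, expected",
        [(1, 0.0005), (0, 0.0), (-9, -0.0001), (2, 0.001 / 3)],
    )
    def test_formula_arithmetic(self, dt, expected):
        assert stdp_delta(dt, 0.001) == pytest.approx(expected)

    def test_antisymmetry_and_strict_decay(self):
        dts = np.arange(1, 51)
        pos = stdp_delta(dts, 0.001)
        neg = stdp_delta(-dts, 0.001)
        np.testing.assert_allclose(pos, -neg)
        assert np.all(np.diff(np.abs(pos)) < 0)
        assert np.all(np.abs(pos) <= 0.001)

    def test_causal_chain_updates_single_edge(self):
        # pre (input) fires at step 3, post (input) at step 5: dt = 2
        params = ReservoirParams(stdp_learning_rate=0.001)
        net = make_net(3, [0, 1], [(0, 1, 0.05), (0, 2, 0.05)], params)
        w0 = net.weights.copy()
        raster = np.zeros((2, N_TIME_STEPS), dtype=np.uint8)
        raster[0, 3] = 1
        raster[1, 5] = 1
        propagate(net, raster, plasticity=True)
        assert net.weights[0] - w0[0] == pytest.approx(0.001 / 3)  # +LR/3
        assert net.weights[1] == w0[1]  # neuron 2 never fired

    def test_anticausal_order_depresses(self):
        params = ReservoirParams(stdp_learning_rate=0.001)
        net = make_net(2, [0, 1], [(0, 1, 0.05)], params)
        w0 = net.weights.copy()
        raster = np.zeros((2, N_TIME_STEPS), dtype=np.uint8)
        raster[1, 3] = 1  # post first
        raster[0, 5] = 1  # pre later: dt = -2
        propagate(net, raster, plasticity=True)
        assert net.weights[0] - w0[0] == pytest.approx(-0.001 / 3)

    def test_empty_rasters_leave_weights_unchanged(self, default_net):
        net = default_net.copy()
        w0 = net.weights.copy()
        train_unsupervised(net, np.zeros((3, 80, N_TIME_STEPS), dtype=np.uint8))
        np.testing.assert_array_equal(net.weights, w0)

    def test_per_update_bound_and_radius_preserved_after_training(
        self, default_net, small_dataset
    ):
        from spikevalence.encoding import QuantilePopulationEncoder, trials_to_array

        net = default_net.copy()
        w0 = net.weights.copy()
        enc = QuantilePopulationEncoder().fit(small_dataset)
        rasters = enc.transform(trials_to_array(small_dataset))
        train_unsupervised(net, rasters[:4])
        assert net.trained
        assert not np.array_equal(net.weights, w0)  # learning happened
        # geometry untouched by training
        c = net.coordinates
        d = np.linalg.norm(c[net.pre] - c[net.post], axis=1)
        assert np.all(d <= 25.0 + 1e-9)


class TestClusters:
    def test_no_activity_leaves_each_input_alone_in_its_cluster(self, default_net):
        net = default_net.copy()
        net.trained = True
        sizes, owner = spike_communication_clusters(
            net, np.zeros((2, 80, N_TIME_STEPS), dtype=np.uint8)
        )
        assert np.all(sizes == 1)
        # everything else is unassigned; assigned + unassigned partition 847
        assert (owner >= 0).sum() + (owner < 0).sum() == 847
        assert (owner >= 0).sum() == 80

    def test_assignment_partitions_the_reservoir(self, default_net, small_dataset):
        from spikevalence.encoding import QuantilePopulationEncoder, trials_to_array

        net = default_net.copy()
        enc = QuantilePopulationEncoder().fit(small_dataset)
        rasters = enc.transform(trials_to_array(small_dataset))
        train_unsupervised(net, rasters)
        sizes, owner = spike_communication_clusters(net, rasters)
        assert sizes.sum() == (owner >= 0).sum()
        assert sizes.sum() + (owner < 0).sum() == 847
        # each input owns itself
        for k, g in enumerate(net.input_map):
            assert owner[g] == k

    def test_untrained_net_warns(self, default_net):
        net = default_net.copy()
        net.trained = False
        with pytest.warns(UserWarning, match="untrained"):
            spike_communication_clusters(
                net, np.zeros((1, 80, N_TIME_STEPS), dtype=np.uint8)
            )


class TestDeterminism:
    def test_identical_seed_and_inputs_reproduce_record_and_weights(
        self, small_dataset
    ):
        from spikevalence.encoding import QuantilePopulationEncoder, trials_to_array

        enc = QuantilePopulationEncoder().fit(small_dataset)
        rasters = enc.transform(trials_to_array(small_dataset))
        results = []
        for _ in range(2):
            net = build_reservoir(ReservoirParams(seed=21))
            train_unsupervised(net, rasters[:3])
            rec = propagate(net, rasters[3])
            results.append((net.weights.copy(), rec.fired.copy()))
        np.testing.assert_array_equal(results[0][0], results[1][0])
        np.testing.assert_array_equal(results[0][1], results[1][1])
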