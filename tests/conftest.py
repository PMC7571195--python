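"""Shared fixtures and independent reference oracles.

The reference LIF simulator here is a deliberately naive per-neuron,
per-edge Python loop, kept independent of the package's vectorized
implementation so the two can be compared spike for spike.
"""

from __future__ import annotations

import numpy as np
import pytest

from spikevalence.reservoir import ReservoirNet, ReservoirParams
from spikevalence.synth import SynthConfig, generate_dataset


def make_net(
    n_neurons: int,
    inputs: list[int],
    edges: list[tuple[int, int, float]],
    params: ReservoirParams | None = None,
) -> ReservoirNet:
    """Hand-build a reservoir net with explicit neurons and weighted edges."""
    params = params or ReservoirParams()
    coords = np.zeros((n_neurons, 3))
    coords[:, 0] = np.arange(n_neurons)
    if edges:
        pre = np.array([e[0] for e in edges], dtype=np.int64)
        post = np.array([e[1] for e in edges], dtype=np.int64)
        w = np.array([e[2] for e in edges], dtype=float)
    else:
        pre = post = np.empty(0, dtype=np.int64)
        w = np.empty(0)
    return ReservoirNet(
        coordinates=coords,
        input_map=np.asarray(inputs, dtype=np.int64),
        pre=pre,
        post=post,
        weights=w,
        is_input_edge=np.isin(pre, inputs),
        params=params,
        features=(),
        trained=True,
    )


def naive_lif_reference(
    net: ReservoirNet, raster: np.ndarray
) -> np.ndarray:
    """Per-neuron, per-edge pure-Python LIF simulation (reference oracle).

    Same contract as ``propagate`` with plasticity off: input neurons fire
    exactly their raster rows; spikes take one step per edge; non-refractory
    neurons leak (floored at zero), integrate, and fire at threshold;
    refractory neurons ignore input and count down. Returns the (N, T)
    boolean firing history.
    """
    p = net.params
    n = net.n_neurons
    horizon = raster.shape[1]
    inputs = set(int(i) for i in net.input_map)
    input_row = {int(g): r for r, g in enumerate(net.input_map)}
    psp = [0.0] * n
    refr = [0] * n
    fired_hist = np.zeros((n, horizon), dtype=bool)
    fired_prev = [False] * n
    for t in range(horizon):
        arriving = [0.0] * n
        for e in range(net.n_edges):
            if fired_prev[net.pre[e]]:
                arriving[net.post[e]] += net.weights[e]
        fired = [False] * n
        for i in range(n):
            if i in inputs:
                fired[i] = raster[input_row[i], t] > 0
                psp[i] = 0.0
                refr[i] = 0
                continue
            if refr[i] > 0:
                refr[i] -= 1
                continue
            psp[i] = max(0.0, psp[i] - p.leak_per_step) + arriving[i]
            if psp[i] >= p.firing_threshold:
                fired[i] = True
                psp[i] = 0.0
                refr[i] = p.refractory_steps
        for i in range(n):
            fired_hist[i, t] = fired[i]
        fired_prev = fired
    return fired_hist


@pytest.fixture(scope="session")
def small_dataset():
    """3 subjects x 4 trials with a clear class effect."""
    cfg = SynthConfig(
        n_subjects=3, trials_per_subject=4, effect_size=2.0, seed=7
    )
    return generate_dataset(cfg)
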