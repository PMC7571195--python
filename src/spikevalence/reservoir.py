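"""3D spiking reservoir: construction, LIF dynamics, STDP, cluster analysis.

The reservoir is an 11x11x7 grid of leaky integrate-and-fire neurons at
spacing 10 (x, y in [-50, 50], z in [-30, 30]). Input neurons are laid out
as 16 lines of five adjacent neurons — one line per feature, neurons n1..n5
coding ascending value ranges — on three layers: facial features at
z = -30 and z = +30, peripheral features at z = 0. Connectivity is
small-world: candidate pairs within radius r are wired with probability
decreasing in distance, one random direction each; initial weights are
u/d (u uniform, d Euclidean distance), with exactly 80% of recurrent edges
excitatory; edges leaving input neurons are always positive and doubled.

Unsupervised training is online nearest-spike STDP:
``dw = sgn(dt) * LR / (|dt| + 1)`` with ``dt = t_post - t_pre``.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._rng import substream
from .encoding import N_TIME_STEPS, NEURONS_PER_FEATURE
from .synth import FEATURE_NAMES

__all__ = [
    "ReservoirParams",
    "ReservoirNet",
    "SpikeRecord",
    "build_reservoir",
    "default_input_layout",
    "lif_step",
    "propagate",
    "stdp_delta",
    "train_unsupervised",
    "spike_communication_clusters",
]


@dataclass(frozen=True)
class ReservoirParams:
    """Reservoir geometry, neuron model and plasticity parameters.

    Units: distances in grid units (spacing 10 between neighbours);
    potentials in threshold units; one simulation step per encoder time step.
    """

    grid_dims: tuple[int, int, int] = (11, 11, 7)
    grid_spacing: float = 10.0
    small_world_radius: float = 25.0
    excitatory_fraction: float = 0.80
    input_weight_multiplier: float = 2.0
    connect_prob_scale: float = 0.30
    firing_threshold: float = 0.5
    leak_per_step: float = 0.002
    refractory_steps: int = 1
    stdp_learning_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_dims) != 3 or any(d < 1 for d in self.grid_dims):
            raise ValueError(f"grid_dims must be 3 positive ints, got {self.grid_dims}")
        if not 0.0 <= self.excitatory_fraction <= 1.0:
            raise ValueError("excitatory_fraction must lie in [0, 1]")
        if not 0.0 <= self.connect_prob_scale <= 1.0:
            raise ValueError("connect_prob_scale must lie in [0, 1]")
        if self.firing_threshold <= 0:
            raise ValueError("firing_threshold must be positive")
        if self.small_world_radius < 0:
            raise ValueError("small_world_radius must be >= 0")
        if self.refractory_steps < 0:
            raise ValueError("refractory_steps must be >= 0")


@dataclass
class ReservoirNet:
    """A built (and possibly STDP-trained) reservoir."""

    coordinates: np.ndarray          # (N, 3)
    input_map: np.ndarray            # (n_inputs,) grid-neuron indices
    pre: np.ndarray                  # (E,)
    post: np.ndarray                 # (E,)
    weights: np.ndarray              # (E,)
    is_input_edge: np.ndarray        # (E,) bool: presynaptic neuron is an input
    params: ReservoirParams
    features: tuple = FEATURE_NAMES  # feature names behind the input lines
    trained: bool = False

    @property
    def n_neurons(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_edges(self) -> int:
        return self.pre.shape[0]

    def copy(self) -> "ReservoirNet":
        return replace(self, weights=self.weights.copy())


@dataclass
class SpikeRecord:
    """Firing history of one or more propagations."""

    fired: np.ndarray        # (N, T) bool
    transmitted: np.ndarray  # (E,) spikes sent along each connection

    @property
    def first_spike_step(self) -> np.ndarray:
        """Per neuron: first firing step, or -1 if it never fired."""
        any_fire = self.fired.any(axis=1)
        first = np.argmax(self.fired, axis=1)
        return np.where(any_fire, first, -1)

    @property
    def spike_counts(self) -> np.ndarray:
        return self.fired.sum(axis=1)


def _grid_coordinates(params: ReservoirParams) -> tuple[np.ndarray, dict]:
    nx, ny, nz = params.grid_dims
    s = params.grid_spacing
    xs = (np.arange(nx) - (nx - 1) / 2) * s
    ys = (np.arange(ny) - (ny - 1) / 2) * s
    zs = (np.arange(nz) - (nz - 1) / 2) * s
    coords = np.array([(x, y, z) for z in zs for y in ys for x in xs])
    index = {tuple(np.round(c, 6)): i for i, c in enumerate(coords)}
    return coords, index


def default_input_layout(
    features: Sequence[str] = FEATURE_NAMES,
) -> dict[str, list[tuple[float, float, float]]]:
    """Grid coordinates of each feature's five-neuron input line (n1..n5).

    Facial features occupy the z = -30 and z = +30 layers (five lines each),
    peripheral features the z = 0 layer (six lines); within a line, n1..n5
    sit at adjacent x positions so that neighbouring neurons code similar
    values.
    """
    xs = [-20.0, -10.0, 0.0, 10.0, 20.0]
    layout: dict[str, list[tuple[float, float, float]]] = {}
    facial = [f for f in features if f.startswith("f")]
    peripheral = [f for f in features if not f.startswith("f")]
    y5 = [-40.0, -20.0, 0.0, 20.0, 40.0]
    all_facial = [f"f{i}" for i in range(1, 11)]
    for name in facial:
        i = all_facial.index(name)
        z = -30.0 if i < 5 else 30.0
        y = y5[i % 5]
        layout[name] = [(x, y, z) for x in xs]
    peripheral_all = [f for f in FEATURE_NAMES if not f.startswith("f")]
    y6 = [-50.0, -30.0, -10.0, 10.0, 30.0, 50.0]
    for name in peripheral:
        y = y6[peripheral_all.index(name)]
        layout[name] = [(x, y, 0.0) for x in xs]
    return layout


def _neighbor_offsets(params: ReservoirParams) -> np.ndarray:
    """Unique unordered-pair offsets with 0 < |offset| <= r (half-space)."""
    s = params.grid_spacing
    reach = int(params.small_world_radius // s) + 1
    offs = []
    for dx in range(-reach, reach + 1):
        for dy in range(-reach, reach + 1):
            for dz in range(-reach, reach + 1):
                # keep one representative of each {+o, -o} pair
                if (dz, dy, dx) <= (0, 0, 0):
                    continue
                d = s * np.sqrt(dx * dx + dy * dy + dz * dz)
                if d <= params.small_world_radius:
                    offs.append((dx, dy, dz))
    return np.asarray(offs, dtype=int) if offs else np.empty((0, 3), dtype=int)


def build_reservoir(
    params: ReservoirParams,
    features: Sequence[str] = FEATURE_NAMES,
) -> ReservoirNet:
    """Construct the reservoir: grid, input placement, small-world wiring.

    ``features`` selects which feature input lines exist (all 16 by
    default; a modality subset gives 50 or 30 input neurons). Deterministic
    given ``params.seed``.
    """
    rng = substream(params.seed, "reservoir")
    coords, index = _grid_coordinates(params)
    n = coords.shape[0]

    layout = default_input_layout(features)
    input_map = []
    for name in features:
        for pos in layout[name]:
            input_map.append(index[tuple(np.round(pos, 6))])
    input_map = np.asarray(input_map, dtype=int)
    if np.unique(input_map).size != input_map.size:
        raise ValueError("input lines overlap on the grid")
    is_input_neuron = np.zeros(n, dtype=bool)
    is_input_neuron[input_map] = True

    offsets = _neighbor_offsets(params)
    nx, ny, nz = params.grid_dims
    gx = np.round(coords[:, 0] / params.grid_spacing + (nx - 1) / 2).astype(int)
    gy = np.round(coords[:, 1] / params.grid_spacing + (ny - 1) / 2).astype(int)
    gz = np.round(coords[:, 2] / params.grid_spacing + (nz - 1) / 2).astype(int)
    pre_l, post_l, dist_l = [], [], []
    for dx, dy, dz in offsets:
        ax, ay, az = gx + dx, gy + dy, gz + dz
        ok = (ax >= 0) & (ax < nx) & (ay >= 0) & (ay < ny) & (az >= 0) & (az < nz)
        a = np.nonzero(ok)[0]
        b = ax[ok] + nx * (ay[ok] + ny * az[ok])
        d = params.grid_spacing * float(np.sqrt(dx * dx + dy * dy + dz * dz))
        p = min(1.0, params.connect_prob_scale * params.grid_spacing / d)
        keep = rng.random(a.size) < p
        a, b = a[keep], b[keep]
        # one random direction per connected pair
        swap = rng.random(a.size) < 0.5
        pre = np.where(swap, b, a)
        post = np.where(swap, a, b)
        pre_l.append(pre)
        post_l.append(post)
        dist_l.append(np.full(pre.size, d))
    if pre_l:
        pre = np.concatenate(pre_l)
        post = np.concatenate(post_l)
        dist = np.concatenate(dist_l)
    else:
        pre = post = np.empty(0, dtype=int)
        dist = np.empty(0)

    u = 1.0 - rng.random(pre.size)  # uniform on (0, 1]
    w = u / np.where(dist > 0, dist, 1.0)
    is_input_edge = is_input_neuron[pre]

    # exact excitatory fraction among recurrent (non-input) edges
    rec = np.nonzero(~is_input_edge)[0]
    n_pos = int(round(params.excitatory_fraction * rec.size))
    sign = np.ones(pre.size)
    neg = rng.permutation(rec)[n_pos:]
    sign[neg] = -1.0
    w *= sign
    w[is_input_edge] *= params.input_weight_multiplier  # positive, doubled

    return ReservoirNet(
        coordinates=coords,
        input_map=input_map,
        pre=pre.astype(np.int64),
        post=post.astype(np.int64),
        weights=w,
        is_input_edge=is_input_edge,
        params=params,
        features=tuple(features),
    )


def stdp_delta(dt: int | np.ndarray, learning_rate: float) -> float | np.ndarray:
    """Nearest-spike STDP increment: sgn(dt) * LR / (|dt| + 1), sgn(0) = 0."""
    dt = np.asarray(dt)
    out = np.sign(dt) * learning_rate / (np.abs(dt) + 1.0)
    return out if out.ndim else float(out)


def lif_step(
    psp: np.ndarray,
    refractory: np.ndarray,
    arriving: np.ndarray,
    params: ReservoirParams,
) -> np.ndarray:
    """One synchronous LIF step, updating ``psp``/``refractory`` in place.

    Non-refractory neurons leak (constant leak, floored at 0), integrate the
    arriving weighted spikes, and fire when the potential reaches threshold
    (reset to 0, refractory period starts). Refractory neurons ignore input
    and count down. Returns the boolean fired mask.
    """
    active = refractory == 0
    psp[active] = np.maximum(0.0, psp[active] - params.leak_per_step) + arriving[active]
    refractory[~active] -= 1
    fired = active & (psp >= params.firing_threshold)
    psp[fired] = 0.0
    refractory[fired] = params.refractory_steps
    return fired


def propagate(
    net: ReservoirNet,
    raster: np.ndarray,
    plasticity: bool = False,
) -> SpikeRecord:
    """Drive the reservoir with one trial's spike raster (one step per column).

    Input neurons fire exactly their raster rows (their own dynamics are
    bypassed); spikes travel one connection per step. With ``plasticity``
    on, online STDP updates ``net.weights`` in place. Neuron state is fresh
    per call; weights persist across calls. Encoded trials have 129 columns;
    any horizon is accepted.
    """
    raster = np.asarray(raster)
    n_inputs = net.input_map.size
    if raster.ndim != 2 or raster.shape[0] != n_inputs:
        raise ValueError(
            f"raster shape {raster.shape} does not match the net's "
            f"{n_inputs} input neurons"
        )
    horizon = raster.shape[1]
    n = net.n_neurons
    params = net.params
    psp = np.zeros(n)
    refractory = np.zeros(n, dtype=np.int64)
    fired_hist = np.zeros((n, horizon), dtype=bool)
    transmitted = np.zeros(net.n_edges, dtype=np.int64)
    last_spike = np.full(n, -1, dtype=np.int64)
    lr = params.stdp_learning_rate
    pre, post, w = net.pre, net.post, net.weights
    fired_prev = np.zeros(n, dtype=bool)

    for t in range(horizon):
        edge_active = fired_prev[pre]
        transmitted += edge_active
        arriving = np.bincount(
            post[edge_active], weights=w[edge_active], minlength=n
        )
        fired = lif_step(psp, refractory, arriving, params)
        # forced input firing per the encoder's deterministic trains
        fired[net.input_map] = raster[:, t] > 0
        psp[net.input_map] = 0.0
        refractory[net.input_map] = 0
        fired_hist[:, t] = fired

        if plasticity and fired.any():
            last_spike[fired] = t
            # potentiation: edges into neurons firing now, from neurons that
            # have spiked (dt >= 0; simultaneous spikes give 0)
            pot = fired[post] & (last_spike[pre] >= 0)
            if pot.any():
                dt = t - last_spike[pre[pot]]
                w[pot] += np.where(dt > 0, lr / (dt + 1.0), 0.0)
            # depression: edges out of neurons firing now whose target
            # spiked earlier (and is not firing now)
            dep = fired[pre] & (last_spike[post] >= 0) & ~fired[post]
            if dep.any():
                dt = last_spike[post[dep]] - t  # strictly negative
                w[dep] -= lr / (np.abs(dt) + 1.0)
        fired_prev = fired

    return SpikeRecord(fired=fired_hist, transmitted=transmitted)


def train_unsupervised(
    net: ReservoirNet, rasters: Sequence[np.ndarray] | np.ndarray
) -> ReservoirNet:
    """One STDP pass over the rasters in the given order; returns the net.

    Neuron states reset between trials; weights accumulate. Modifies
    ``net.weights`` in place and flags the net trained.
    """
    if net.n_neurons == 0:
        raise ValueError("reservoir not built")
    for raster in rasters:
        propagate(net, raster, plasticity=True)
    net.trained = True
    return net


def spike_communication_clusters(
    net: ReservoirNet, rasters: Sequence[np.ndarray] | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster reservoir neurons around input neurons by spike traffic.

    Propagates all rasters (plasticity off), accumulates per-connection
    transmitted spike counts, then assigns every reservoir neuron to the
    input neuron reachable along the directed path maximising the minimum
    transmitted count (widest path). Capacity ties go to the Euclidean-
    nearest input. Neurons with no positive-traffic path from any input stay
    unassigned (-1); each input neuron always belongs to its own cluster.

    Returns ``(cluster_sizes, assignment)`` with one size per input neuron.
    """
    if not net.trained:
        warnings.warn("cluster analysis on an untrained reservoir", stacklevel=2)
    transmitted = np.zeros(net.n_edges, dtype=np.int64)
    for raster in rasters:
        rec = propagate(net, raster, plasticity=False)
        transmitted += rec.transmitted

    n = net.n_neurons
    succ: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for e in range(net.n_edges):
        if transmitted[e] > 0:
            succ[net.pre[e]].append((int(net.post[e]), int(transmitted[e])))

    capacity = np.zeros(n)
    owner = np.full(n, -1, dtype=np.int64)
    heap: list[tuple[float, int, int]] = []
    for k, g in enumerate(net.input_map):
        capacity[g] = np.inf
        owner[g] = k
        heapq.heappush(heap, (-np.inf, int(g), k))

    input_coords = net.coordinates[net.input_map]

    def closer(node: int, cand_owner: int, cur_owner: int) -> bool:
        dc = np.linalg.norm(net.coordinates[node] - input_coords[cand_owner])
        du = np.linalg.norm(net.coordinates[node] - input_coords[cur_owner])
        return dc < du

    while heap:
        neg_cap, node, own = heapq.heappop(heap)
        cap = -neg_cap
        if cap < capacity[node] or own != owner[node]:
            continue
        for nxt, count in succ[node]:
            c = min(cap, float(count))
            if c > capacity[nxt] or (
                c == capacity[nxt]
                and owner[nxt] >= 0
                and owner[nxt] != own
                and closer(nxt, own, int(owner[nxt]))
            ):
                capacity[nxt] = c
                owner[nxt] = own
                heapq.heappush(heap, (-c, nxt, own))

    # input neurons always own themselves, whatever the traffic says
    for k, g in enumerate(net.input_map):
        owner[g] = k
    sizes = np.bincount(owner[owner >= 0], minlength=net.input_map.size)
    return sizes, owner
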