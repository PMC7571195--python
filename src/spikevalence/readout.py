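"""deSNN readout: rank-order initialised, drift-updated output neurons.

For every sample an output neuron is connected to all reservoir neurons.
Its weights start from the rank-order rule ``w_i = alpha * mod**rank_i``
(ranks by first-spike time, earliest = 0; silent neurons stay 0) and then
drift: from the step after synapse i's first spike onward, +drift whenever
neuron i fires again, -drift on every silent step. The resulting weight
vectors are what the KNN classifier compares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reservoir import ReservoirNet, SpikeRecord, propagate

__all__ = [
    "ReadoutParams",
    "OutputNeuron",
    "rank_order_init",
    "drift_update",
    "create_output_neuron",
]


@dataclass(frozen=True)
class ReadoutParams:
    """alpha: rank-order scale; mod: order modulation in (0, 1]; drift: per-step increment."""

    alpha: float = 1.0
    mod: float = 0.8
    drift: float = 0.005

    def __post_init__(self) -> None:
        if not 0.0 < self.mod <= 1.0:
            raise ValueError(f"mod must lie in (0, 1], got {self.mod}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.drift < 0:
            raise ValueError(f"drift must be >= 0, got {self.drift}")


@dataclass
class OutputNeuron:
    """One readout neuron: a weight vector over all reservoir neurons."""

    weights: np.ndarray
    label: str | None = None  # None for test neurons
    subject_id: int | None = None
    trial_id: int | None = None


def rank_order_init(
    first_spike_steps: np.ndarray, params: ReadoutParams
) -> np.ndarray:
    """Initial weights alpha * mod**rank by ascending first-spike step.

    ``first_spike_steps`` holds -1 for neurons that never spiked; those get
    weight 0. Ties in first-spike step break by neuron index (ascending).
    """
    steps = np.asarray(first_spike_steps)
    n = steps.size
    weights = np.zeros(n)
    spiking = np.nonzero(steps >= 0)[0]
    if spiking.size == 0:
        return weights
    # lexicographic (step, index): stable sort on index-ordered array
    order = spiking[np.argsort(steps[spiking], kind="stable")]
    weights[order] = params.alpha * params.mod ** np.arange(order.size)
    return weights


def drift_update(
    weights: np.ndarray,
    spike_record: SpikeRecord | np.ndarray,
    params: ReadoutParams,
    horizon: int | None = None,
) -> np.ndarray:
    """Apply the drift dynamics after rank-order initialisation.

    For each synapse whose neuron first fired at t0: every step t in
    (t0, horizon) contributes +drift if the neuron fired at t, else -drift.
    Synapses of never-firing neurons stay untouched (zero). Closed form:
    ``w += drift * (2 * fires_after - steps_after)``.
    """
    fired = spike_record.fired if isinstance(spike_record, SpikeRecord) else np.asarray(
        spike_record, dtype=bool
    )
    if horizon is None:
        horizon = fired.shape[1]
    w = np.asarray(weights, dtype=float).copy()
    any_fire = fired.any(axis=1)
    if not any_fire.any():
        return w
    first = np.argmax(fired, axis=1)
    fires_total = fired[:, :horizon].sum(axis=1)
    fires_after = fires_total - 1  # exclude the initialising spike
    steps_after = horizon - 1 - first
    delta = params.drift * (2 * fires_after - steps_after)
    w[any_fire] += delta[any_fire]
    return w


def create_output_neuron(
    net: ReservoirNet,
    raster: np.ndarray,
    label: str | None,
    params: ReadoutParams,
    subject_id: int | None = None,
    trial_id: int | None = None,
) -> OutputNeuron:
    """Propagate one sample through the frozen reservoir and build its neuron."""
    record = propagate(net, raster, plasticity=False)
    w = rank_order_init(record.first_spike_step, params)
    w = drift_update(w, record, params)
    return OutputNeuron(weights=w, label=label, subject_id=subject_id, trial_id=trial_id)
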