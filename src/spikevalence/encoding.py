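"""Quantile population spike encoding.

Each of the 16 feature series gets a population of five input neurons whose
receptive-field ranges are the equal-count (quantile) partition of the
pooled feature values across the fitting trials. At each of the 64 feature
samples exactly one neuron of the population spikes — the one whose range
contains the value — and zeros are interleaved between spike opportunities,
so each train is 129 steps long (spikes sit at odd steps 1, 3, ..., 127;
step 0 is silent for clean reservoir initialisation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .synth import FEATURE_NAMES, LabeledTrial, N_SAMPLES

__all__ = [
    "N_TIME_STEPS",
    "NEURONS_PER_FEATURE",
    "ReceptiveFieldBank",
    "QuantilePopulationEncoder",
    "fit_receptive_fields",
    "encode_feature",
    "encode_trial",
    "trials_to_array",
]

NEURONS_PER_FEATURE = 5
#: 64 spike opportunities with zeros interleaved: 2*64 + 1 = 129 steps.
N_TIME_STEPS = 2 * N_SAMPLES + 1


def trials_to_array(trials: Iterable[LabeledTrial] | np.ndarray) -> np.ndarray:
    """Stack trials into an (n_trials, n_features, 64) array."""
    if isinstance(trials, np.ndarray):
        arr = np.asarray(trials, dtype=float)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3-d trial array, got shape {arr.shape}")
        return arr
    mats = [t.features for t in trials]
    if not mats:
        raise ValueError("empty trial list")
    return np.stack(mats)


@dataclass
class ReceptiveFieldBank:
    """Fitted per-feature range boundaries (4 ascending cuts -> 5 ranges)."""

    boundaries: np.ndarray            # (n_features, 4)
    degenerate: np.ndarray            # (n_features,) bool
    fitted_on: str = ""               # human-readable provenance
    feature_names: tuple = field(default=FEATURE_NAMES)

    @property
    def n_features(self) -> int:
        return self.boundaries.shape[0]


def _equal_count_boundaries(values: np.ndarray, n_bins: int) -> tuple[np.ndarray, bool]:
    """Cut points splitting the pooled sample into equal-count bins.

    Boundary i is the midpoint between order statistics floor(n*i/k) and the
    next one, so bin occupancies differ by at most 1 for distinct values.
    All-identical input is flagged degenerate.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("no values to fit receptive fields on")
    if v[0] == v[-1]:
        return np.full(n_bins - 1, v[0]), True
    cuts = np.empty(n_bins - 1)
    for i in range(1, n_bins):
        k = (n * i) // n_bins
        k = min(max(k, 1), n - 1)
        cuts[i - 1] = 0.5 * (v[k - 1] + v[k])
    degenerate = not np.all(np.diff(cuts) > 0)
    return cuts, degenerate


def fit_receptive_fields(
    trials: Sequence[LabeledTrial] | np.ndarray,
    per_feature_neurons: int = NEURONS_PER_FEATURE,
    fitted_on: str = "",
) -> ReceptiveFieldBank:
    """Fit the equal-count receptive-field bank on pooled per-feature values."""
    arr = trials_to_array(trials)
    n_features = arr.shape[1]
    boundaries = np.empty((n_features, per_feature_neurons - 1))
    degenerate = np.zeros(n_features, dtype=bool)
    for f in range(n_features):
        boundaries[f], degenerate[f] = _equal_count_boundaries(
            arr[:, f, :].ravel(), per_feature_neurons
        )
    names = FEATURE_NAMES if n_features == len(FEATURE_NAMES) else tuple(
        f"feature{i}" for i in range(n_features)
    )
    return ReceptiveFieldBank(boundaries, degenerate, fitted_on, names)


def encode_feature(
    series: np.ndarray,
    boundaries: np.ndarray,
    degenerate: bool = False,
    n_neurons: int = NEURONS_PER_FEATURE,
) -> np.ndarray:
    """Encode one 64-sample series as a (5, 129) one-hot spike block.

    Sample k spikes at time step 2k+1 on the neuron whose range contains the
    value; a value equal to a boundary goes to the lower range; values
    outside all boundaries go to the extreme neurons. A degenerate bank
    routes everything to the middle neuron n3.
    """
    x = np.asarray(series, dtype=float)
    if x.shape != (N_SAMPLES,):
        raise ValueError(f"series must have {N_SAMPLES} samples, got {x.shape}")
    if degenerate:
        idx = np.full(N_SAMPLES, n_neurons // 2)
    else:
        # side='left': value == boundary maps to the boundary's index,
        # i.e. the lower range
        idx = np.searchsorted(boundaries, x, side="left")
    block = np.zeros((n_neurons, N_TIME_STEPS), dtype=np.uint8)
    block[idx, 2 * np.arange(N_SAMPLES) + 1] = 1
    return block


def encode_trial(
    trial: LabeledTrial | np.ndarray, bank: ReceptiveFieldBank
) -> np.ndarray:
    """Encode a trial's feature matrix into an (n_features*5, 129) raster."""
    feats = trial.features if isinstance(trial, LabeledTrial) else np.asarray(trial)
    if feats.shape[0] != bank.n_features:
        raise ValueError(
            f"trial has {feats.shape[0]} features but bank was fitted on "
            f"{bank.n_features}"
        )
    blocks = [
        encode_feature(feats[f], bank.boundaries[f], bool(bank.degenerate[f]))
        for f in range(bank.n_features)
    ]
    return np.vstack(blocks)


class QuantilePopulationEncoder(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: feature matrices -> population spike rasters.

    Parameters
    ----------
    per_feature_neurons:
        Population size per feature (5 by default).

    Attributes
    ----------
    bank_ : ReceptiveFieldBank
        Fitted equal-count receptive fields.
    """

    def __init__(self, per_feature_neurons: int = NEURONS_PER_FEATURE):
        self.per_feature_neurons = per_feature_neurons

    def fit(self, X, y=None):
        arr = trials_to_array(X)
        self.bank_ = fit_receptive_fields(
            arr, self.per_feature_neurons, fitted_on=f"{arr.shape[0]} trials"
        )
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "bank_")
        arr = trials_to_array(X)
        return np.stack([encode_trial(arr[i], self.bank_) for i in range(arr.shape[0])])
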