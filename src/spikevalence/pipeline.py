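"""End-to-end classifier: encoder -> reservoir -> deSNN readout -> KNN.

:class:`NeuCubeClassifier` wraps the whole pipeline as a scikit-learn
estimator. ``fit`` fits the receptive-field bank, builds and STDP-trains a
reservoir, and creates one output neuron per training sample; ``predict``
encodes test samples, runs them through the frozen reservoir, and classifies
their output-neuron weight vectors by K-nearest neighbours against the
training neurons' vectors.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._rng import substream
from .encoding import QuantilePopulationEncoder, ReceptiveFieldBank, encode_trial
from .readout import OutputNeuron, ReadoutParams, create_output_neuron
from .reservoir import ReservoirParams, build_reservoir, train_unsupervised
from .synth import FEATURE_NAMES

__all__ = ["NeuCubeClassifier", "knn_classify"]


def knn_classify(
    test_weights: np.ndarray,
    train_weights: np.ndarray,
    train_labels: Sequence[str],
    k: int = 3,
    metric: str = "euclidean",
) -> str:
    """Majority label among the K nearest training weight vectors.

    Distance ties break by training order (stable sort); a tied vote falls
    back to the single nearest neighbour's label.
    """
    if len(train_labels) < k:
        raise ValueError(f"need at least k={k} training samples, got {len(train_labels)}")
    diff = np.asarray(train_weights) - np.asarray(test_weights)
    if metric == "euclidean":
        dist = np.linalg.norm(diff, axis=1)
    elif metric == "manhattan":
        dist = np.abs(diff).sum(axis=1)
    else:
        raise ValueError(f"unsupported metric {metric!r}")
    order = np.argsort(dist, kind="stable")
    top = [train_labels[i] for i in order[:k]]
    labels, counts = np.unique(top, return_counts=True)
    best = counts == counts.max()
    if best.sum() > 1:
        return train_labels[order[0]]
    return str(labels[np.argmax(counts)])


class NeuCubeClassifier(ClassifierMixin, BaseEstimator):
    """Spiking reservoir classifier for 16x64 feature matrices.

    Parameters
    ----------
    reservoir_params, readout_params:
        Neuron-model / plasticity and readout parameter blocks (defaults
        mirror the standard parameter set: threshold 0.5, leak 0.002 per
        step, refractory 1 step, STDP learning rate 0.001, mod 0.8,
        drift 0.005).
    n_neighbors:
        K of the KNN vote (odd).
    features:
        Optional feature-name subset (e.g. facial-only); selects matrix
        rows and reservoir input lines.
    bank:
        Optional pre-fitted receptive-field bank; when given, ``fit`` skips
        bank fitting (pooled-across-all-subjects encoding mode).
    random_state:
        Seeds the reservoir wiring substream.

    Attributes
    ----------
    encoder_ : QuantilePopulationEncoder
    net_ : ReservoirNet (STDP-trained, then frozen)
    output_neurons_ : list of OutputNeuron, one per training sample
    """

    def __init__(
        self,
        reservoir_params: ReservoirParams | None = None,
        readout_params: ReadoutParams | None = None,
        n_neighbors: int = 3,
        metric: str = "euclidean",
        features: Sequence[str] | None = None,
        bank: ReceptiveFieldBank | None = None,
        random_state: int = 0,
    ):
        self.reservoir_params = reservoir_params
        self.readout_params = readout_params
        self.n_neighbors = n_neighbors
        self.metric = metric
        self.features = features
        self.bank = bank
        self.random_state = random_state

    def _feature_rows(self) -> list[int]:
        names = self.feature_names_
        return [FEATURE_NAMES.index(n) for n in names]

    def _resolve(self):
        if self.n_neighbors < 1 or self.n_neighbors % 2 == 0:
            raise ValueError(f"n_neighbors must be odd and >= 1, got {self.n_neighbors}")
        rp = self.reservoir_params or ReservoirParams()
        # derive the wiring seed from random_state so clones differ per fold
        seed = int(substream(self.random_state, "reservoir-seed").integers(2**31))
        rp = ReservoirParams(**{**rp.__dict__, "seed": seed})
        ro = self.readout_params or ReadoutParams()
        names = tuple(self.features) if self.features is not None else FEATURE_NAMES
        unknown = set(names) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature names: {sorted(unknown)}")
        return rp, ro, names

    def fit(self, X, y):
        """Fit on (n_trials, 16, 64) matrices (or LabeledTrials) and labels."""
        from .encoding import trials_to_array

        arr = trials_to_array(X)
        y = np.asarray(y, dtype=object)
        if y.shape[0] != arr.shape[0]:
            raise ValueError("X and y length mismatch")
        rp, ro, names = self._resolve()
        self.feature_names_ = names
        rows = [FEATURE_NAMES.index(n) for n in names]
        sub = arr[:, rows, :]

        self.encoder_ = QuantilePopulationEncoder()
        if self.bank is not None:
            if self.bank.n_features == len(FEATURE_NAMES) and len(rows) < 16:
                # slice the pooled bank down to the selected features
                bank = ReceptiveFieldBank(
                    self.bank.boundaries[rows],
                    self.bank.degenerate[rows],
                    self.bank.fitted_on,
                    names,
                )
            else:
                bank = self.bank
            self.encoder_.bank_ = bank
            self.encoder_.n_features_in_ = len(rows)
        else:
            self.encoder_.fit(sub)

        rasters = self.encoder_.transform(sub)
        net = build_reservoir(rp, features=names)
        train_unsupervised(net, rasters)
        self.net_ = net
        self.readout_params_ = ro
        self.output_neurons_ = [
            create_output_neuron(net, rasters[i], str(y[i]), ro)
            for i in range(rasters.shape[0])
        ]
        self.train_weights_ = np.stack([o.weights for o in self.output_neurons_])
        self.train_labels_ = [str(lbl) for lbl in y]
        self.classes_ = np.unique(self.train_labels_)
        return self

    def _test_neuron(self, features: np.ndarray) -> OutputNeuron:
        raster = encode_trial(features, self.encoder_.bank_)
        return create_output_neuron(self.net_, raster, None, self.readout_params_)

    def predict(self, X) -> np.ndarray:
        from .encoding import trials_to_array

        check_is_fitted(self, "net_")
        arr = trials_to_array(X)
        rows = [FEATURE_NAMES.index(n) for n in self.feature_names_]
        sub = arr[:, rows, :]
        preds = []
        for i in range(sub.shape[0]):
            neuron = self._test_neuron(sub[i])
            preds.append(
                knn_classify(
                    neuron.weights,
                    self.train_weights_,
                    self.train_labels_,
                    k=self.n_neighbors,
                    metric=self.metric,
                )
            )
        return np.asarray(preds, dtype=object)
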