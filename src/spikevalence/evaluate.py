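"""Leave-one-subject-out evaluation with feature- and decision-level fusion.

For each held-out subject a fresh pipeline (receptive fields, reservoir,
STDP, output neurons) is fitted on the remaining subjects; the held-out
trials are then classified and pooled into per-subject and total accuracy
and F1 (positive class = high valence). Fusion modes:

* ``feature`` — all 16 features drive one reservoir (feature-level fusion);
* ``facial_only`` / ``peripheral_only`` — single modality;
* ``decision`` — per held-out subject, an internal LOSO over the training
  subjects estimates each modality's accuracy and the better one (tie ->
  facial) classifies the held-out subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import f1_score

from ._rng import substream
from .encoding import fit_receptive_fields
from .pipeline import NeuCubeClassifier
from .readout import ReadoutParams
from .reservoir import ReservoirParams
from .synth import FACIAL_FEATURES, PERIPHERAL_FEATURES, LabeledTrial

__all__ = [
    "EvalParams",
    "SubjectResult",
    "EvalReport",
    "compute_metrics",
    "loso_evaluate",
    "decision_fusion",
]

FUSION_MODES = ("feature", "decision", "facial_only", "peripheral_only")


@dataclass(frozen=True)
class EvalParams:
    """KNN and protocol settings for LOSO evaluation."""

    k: int = 3
    metric: str = "euclidean"
    fusion_mode: str = "feature"
    pool_all: bool = False  # fit receptive fields on all subjects (legacy mode)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError(f"K must be odd and >= 1, got {self.k}")
        if self.fusion_mode not in FUSION_MODES:
            raise ValueError(
                f"fusion_mode must be one of {FUSION_MODES}, got {self.fusion_mode!r}"
            )


@dataclass
class SubjectResult:
    accuracy: float  # percent
    f1: float
    n_trials: int
    confusion: np.ndarray  # 2x2 counts, rows true (low, high), cols predicted
    chosen_modality: str | None = None  # decision fusion only


@dataclass
class EvalReport:
    """Per-subject and pooled LOSO results for one fusion mode."""

    fusion_mode: str
    per_subject: dict[int, SubjectResult] = field(default_factory=dict)
    total_accuracy: float = 0.0
    total_f1: float = 0.0
    confusion: np.ndarray = field(default_factory=lambda: np.zeros((2, 2), dtype=int))

    def finalize(self) -> "EvalReport":
        conf = sum((r.confusion for r in self.per_subject.values()),
                   np.zeros((2, 2), dtype=int))
        self.confusion = conf
        total = conf.sum()
        correct = np.trace(conf)
        self.total_accuracy = 100.0 * correct / total if total else 0.0
        tp = conf[1, 1]
        fp = conf[0, 1]
        fn = conf[1, 0]
        denom = 2 * tp + fp + fn
        self.total_f1 = 2 * tp / denom if denom else 0.0
        return self


def _confusion(y_true: Sequence[str], y_pred: Sequence[str]) -> np.ndarray:
    conf = np.zeros((2, 2), dtype=int)
    idx = {"low": 0, "high": 1}
    for t, p in zip(y_true, y_pred):
        conf[idx[str(t)], idx[str(p)]] += 1
    return conf


def compute_metrics(
    predictions: Sequence[str], labels: Sequence[str]
) -> tuple[float, float]:
    """(accuracy %, F1 of the high-valence class)."""
    preds = [str(p) for p in predictions]
    labs = [str(y) for y in labels]
    if not preds or len(preds) != len(labs):
        raise ValueError("predictions and labels must be equal-length and non-empty")
    acc = 100.0 * np.mean([p == y for p, y in zip(preds, labs)])
    f1 = f1_score(labs, preds, pos_label="high", zero_division=0)
    return float(acc), float(f1)


def _group_by_subject(trials: Sequence[LabeledTrial]) -> dict[int, list[LabeledTrial]]:
    groups: dict[int, list[LabeledTrial]] = {}
    for t in trials:
        groups.setdefault(t.subject_id, []).append(t)
    return groups


def _mode_features(mode: str) -> tuple[str, ...] | None:
    if mode == "facial_only":
        return FACIAL_FEATURES
    if mode == "peripheral_only":
        return PERIPHERAL_FEATURES
    return None  # all features


def _fit_predict(
    train: Sequence[LabeledTrial],
    test: Sequence[LabeledTrial],
    features: tuple[str, ...] | None,
    reservoir_params: ReservoirParams,
    readout_params: ReadoutParams,
    eval_params: EvalParams,
    fold_seed: int,
    bank=None,
) -> list[str]:
    clf = NeuCubeClassifier(
        reservoir_params=reservoir_params,
        readout_params=readout_params,
        n_neighbors=eval_params.k,
        metric=eval_params.metric,
        features=features,
        bank=bank,
        random_state=fold_seed,
    )
    X_train = np.stack([t.features for t in train])
    y_train = [t.label for t in train]
    clf.fit(X_train, y_train)
    X_test = np.stack([t.features for t in test])
    return [str(p) for p in clf.predict(X_test)]


def loso_evaluate(
    dataset: Sequence[LabeledTrial],
    reservoir_params: ReservoirParams | None = None,
    readout_params: ReadoutParams | None = None,
    eval_params: EvalParams | None = None,
) -> EvalReport:
    """LOSO cross-validation of the full pipeline in the configured fusion mode."""
    eval_params = eval_params or EvalParams()
    if eval_params.fusion_mode == "decision":
        return decision_fusion(dataset, reservoir_params, readout_params, eval_params)
    reservoir_params = reservoir_params or ReservoirParams()
    readout_params = readout_params or ReadoutParams()
    groups = _group_by_subject(dataset)
    if len(groups) < 2:
        raise ValueError(f"LOSO needs >= 2 subjects, got {len(groups)}")
    features = _mode_features(eval_params.fusion_mode)
    pooled_bank = (
        fit_receptive_fields(list(dataset), fitted_on="all subjects (pooled)")
        if eval_params.pool_all
        else None
    )
    report = EvalReport(fusion_mode=eval_params.fusion_mode)
    rng = substream(eval_params.seed, "evaluation")
    for subject in sorted(groups):
        test = groups[subject]
        train = [t for t in dataset if t.subject_id != subject]
        assert not {t.subject_id for t in train} & {subject}, "LOSO leakage"
        fold_seed = int(rng.integers(2**31))
        preds = _fit_predict(
            train, test, features, reservoir_params, readout_params,
            eval_params, fold_seed, bank=pooled_bank,
        )
        labels = [t.label for t in test]
        acc, f1 = compute_metrics(preds, labels)
        report.per_subject[subject] = SubjectResult(
            acc, f1, len(test), _confusion(labels, preds)
        )
    return report.finalize()


def decision_fusion(
    dataset: Sequence[LabeledTrial],
    reservoir_params: ReservoirParams | None = None,
    readout_params: ReadoutParams | None = None,
    eval_params: EvalParams | None = None,
) -> EvalReport:
    """Decision-level fusion: per subject, use the stronger single modality.

    The per-subject modality choice comes from an internal LOSO over the
    training subjects (resubstitution with per-sample output neurons would
    be trivially near-perfect). Ties go to facial.
    """
    eval_params = eval_params or EvalParams(fusion_mode="decision")
    reservoir_params = reservoir_params or ReservoirParams()
    readout_params = readout_params or ReadoutParams()
    groups = _group_by_subject(dataset)
    if len(groups) < 2:
        raise ValueError(f"LOSO needs >= 2 subjects, got {len(groups)}")
    report = EvalReport(fusion_mode="decision")
    rng = substream(eval_params.seed, "evaluation-decision")
    for subject in sorted(groups):
        test = groups[subject]
        train = [t for t in dataset if t.subject_id != subject]
        if len({t.subject_id for t in train}) < 2:
            # inner LOSO needs >= 2 training subjects; fall back to the
            # tie-rule default modality
            preds = _fit_predict(
                train, test, _mode_features("facial_only"), reservoir_params,
                readout_params, eval_params, int(rng.integers(2**31)),
            )
            labels = [t.label for t in test]
            acc, f1 = compute_metrics(preds, labels)
            report.per_subject[subject] = SubjectResult(
                acc, f1, len(test), _confusion(labels, preds),
                chosen_modality="facial_only",
            )
            continue
        inner_params = EvalParams(
            k=eval_params.k,
            metric=eval_params.metric,
            fusion_mode="facial_only",
            pool_all=eval_params.pool_all,
            seed=int(rng.integers(2**31)),
        )
        inner_facial = loso_evaluate(
            train, reservoir_params, readout_params, inner_params
        ).total_accuracy
        inner_params = EvalParams(
            k=eval_params.k,
            metric=eval_params.metric,
            fusion_mode="peripheral_only",
            pool_all=eval_params.pool_all,
            seed=int(rng.integers(2**31)),
        )
        inner_peripheral = loso_evaluate(
            train, reservoir_params, readout_params, inner_params
        ).total_accuracy
        modality = "facial_only" if inner_facial >= inner_peripheral else "peripheral_only"
        preds = _fit_predict(
            train, test, _mode_features(modality), reservoir_params,
            readout_params, eval_params, int(rng.integers(2**31)),
        )
        labels = [t.label for t in test]
        acc, f1 = compute_metrics(preds, labels)
        report.per_subject[subject] = SubjectResult(
            acc, f1, len(test), _confusion(labels, preds), chosen_modality=modality
        )
    return report.finalize()
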