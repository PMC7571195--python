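"""File formats and run configuration.

Feature tables are long-format delimited text (columns ``subject, trial,
label, feature, t0..t63``); spike rasters are sparse event lists with a
shape header; evaluation reports are CSVs mirroring the per-subject /
total accuracy table layout; raw recordings and trained nets use numpy
archives (runtime artifacts). Run configuration is a single YAML file with
one block per parameter group; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .encoding import N_TIME_STEPS
from .evaluate import EvalParams, EvalReport
from .readout import ReadoutParams
from .reservoir import ReservoirNet, ReservoirParams
from .synth import FEATURE_NAMES, LabeledTrial, RawRecording, SynthConfig

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_raster",
    "write_raster",
    "write_report",
    "read_report",
    "save_raw_recording",
    "load_raw_recording",
    "save_net",
    "load_net",
    "RunConfig",
]

_TIME_COLS = [f"t{i}" for i in range(64)]
_REPORT_COLS = ["Subject", "Facial", "Peripheral", "FusionDecision", "FusionFeatures"]
_MODE_TO_COL = {
    "facial_only": "Facial",
    "peripheral_only": "Peripheral",
    "decision": "FusionDecision",
    "feature": "FusionFeatures",
}


def write_feature_table(trials: Sequence[LabeledTrial], path: str | Path) -> None:
    rows = []
    for t in trials:
        for f, name in enumerate(FEATURE_NAMES):
            rows.append(
                {"subject": t.subject_id, "trial": t.trial_id, "label": t.label,
                 "feature": name, **dict(zip(_TIME_COLS, t.features[f]))}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_feature_table(path: str | Path) -> list[LabeledTrial]:
    """Read and validate a long-format feature table into trials."""
    df = pd.read_csv(path)
    required = {"subject", "trial", "label", "feature", *_TIME_COLS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    trials = []
    for (subject, trial), grp in df.groupby(["subject", "trial"], sort=True):
        labels = grp["label"].unique()
        if len(labels) != 1:
            raise ValueError(f"subject {subject} trial {trial}: inconsistent labels")
        label = str(labels[0])
        if label not in ("low", "high"):
            raise ValueError(
                f"subject {subject} trial {trial}: unknown label {label!r}"
            )
        grp = grp.set_index("feature")
        absent = set(FEATURE_NAMES) - set(grp.index)
        if absent:
            raise ValueError(
                f"subject {subject} trial {trial}: missing feature rows "
                f"{sorted(absent)}"
            )
        if len(grp) != len(FEATURE_NAMES):
            raise ValueError(
                f"subject {subject} trial {trial}: duplicate feature rows"
            )
        mat = grp.loc[list(FEATURE_NAMES), _TIME_COLS].to_numpy(dtype=float)
        if not np.isfinite(mat).all():
            raise ValueError(
                f"subject {subject} trial {trial}: non-finite feature values"
            )
        trials.append(LabeledTrial(int(subject), int(trial), label, mat))
    if not trials:
        raise ValueError(f"no trials found in {path}")
    return trials


def write_raster(raster: np.ndarray, path: str | Path) -> None:
    """Sparse event-list text format: '# shape: R C' then 'neuron step' lines."""
    raster = np.asarray(raster)
    rows, cols = np.nonzero(raster)
    with open(path, "w") as fh:
        fh.write(f"# shape: {raster.shape[0]} {raster.shape[1]}\n")
        for r, c in zip(rows, cols):
            fh.write(f"{r} {c}\n")


def read_raster(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# shape:"):
            raise ValueError(f"{path}: missing raster shape header")
        r, c = (int(x) for x in header.split(":")[1].split())
        raster = np.zeros((r, c), dtype=np.uint8)
        for line in fh:
            i, j = (int(x) for x in line.split())
            raster[i, j] = 1
    return raster


def write_report(reports: dict[str, EvalReport], path: str | Path) -> None:
    """Write per-subject + Total accuracy CSV (one column per fusion mode).

    ``reports`` maps fusion-mode names to their EvalReport; absent modes
    leave blank columns.
    """
    subjects = sorted({s for r in reports.values() for s in r.per_subject})
    rows = []
    for s in subjects:
        row: dict[str, object] = {"Subject": s}
        for mode, col in _MODE_TO_COL.items():
            r = reports.get(mode)
            row[col] = (
                round(r.per_subject[s].accuracy, 2)
                if r is not None and s in r.per_subject
                else ""
            )
        rows.append(row)
    total: dict[str, object] = {"Subject": "Total"}
    for mode, col in _MODE_TO_COL.items():
        r = reports.get(mode)
        total[col] = round(r.total_accuracy, 2) if r is not None else ""
    rows.append(total)
    pd.DataFrame(rows, columns=_REPORT_COLS).to_csv(path, index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_REPORT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"report missing columns: {sorted(missing)}")
    return df


def save_raw_recording(raw: RawRecording, path: str | Path) -> None:
    np.savez(
        path,
        label=raw.label,
        duration=raw.duration,
        fs_physio=raw.fs_physio,
        fs_video=raw.fs_video,
        fs_gaze=raw.fs_gaze,
        ecg=raw.ecg,
        respiration=raw.respiration,
        temperature=raw.temperature,
        gsr=raw.gsr,
        pupil_left=raw.pupil_left,
        pupil_right=raw.pupil_right,
        landmarks=raw.landmarks,
        true_r_times=raw.true_r_times,
        true_resp_cycles=raw.true_resp_cycles,
    )


def load_raw_recording(path: str | Path) -> RawRecording:
    with np.load(path, allow_pickle=False) as z:
        return RawRecording(
            label=str(z["label"]),
            duration=float(z["duration"]),
            fs_physio=float(z["fs_physio"]),
            fs_video=float(z["fs_video"]),
            fs_gaze=float(z["fs_gaze"]),
            ecg=z["ecg"],
            respiration=z["respiration"],
            temperature=z["temperature"],
            gsr=z["gsr"],
            pupil_left=z["pupil_left"],
            pupil_right=z["pupil_right"],
            landmarks=z["landmarks"],
            true_r_times=z["true_r_times"],
            true_resp_cycles=z["true_resp_cycles"],
        )


def save_net(net: ReservoirNet, path: str | Path) -> None:
    np.savez(
        path,
        coordinates=net.coordinates,
        input_map=net.input_map,
        pre=net.pre,
        post=net.post,
        weights=net.weights,
        is_input_edge=net.is_input_edge,
        params=json.dumps(dataclasses.asdict(net.params)),
        features=json.dumps(list(net.features)),
        trained=net.trained,
    )


def load_net(path: str | Path) -> ReservoirNet:
    with np.load(path, allow_pickle=False) as z:
        params = json.loads(str(z["params"]))
        params["grid_dims"] = tuple(params["grid_dims"])
        return ReservoirNet(
            coordinates=z["coordinates"],
            input_map=z["input_map"],
            pre=z["pre"],
            post=z["post"],
            weights=z["weights"],
            is_input_edge=z["is_input_edge"],
            params=ReservoirParams(**params),
            features=tuple(json.loads(str(z["features"]))),
            trained=bool(z["trained"]),
        )


_BLOCKS = {
    "synth": SynthConfig,
    "reservoir": ReservoirParams,
    "readout": ReadoutParams,
    "eval": EvalParams,
}


@dataclasses.dataclass
class RunConfig:
    """All parameter blocks resolved from YAML + CLI overrides."""

    synth: SynthConfig
    reservoir: ReservoirParams
    readout: ReadoutParams
    eval: EvalParams
    seed: int = 0

    @classmethod
    def load(cls, path: str | Path | None = None, seed: int | None = None,
             **overrides) -> "RunConfig":
        raw: dict = {}
        if path is not None:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(_BLOCKS) - {"seed"}
        if unknown:
            raise ValueError(f"unknown config blocks: {sorted(unknown)}")
        blocks = {}
        for name, klass in _BLOCKS.items():
            block = dict(raw.get(name, {}))
            block.update(overrides.get(name, {}))
            valid = {f.name for f in dataclasses.fields(klass)}
            bad = set(block) - valid
            if bad:
                raise ValueError(f"unknown keys in '{name}' block: {sorted(bad)}")
            blocks[name] = klass(**block)
        top_seed = seed if seed is not None else int(raw.get("seed", 0))
        # thread the top-level seed into the blocks that take one
        blocks["synth"] = dataclasses.replace(blocks["synth"], seed=top_seed)
        blocks["reservoir"] = dataclasses.replace(blocks["reservoir"], seed=top_seed)
        blocks["eval"] = dataclasses.replace(blocks["eval"], seed=top_seed)
        return cls(seed=top_seed, **blocks)

    def resolved(self) -> dict:
        return {
            "seed": self.seed,
            **{k: dataclasses.asdict(getattr(self, k)) for k in _BLOCKS},
        }
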