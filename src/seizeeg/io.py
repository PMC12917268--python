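"""Readers and writers for the pipeline's on-disk formats.

EDF carries raw multichannel signals (see :mod:`seizeeg.edf`); a CSV
pair (signal matrix + labels) is the delimited-text alternative that
round-trips exactly; feature tables are CSVs with a fixed validated
header; trained models serialise to JSON as config + flat parameter
vector + packing-order version tag; run configuration loads from YAML
or JSON.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import bilstm
from .edf import read_edf, write_edf  # re-exported
from .features import FEATURE_NAMES
from .record import EEGRecord

__all__ = [
    "read_edf",
    "write_edf",
    "write_features",
    "read_features",
    "write_record_csv",
    "read_record_csv",
    "save_model_json",
    "load_model_json",
    "RunConfig",
    "load_run_config",
]

_FEATURE_HEADER = ["segment_id", "channel", *FEATURE_NAMES, "label"]


class FormatError(ValueError):
    """Raised when a file does not match the expected layout."""


def write_features(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a feature table as CSV with the fixed 16-column header.

    Floats are emitted with 17 significant digits so the read-back is
    value-identical.
    """
    missing = [c for c in _FEATURE_HEADER if c not in table.columns]
    if missing:
        raise FormatError(f"feature table is missing columns {missing}")
    table[_FEATURE_HEADER].to_csv(path, index=False, float_format="%.17g")


def read_features(path: str | os.PathLike) -> pd.DataFrame:
    """Read a feature CSV, validating the header."""
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _FEATURE_HEADER if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: feature file is missing columns {missing}")
    return table[_FEATURE_HEADER]


def write_record_csv(record: EEGRecord, signal_path, labels_path) -> None:
    """Delimited-text pair: channels-as-columns signal matrix + label list."""
    pd.DataFrame(record.signal.T, columns=record.channel_names).to_csv(
        signal_path, index=False, float_format="%.17g"
    )
    pd.DataFrame(
        {
            "segment_id": np.arange(record.segment_labels.size),
            "label": record.segment_labels,
        }
    ).to_csv(labels_path, index=False)


def read_record_csv(
    signal_path, labels_path=None, fs: float = 256.0, segment_length: int = 2000
) -> EEGRecord:
    """Rebuild a record from the CSV pair written by :func:`write_record_csv`."""
    signal = pd.read_csv(signal_path, float_precision="round_trip")
    labels = np.zeros(0, dtype=np.int64)
    if labels_path is not None:
        lab = pd.read_csv(labels_path)
        if "label" not in lab.columns:
            raise FormatError(f"{labels_path}: missing 'label' column")
        labels = lab["label"].to_numpy(dtype=np.int64)
    return EEGRecord(
        signal=signal.to_numpy().T,
        fs=fs,
        channel_names=list(signal.columns),
        segment_labels=labels,
        segment_length=segment_length,
    )


def save_model_json(results, path: str | os.PathLike) -> None:
    """Serialise a fitted classifier: config, packing tag, flat params."""
    net = results.model.network
    payload = {
        "packing_version": results.packing_version,
        "network": {
            "input_length": net.input_length,
            "input_size": net.input_size,
            "hidden_units": net.hidden_units,
            "n_classes": net.n_classes,
            "pooling": net.pooling,
        },
        "mode": results.model.mode,
        "method": results.method,
        "fitness": results.fitness,
        "scaler": None
        if results.scaler is None
        else {"mean": results.scaler.mean.tolist(), "std": results.scaler.std.tolist()},
        "params": results.params_vector.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model_json(path: str | os.PathLike) -> tuple[bilstm.LSTMParams, dict]:
    """Load a serialised model; returns (structured params, raw payload)."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("packing_version") != bilstm.PACKING_VERSION:
        raise FormatError(
            f"{path}: packing version {payload.get('packing_version')!r} "
            f"does not match {bilstm.PACKING_VERSION!r}"
        )
    config = bilstm.NetworkConfig(**payload["network"])
    params = bilstm.unpack_params(np.asarray(payload["params"]), config)
    return params, payload


@dataclass
class RunConfig:
    """End-to-end run configuration loadable from YAML/JSON.

    ``reference_hyperparameters`` echoes the published gradient-training
    constants (learning rate 0.001, 100 epochs, cross-entropy loss,
    dropout 0.5, ...) for reporting only — training here is
    optimizer-driven and never consumes them.
    """

    band: tuple[float, float] = (0.05, 75.0)
    segment_length: int = 2000
    input_mode: str = "features"  # "segment" | "features"
    hidden_units: int = 8
    population_size: int = 20
    max_iterations: int = 50
    split_mode: str = "train_pct"
    train_pct: int = 90
    k: int = 10
    seed: int = 0
    output_dir: str = "."
    reference_hyperparameters: dict = field(
        default_factory=lambda: {
            "learning_rate": 0.001,
            "batch_size": 128,
            "epochs": 100,
            "loss": "cross_entropy",
            "dropout": 0.5,
            "optimizer": "adam (superseded by metaheuristic training)",
        }
    )

    def __post_init__(self) -> None:
        self.band = tuple(self.band)
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("band must satisfy 0 < low < high")
        if self.input_mode not in ("segment", "features"):
            raise ValueError("input_mode must be 'segment' or 'features'")
        if self.split_mode == "train_pct":
            if not 40 <= self.train_pct <= 90:
                raise ValueError("train_pct must lie in [40, 90]")
        elif self.split_mode == "kfold":
            if self.k < 2:
                raise ValueError("k must be >= 2")
        else:
            raise ValueError("split_mode must be 'train_pct' or 'kfold'")

    def to_dict(self) -> dict:
        return asdict(self)


def load_run_config(path: str | os.PathLike) -> RunConfig:
    """Load a run configuration from a YAML or JSON file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: run config must be a mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"{path}: unknown run-config keys {sorted(unknown)}")
    return RunConfig(**raw)
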