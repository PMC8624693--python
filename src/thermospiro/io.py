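"""Reading and writing the pipeline's on-disk formats.

* Thermal stacks: multi-frame TIFF (32-bit float, deg C) with an optional
  JSON sidecar (same stem, ``.json``) holding the frame rate, generator
  configuration and ground truth; or a directory of one CSV per frame.
* Respiration signals: two-column CSV ``time_s,temp_C``.
* Regression datasets: CSV with columns ``f_000 .. f_{N-1}, volume_l``.
* Trained models: a single file with a JSON metadata header line followed by
  the pickled estimator.
"""

from __future__ import annotations

import json
import pickle
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError
from .regress import RegressionDataset, TrainedVolumeModel
from .signal import RespirationSignal, ThermalSequence

__all__ = [
    "write_sequence",
    "read_sequence",
    "write_signal_csv",
    "read_signal_csv",
    "write_dataset_csv",
    "read_dataset_csv",
    "save_model",
    "load_model",
]

_MODEL_MAGIC = "thermospiro-model"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_sequence(path, seq: ThermalSequence, sidecar: dict | None = None) -> None:
    """Write a stack as multi-frame float32 TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, seq.frames.astype(np.float32))
    meta = {"frame_rate": seq.frame_rate}
    if sidecar:
        meta.update(sidecar)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_sequence(path, frame_rate: float | None = None) -> ThermalSequence:
    """Read a stack from a multi-frame TIFF or a CSV-per-frame directory.

    The frame rate is taken from the JSON sidecar when present, else from
    the ``frame_rate`` argument, else defaults to 9 frames/s.
    """
    path = Path(path)
    if path.is_dir():
        csvs = sorted(path.glob("*.csv"))
        if not csvs:
            raise ConfigurationError(f"no per-frame CSV files found in {path}")
        frames = np.stack([np.loadtxt(f, delimiter=",", ndmin=2) for f in csvs])
    else:
        frames = np.asarray(tifffile.imread(path), dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
    sidecar = _sidecar_path(path)
    if frame_rate is None and sidecar.is_file():
        frame_rate = json.loads(sidecar.read_text()).get("frame_rate")
    return ThermalSequence(frames=frames, frame_rate=frame_rate or 9.0)


def write_signal_csv(path, sig: RespirationSignal) -> None:
    pd.DataFrame({"time_s": sig.times, "temp_C": sig.values}).to_csv(path, index=False)


def read_signal_csv(path) -> RespirationSignal:
    """Read a ``time_s,temp_C`` CSV; the frame rate is inferred from spacing."""
    df = pd.read_csv(path)
    for col in ("time_s", "temp_C"):
        if col not in df.columns:
            raise ConfigurationError(f"signal CSV must have a {col!r} column")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ConfigurationError("signal CSV needs at least 2 rows to infer frame rate")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-3) or dt[0] <= 0:
        raise ConfigurationError("signal CSV must be uniformly sampled in time")
    return RespirationSignal(
        values=df["temp_C"].to_numpy(dtype=float),
        frame_rate=1.0 / float(dt[0]),
        provenance=f"read from {path}",
    )


def write_dataset_csv(path, dataset: RegressionDataset) -> None:
    n = dataset.n_features
    cols = {f"f_{i:03d}": dataset.features[:, i] for i in range(n)}
    cols["volume_l"] = dataset.labels
    pd.DataFrame(cols).to_csv(path, index=False)


def read_dataset_csv(path) -> RegressionDataset:
    df = pd.read_csv(path)
    if "volume_l" not in df.columns:
        raise ConfigurationError("dataset CSV must have a 'volume_l' column")
    feature_cols = [c for c in df.columns if c.startswith("f_")]
    if not feature_cols:
        raise ConfigurationError("dataset CSV has no feature columns (f_000, ...)")
    feature_cols.sort()
    return RegressionDataset(
        features=df[feature_cols].to_numpy(dtype=float),
        labels=df["volume_l"].to_numpy(dtype=float),
        metadata={"source": str(path)},
    )


def save_model(path, model: TrainedVolumeModel) -> None:
    """Persist a trained model: one JSON header line, then the pickled estimator."""
    header = {
        "format": _MODEL_MAGIC,
        "method": model.method,
        "feature_length": model.feature_length,
        "hyperparameters": model.hyperparameters,
        "seed": model.seed,
    }
    with open(path, "wb") as fh:
        fh.write(json.dumps(header).encode() + b"\n")
        fh.write(pickle.dumps(model.estimator))


def load_model(path) -> TrainedVolumeModel:
    with open(path, "rb") as fh:
        header_line = fh.readline()
        payload = fh.read()
    header = json.loads(header_line.decode())
    if header.get("format") != _MODEL_MAGIC:
        raise ConfigurationError(f"{path} is not a thermospiro model file")
    return TrainedVolumeModel(
        method=header["method"],
        estimator=pickle.loads(payload),
        feature_length=int(header["feature_length"]),
        hyperparameters=dict(header["hyperparameters"]),
        seed=int(header["seed"]),
    )
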