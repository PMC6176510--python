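"""Readers and writers: recordings (CSV, optionally EDF), seizure-interval
sidecars, feature archives, synchronization matrices, and model parameters."""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from eegsync.clfcnn import CLFCNNConfig, CLFCNNParams
from eegsync.synchrony import SyncMatrix
from eegsync.windowing import Recording

__all__ = [
    "read_recording",
    "write_recording",
    "read_intervals",
    "write_intervals",
    "write_features",
    "read_features",
    "write_sync_matrix",
    "read_sync_matrix",
    "save_model",
    "load_model",
]


def read_recording(
    path: Union[str, Path],
    format: str = "csv",
    sampling_rate: Union[float, None] = None,
    intervals_path: Union[str, Path, None] = None,
) -> Recording:
    """Load a recording.

    CSV layout is samples as rows, channels as columns, with a header of
    channel names; ``sampling_rate`` is then required.  EDF files need an EDF
    reader (pyedflib or mne) to be importable.
    """
    path = Path(path)
    if format == "edf":
        signal, rate = _read_edf(path)
    elif format == "csv":
        if sampling_rate is None:
            raise ValueError("sampling_rate is required for CSV recordings")
        signal, _names = _read_signal_csv(path)
        rate = float(sampling_rate)
    else:
        raise ValueError(f"unknown format {format!r}")
    intervals = read_intervals(intervals_path) if intervals_path else []
    return Recording(signal=signal, sampling_rate=rate, seizure_intervals=intervals)


def _read_signal_csv(path: Path) -> tuple:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        n_cols = len(header)
        rows = []
        for i, row in enumerate(reader, start=2):
            if len(row) != n_cols:
                raise ValueError(
                    f"{path}: ragged row {i} (expected {n_cols} cells, "
                    f"got {len(row)})"
                )
            try:
                rows.append([float(c) for c in row])
            except ValueError:
                raise ValueError(f"{path}: non-numeric cell in row {i}") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float).T, header


def _read_edf(path: Path) -> tuple:
    try:
        import pyedflib  # type: ignore
    except ImportError:
        try:
            import mne  # type: ignore
        except ImportError:
            raise RuntimeError(
                "EDF reader unavailable: install pyedflib or mne, or convert "
                "the recording to CSV"
            ) from None
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        return raw.get_data(), float(raw.info["sfreq"])
    with pyedflib.EdfReader(str(path)) as f:
        signal = np.vstack([f.readSignal(i) for i in range(f.signals_in_file)])
        rate = float(f.getSampleFrequency(0))
    return signal, rate


def write_recording(
    path: Union[str, Path],
    signal: np.ndarray,
    channel_names: Union[Sequence[str], None] = None,
) -> None:
    """Write a channels x samples signal as a samples x channels CSV."""
    signal = np.asarray(signal, dtype=float)
    names = channel_names or [f"ch{i}" for i in range(signal.shape[0])]
    pd.DataFrame(signal.T, columns=list(names)).to_csv(path, index=False)


def read_intervals(path: Union[str, Path]) -> list:
    """Seizure-interval sidecar: CSV with start_sample, end_sample columns."""
    df = pd.read_csv(path)
    return [
        (int(s), int(e))
        for s, e in zip(df["start_sample"], df["end_sample"])
    ]


def write_intervals(path: Union[str, Path], intervals: Sequence[tuple]) -> None:
    pd.DataFrame(intervals, columns=["start_sample", "end_sample"]).to_csv(
        path, index=False
    )


def write_features(
    path: Union[str, Path],
    matrices: Sequence[SyncMatrix],
    labels: Sequence[int],
    fingerprint: Union[dict, None] = None,
) -> None:
    """Archive synchronization matrices + labels (+ a config fingerprint)."""
    mats = [np.asarray(m.values, dtype=float) for m in matrices]
    if len({m.shape for m in mats}) > 1:
        raise ValueError("mixed channel counts across matrices")
    np.savez(
        path,
        matrices=np.stack(mats),
        labels=np.asarray(labels, dtype=int),
        channel_names=np.asarray(matrices[0].channel_names, dtype=object),
        fingerprint=json.dumps(fingerprint or {}),
    )


def read_features(
    path: Union[str, Path],
    expect_fingerprint: Union[dict, None] = None,
) -> tuple:
    """Load a feature archive -> ``(matrices, labels, fingerprint)``.

    A fingerprint mismatch (e.g. features built at a different window size)
    is a warning, not an error.
    """
    with np.load(path, allow_pickle=True) as data:
        stack = data["matrices"]
        labels = data["labels"]
        names = [str(c) for c in data["channel_names"]]
        fingerprint = json.loads(str(data["fingerprint"]))
    if expect_fingerprint is not None and fingerprint != expect_fingerprint:
        warnings.warn(
            f"feature archive fingerprint {fingerprint} does not match the "
            f"expected configuration {expect_fingerprint}",
            stacklevel=2,
        )
    matrices = [SyncMatrix(values=m, channel_names=list(names)) for m in stack]
    return matrices, labels, fingerprint


def write_sync_matrix(path: Union[str, Path], matrix: SyncMatrix) -> None:
    """Square numeric CSV with channel names as header row and index column."""
    pd.DataFrame(
        matrix.values, index=matrix.channel_names, columns=matrix.channel_names
    ).to_csv(path)


def read_sync_matrix(path: Union[str, Path]) -> SyncMatrix:
    df = pd.read_csv(path, index_col=0)
    return SyncMatrix(values=df.to_numpy(), channel_names=[str(c) for c in df.columns])


def save_model(
    path: Union[str, Path], params: CLFCNNParams, config: CLFCNNConfig
) -> None:
    """Serialize model parameters and configuration to JSON."""
    payload = {
        "widths": list(params.widths),
        "config": {
            "input_dim": config.input_dim,
            "hidden_widths": list(config.hidden_widths),
            "output_dim": config.output_dim,
            "dropout_input": config.dropout_input,
            "learning_rate": config.learning_rate,
            "momentum": config.momentum,
            "weight_decay": config.weight_decay,
            "batch_size": config.batch_size,
            "max_epochs": config.max_epochs,
            "patience": config.patience,
            "threshold": config.threshold,
            "seed": config.seed,
            "cross_layer": config.cross_layer,
        },
        "edges": [
            {
                "edge": list(e),
                "weight_shape": list(params.weights[e].shape),
                "weight": params.weights[e].reshape(-1).tolist(),
                "bias": params.biases[e].tolist(),
            }
            for e in params.edges
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: Union[str, Path]) -> tuple:
    """Load a model -> ``(CLFCNNParams, CLFCNNConfig)``."""
    payload = json.loads(Path(path).read_text())
    cfg = payload["config"]
    cfg["hidden_widths"] = tuple(cfg["hidden_widths"])
    config = CLFCNNConfig(**cfg)
    params = CLFCNNParams(widths=tuple(payload["widths"]))
    for entry in payload["edges"]:
        e = tuple(entry["edge"])
        params.weights[e] = np.asarray(entry["weight"], dtype=float).reshape(
            entry["weight_shape"]
        )
        params.biases[e] = np.asarray(entry["bias"], dtype=float)
    return params, config
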