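"""Readers and writers for recordings, connectivity tensors and tables.

Recordings travel as EDF (labels and sampling rate from the header; needs
the optional ``mne`` dependency) or plain CSV — one row per channel, first
column the channel label, with the sampling rate supplied by the caller.
Connectivity tensors are stored in HDF5 with their pair and scale tables
and window start indices, plus an optional long-format CSV mirror.
"""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .fractal import ConnectivityTensor, DFAExponentSeries, ScaleSet
from .preprocess import EEGRecording

__all__ = [
    "read_recording",
    "write_recording_csv",
    "write_tensor_h5",
    "read_tensor_h5",
    "tensor_long_frame",
]


def _read_recording_csv(path: Path, fs: float | None) -> EEGRecording:
    if fs is None:
        raise ValueError("CSV recordings need an explicit sampling rate (fs)")
    labels: list[str] = []
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for ln, row in enumerate(reader, start=1):
            if not row:
                continue
            labels.append(row[0])
            try:
                rows.append([float(v) for v in row[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric sample ({exc})") from exc
            if len(rows[-1]) != len(rows[0]):
                raise ValueError(
                    f"{path}:{ln}: ragged row ({len(rows[-1])} samples, "
                    f"expected {len(rows[0])})"
                )
    if not rows:
        raise ValueError(f"{path}: empty recording")
    return EEGRecording(np.array(rows), fs, labels)


def _read_recording_edf(path: Path) -> EEGRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return EEGRecording(raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names))


def read_recording(path, fmt: str | None = None, fs: float | None = None) -> EEGRecording:
    """Load a recording from EDF or channel-per-row CSV.

    ``fmt`` defaults to the file extension; CSV requires ``fs``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        return _read_recording_csv(path, fs)
    if fmt == "edf":
        return _read_recording_edf(path)
    raise ValueError(f"unknown recording format '{fmt}'")


def write_recording_csv(rec: EEGRecording, path) -> None:
    """Write a recording in the package's CSV dialect (label, then samples)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for label, row in zip(rec.labels, rec.data):
            writer.writerow([label] + [repr(float(v)) for v in row])


def write_tensor_h5(
    tensor: ConnectivityTensor, dfa: DFAExponentSeries, path
) -> None:
    """Persist a connectivity tensor and DFA exponent series to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("dccc", data=tensor.dccc)
        f.create_dataset("dfa", data=dfa.exponents)
        f.create_dataset("pairs", data=np.array(tensor.pairs, dtype=np.int64))
        f.create_dataset("scales", data=np.array(tensor.scales.scales, dtype=np.int64))
        f.create_dataset("window_starts", data=np.asarray(tensor.window_starts, dtype=np.int64))
        f.create_dataset(
            "labels", data=np.array(tensor.labels, dtype=h5py.string_dtype())
        )


def read_tensor_h5(path) -> tuple[ConnectivityTensor, DFAExponentSeries]:
    with h5py.File(path, "r") as f:
        labels = [s.decode() if isinstance(s, bytes) else str(s) for s in f["labels"][()]]
        scales = ScaleSet(tuple(int(s) for s in f["scales"][()]))
        pairs = [tuple(int(v) for v in row) for row in f["pairs"][()]]
        starts = f["window_starts"][()]
        tensor = ConnectivityTensor(f["dccc"][()], pairs, scales, labels, starts)
        dfa = DFAExponentSeries(f["dfa"][()], labels, starts)
    return tensor, dfa


def tensor_long_frame(tensor: ConnectivityTensor) -> pd.DataFrame:
    """Long-format view: one row per (window, ch1, ch2, scale) coefficient."""
    rows = []
    for w in range(tensor.n_windows):
        for p, (a, b) in enumerate(tensor.pair_labels()):
            for k, s in enumerate(tensor.scales.scales):
                rows.append((w, a, b, s, tensor.dccc[w, p, k]))
    return pd.DataFrame(rows, columns=["window", "ch1", "ch2", "scale", "dccc"])
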