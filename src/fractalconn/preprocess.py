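"""Deterministic conditioning of raw multichannel EEG before connectivity analysis.

The conditioning chain mirrors standard resting-state EEG practice: a
zero-phase Butterworth band-pass (0.5–45 Hz by default), re-referencing to
the common average, and trimming to a fixed-length epoch so that every
subject contributes the same amount of data. Artifact rejection by visual
inspection or ICA is a human-in-the-loop step and is deliberately not
implemented; externally cleaned data passes through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "EEGRecording",
    "bandpass_filter",
    "common_average_reference",
    "trim_epoch",
    "random_trim_offset",
]


@dataclass
class EEGRecording:
    """A multichannel recording: ``channels x samples`` in microvolts.

    Parameters
    ----------
    data : ndarray of shape (n_channels, n_samples)
        One row per channel.
    fs : float
        Sampling rate in Hz; must be positive.
    labels : list of str
        Ordered, unique channel names.
    subject_id : str
        Opaque subject identifier.
    group : str
        ``"young"``, ``"elderly"`` or ``"unknown"``.
    """

    data: np.ndarray
    fs: float
    labels: list[str] = field(default_factory=list)
    subject_id: str = ""
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def bandpass_filter(
    rec: EEGRecording,
    low_hz: float = 0.5,
    high_hz: float = 45.0,
    order: int = 4,
) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied forward and backward per channel.

    Edge transients are suppressed by reflect-padding each channel
    (``scipy.signal.filtfilt`` with odd-type padding), so short epochs are
    not contaminated by filter startup.

    Raises
    ------
    ValueError
        If the cutoffs do not satisfy ``0 < low < high < fs/2`` or the data
        contains non-finite values.
    """
    nyq = rec.fs / 2.0
    if not (0 < low_hz < high_hz):
        raise ValueError(f"need 0 < low ({low_hz}) < high ({high_hz})")
    if high_hz >= nyq:
        raise ValueError(f"high cutoff {high_hz} Hz must be below Nyquist {nyq} Hz")
    if not np.all(np.isfinite(rec.data)):
        raise ValueError("input contains NaN or infinite samples")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=filtered)


def common_average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous across-channel mean from every channel.

    After referencing, the per-sample channel sum is exactly zero; applying
    the operation twice is a no-op.
    """
    if rec.n_channels < 2:
        raise ValueError("common average reference requires at least 2 channels")
    return replace(rec, data=rec.data - rec.data.mean(axis=0, keepdims=True))


def trim_epoch(
    rec: EEGRecording, length_s: float = 72.0, offset_s: float = 0.0
) -> EEGRecording:
    """Extract a fixed-length epoch starting at ``offset_s``.

    The output has exactly ``round(length_s * fs)`` samples per channel;
    intervals are half-open with 0-based indexing.
    """
    n_out = int(round(length_s * rec.fs))
    start = int(round(offset_s * rec.fs))
    if start < 0:
        raise ValueError("offset must be non-negative")
    if start + n_out > rec.n_samples:
        raise ValueError(
            f"requested span [{start}, {start + n_out}) exceeds recording "
            f"length {rec.n_samples}"
        )
    return replace(rec, data=rec.data[:, start : start + n_out].copy())


def random_trim_offset(
    rec: EEGRecording, length_s: float, rng: np.random.Generator | int | None = None
) -> float:
    """Draw a uniform random epoch offset reproducing random trimming of
    long recordings to a common length.

    Returns an offset in seconds such that ``trim_epoch(rec, length_s,
    offset)`` is valid; deterministic given a seeded generator.
    """
    rng = np.random.default_rng(rng)
    slack = rec.n_samples - int(round(length_s * rec.fs))
    if slack < 0:
        raise ValueError("recording shorter than requested epoch")
    return float(rng.integers(0, slack + 1)) / rec.fs
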