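"""Reading, writing and windowing of raw peripheral physiological channels.

Raw recordings are per-channel CSV files in the Empatica-E4 dialect: the
first line is the UTC start time in seconds, the second line the sampling
rate in Hz, and every following line one sample.  Blood volume pulse (BVP)
is typically sampled at 128 Hz and skin conductance (GSR) at 4 Hz, so
windows are defined in seconds on a shared clock and each channel is sliced
on its own sample grid with half-open ``[start, end)`` intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np

__all__ = [
    "SignalRecord",
    "WindowSpec",
    "WindowedSegment",
    "SignalFormatError",
    "read_signal_csv",
    "write_signal_csv",
    "segment_windows",
]

#: Channel names accepted throughout the package.
CHANNELS = ("BVP", "GSR")


class SignalFormatError(ValueError):
    """Raised when a signal CSV does not follow the E4-style dialect."""


@dataclass
class SignalRecord:
    """A single-channel recording on a uniform sample grid.

    Parameters
    ----------
    channel
        ``"BVP"`` or ``"GSR"``.
    sampling_rate
        Samples per second, strictly positive.
    start_time
        Seconds since the epoch of the first sample.
    samples
        The recorded values (microsiemens for GSR, arbitrary reflectance
        units for BVP).
    """

    channel: str
    sampling_rate: float
    start_time: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return len(self.samples) / self.sampling_rate

    def time_axis(self) -> np.ndarray:
        """Absolute timestamp of every sample."""
        return self.start_time + np.arange(len(self.samples)) / self.sampling_rate


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in seconds."""

    window_length: float = 3.0
    hop: float = 1.0

    def __post_init__(self) -> None:
        if not self.window_length > 0:
            raise ValueError("window_length must be positive")
        if not 0 < self.hop <= self.window_length:
            raise ValueError("hop must satisfy 0 < hop <= window_length")


@dataclass
class WindowedSegment:
    """One aligned multi-channel window, optionally labeled."""

    channels: dict[str, np.ndarray]
    start: float
    end: float
    sampling_rates: dict[str, float]
    y: float | None = None
    subject_id: str | None = None


def read_signal_csv(path, channel: str) -> SignalRecord:
    """Read one E4-style channel file.

    The file must contain the start time on line 1, the sampling rate on
    line 2 and one sample per subsequent line.  A file with only the two
    header lines yields an empty (but valid) record.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() != ""]
    if len(lines) < 2:
        raise SignalFormatError(f"{path}: expected start-time and sample-rate header lines")
    try:
        start_time = float(lines[0])
    except ValueError:
        raise SignalFormatError(f"{path}: line 1 (start time) is not numeric: {lines[0]!r}") from None
    try:
        fs = float(lines[1])
    except ValueError:
        raise SignalFormatError(f"{path}: line 2 (sample rate) is not numeric: {lines[1]!r}") from None
    if fs <= 0:
        raise SignalFormatError(f"{path}: sample rate must be positive, got {fs}")
    samples = np.empty(len(lines) - 2)
    for i, ln in enumerate(lines[2:], start=3):
        try:
            samples[i - 3] = float(ln)
        except ValueError:
            raise SignalFormatError(f"{path}: line {i}: non-numeric sample {ln!r}") from None
    return SignalRecord(channel=channel, sampling_rate=fs, start_time=start_time, samples=samples)


def write_signal_csv(record: SignalRecord, path) -> None:
    """Write an E4-style channel file; ``read_signal_csv`` round-trips it."""
    with open(path, "w") as fh:
        fh.write(f"{record.start_time!r}\n{record.sampling_rate!r}\n")
        for v in record.samples:
            fh.write(f"{float(v)!r}\n")


def _slice_channel(rec: SignalRecord, start: float, end: float) -> np.ndarray:
    # half-open [start, end) on the channel's own grid; tolerate fp jitter
    # of a fraction of one sample period at the boundaries
    eps = 1e-9
    i0 = math.ceil((start - rec.start_time) * rec.sampling_rate - eps)
    i1 = math.ceil((end - rec.start_time) * rec.sampling_rate - eps)
    i0 = max(i0, 0)
    i1 = min(i1, len(rec.samples))
    return rec.samples[i0:i1]


def _label_at(labels, t: float) -> float | None:
    if labels is None:
        return None
    if callable(labels):
        return float(labels(t))
    if hasattr(labels, "value_at"):
        return float(labels.value_at(t))
    return float(labels)  # constant track


def segment_windows(
    signals: Iterable[SignalRecord] | Mapping[str, SignalRecord],
    spec: WindowSpec,
    labels: float | Callable[[float], float] | None = None,
    subject_id: str | None = None,
) -> list[WindowedSegment]:
    """Cut aligned sliding windows across channels of different rates.

    Windows start at the latest channel start time and advance by
    ``spec.hop``; a window that would extend past the end of any channel is
    not emitted.  The label attached to a window is the label-track value
    at the window *end* time (the window summarises the signal leading up
    to that moment).

    ``labels`` may be ``None``, a constant, a callable ``t -> y``, or any
    object with a ``value_at(t)`` method (e.g. a Stroop label track).
    """
    if isinstance(signals, Mapping):
        records = list(signals.values())
    else:
        records = list(signals)
    if not records:
        raise ValueError("at least one channel is required")
    for rec in records:
        if len(rec.samples) == 0:
            raise ValueError(f"channel {rec.channel} has no samples")

    t0 = max(rec.start_time for rec in records)
    t_end = min(rec.start_time + rec.duration for rec in records)
    if t_end - t0 < spec.window_length - 1e-9:  # same slack as the emission loop
        warnings.warn(
            f"window length {spec.window_length}s exceeds the usable recording "
            f"span {t_end - t0:.3f}s; no windows emitted",
            stacklevel=2,
        )
        return []

    out: list[WindowedSegment] = []
    k = 0
    while True:
        start = t0 + k * spec.hop
        end = start + spec.window_length
        if end > t_end + 1e-9:
            break
        out.append(
            WindowedSegment(
                channels={rec.channel: _slice_channel(rec, start, end) for rec in records},
                start=start,
                end=end,
                sampling_rates={rec.channel: rec.sampling_rate for rec in records},
                y=_label_at(labels, end),
                subject_id=subject_id,
            )
        )
        k += 1
    return out
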