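"""Sliding-window RMS feature extraction for multichannel surface EMG.

The decoder downstream consumes one root-mean-square (RMS) value per
channel per window.  RMS of a short EMG window is the standard proxy for
muscle activation level, and a linear map from per-channel RMS to motor
intent is the model the rest of the package estimates.

Conventions
-----------
* The reference configuration is an 8-channel armband sampled at 200 Hz,
  framed into 200 ms windows advanced by 40 ms (40 and 8 samples).  Any
  positive channel count and sample rate is accepted.
* Windows are aligned to sample 0 of the stream; partial trailing
  windows are dropped so every feature is a full-window statistic.
* A feature carries the END time of its source window: in a causal
  real-time system the feature exists only once the window completes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "EmgStream",
    "WindowingConfig",
    "FeatureVector",
    "RollingWindow",
    "rms_window",
    "sliding_features",
    "read_emg_csv",
    "write_emg_csv",
]


@dataclass(frozen=True)
class WindowingConfig:
    """Sliding-window geometry in seconds.

    Parameters
    ----------
    window_duration : float
        Window length T in seconds (default 0.200).
    hop_duration : float
        Increment between consecutive windows in seconds (default 0.040).
        The hop doubles as the control tick of the real-time loop: one
        new feature, one decoder update, one cursor refresh per hop.
    """

    window_duration: float = 0.200
    hop_duration: float = 0.040

    def __post_init__(self) -> None:
        if not (0.0 < self.hop_duration <= self.window_duration):
            raise InvalidInputError(
                "need 0 < hop_duration <= window_duration, got "
                f"hop={self.hop_duration}, window={self.window_duration}"
            )

    def _samples(self, duration: float, sample_rate: float, what: str) -> int:
        n = duration * sample_rate
        if abs(n - round(n)) > 1e-9:
            raise InvalidInputError(
                f"{what} of {duration} s is not a whole number of samples "
                f"at {sample_rate} Hz"
            )
        n = int(round(n))
        if n < 1:
            raise InvalidInputError(f"{what} shorter than one sample")
        return n

    def window_samples(self, sample_rate: float) -> int:
        """Window length in samples (40 at the 200 Hz default)."""
        return self._samples(self.window_duration, sample_rate, "window")

    def hop_samples(self, sample_rate: float) -> int:
        """Hop length in samples (8 at the 200 Hz default)."""
        return self._samples(self.hop_duration, sample_rate, "hop")


@dataclass
class EmgStream:
    """A time-ordered block of multichannel EMG samples.

    ``samples`` is an (n_samples, channel_count) float array in raw
    signal units; ``sample_rate`` in Hz.
    """

    samples: np.ndarray
    sample_rate: float = 200.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise InvalidInputError(
                f"samples must be 2-D (n, channels), got shape {self.samples.shape}"
            )
        if self.sample_rate <= 0:
            raise InvalidInputError(f"sample_rate must be > 0, got {self.sample_rate}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def channel_count(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass(frozen=True)
class FeatureVector:
    """Per-channel RMS of one window; timestamp is the window end time."""

    values: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return self.values.shape[0]


def rms_window(segment: np.ndarray, timestamp: float = 0.0) -> FeatureVector:
    """Per-channel RMS of one sample block.

    Parameters
    ----------
    segment : array-like, shape (n_frames, channels)
        One window of samples.  Must be rectangular and non-empty.
    timestamp : float
        End time of the window in seconds.
    """
    try:
        seg = np.asarray(segment, dtype=float)
    except ValueError as exc:  # ragged nested sequence
        raise InvalidInputError(f"ragged segment: {exc}") from exc
    if seg.ndim != 2 or seg.shape[0] < 1 or seg.shape[1] < 1:
        raise InvalidInputError(
            f"segment must be a non-empty (frames, channels) block, got shape {seg.shape}"
        )
    values = np.sqrt(np.mean(np.square(seg), axis=0))
    return FeatureVector(values=values, timestamp=timestamp)


def sliding_features(stream: EmgStream, cfg: WindowingConfig | None = None) -> list[FeatureVector]:
    """Frame a stream into sliding windows and compute the RMS of each.

    Windows start at sample 0 and advance by the hop; only full windows
    are emitted, so the count is ``floor((N - W) / H) + 1``.  A stream
    shorter than one window yields an empty list (with a warning).
    """
    cfg = cfg or WindowingConfig()
    w = cfg.window_samples(stream.sample_rate)
    h = cfg.hop_samples(stream.sample_rate)
    n = stream.n_samples
    if n < w:
        logger.warning(
            "stream of %d samples is shorter than one %d-sample window; no features", n, w
        )
        return []
    out: list[FeatureVector] = []
    for start in range(0, n - w + 1, h):
        end = start + w
        out.append(rms_window(stream.samples[start:end], timestamp=end / stream.sample_rate))
    return out


class RollingWindow:
    """Streaming counterpart of :func:`sliding_features`.

    Push hop-sized sample blocks as they are produced; once at least one
    full window has accumulated, every push returns the RMS feature of
    the trailing window.  Used by the real-time training and test loops.
    """

    def __init__(self, window_samples: int, channel_count: int, sample_rate: float) -> None:
        if window_samples < 1 or channel_count < 1 or sample_rate <= 0:
            raise InvalidInputError("window_samples, channel_count, sample_rate must be positive")
        self.window_samples = window_samples
        self.channel_count = channel_count
        self.sample_rate = sample_rate
        self._buffer = np.empty((0, channel_count), dtype=float)
        self._total_samples = 0

    def push(self, block: np.ndarray) -> FeatureVector | None:
        block = np.asarray(block, dtype=float)
        if block.ndim != 2 or block.shape[1] != self.channel_count:
            raise InvalidInputError(
                f"block must be (n, {self.channel_count}), got shape {block.shape}"
            )
        self._total_samples += block.shape[0]
        self._buffer = np.concatenate([self._buffer, block])[-self.window_samples :]
        if self._buffer.shape[0] < self.window_samples:
            return None
        return rms_window(self._buffer, timestamp=self._total_samples / self.sample_rate)

    def reset(self) -> None:
        self._buffer = np.empty((0, self.channel_count), dtype=float)
        self._total_samples = 0


def read_emg_csv(path: str | Path, sample_rate: float | None = None) -> EmgStream:
    """Read an EMG recording from delimited text.

    Expected layout: header row with ``t, ch1, ..., chM``; one row per
    sample.  Time must be strictly increasing; the sample rate is taken
    from the median time step unless given explicitly.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise InvalidInputError(f"{path}: empty EMG recording") from exc
    if frame.shape[1] < 2 or frame.columns[0] != "t":
        raise InvalidInputError(
            f"{path}: expected columns t, ch1..chM, got {list(frame.columns)}"
        )
    t = frame["t"].to_numpy(dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise InvalidInputError(f"{path}: time column must be strictly increasing")
    if sample_rate is None:
        if t.size < 2:
            raise InvalidInputError(f"{path}: cannot infer sample rate from {t.size} sample(s)")
        sample_rate = 1.0 / float(np.median(np.diff(t)))
    samples = frame.iloc[:, 1:].to_numpy(dtype=float)
    return EmgStream(samples=samples, sample_rate=sample_rate)


def write_emg_csv(path: str | Path, stream: EmgStream, t0: float = 0.0) -> None:
    """Write a recording in the same ``t, ch1..chM`` layout the reader expects."""
    t = t0 + np.arange(stream.n_samples) / stream.sample_rate
    cols = {"t": t}
    for j in range(stream.channel_count):
        cols[f"ch{j + 1}"] = stream.samples[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)
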