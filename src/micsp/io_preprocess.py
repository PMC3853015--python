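"""Epoched-EEG container, HDF5 round-trip I/O, and the preprocessing chain.

The exchange type for the whole package is :class:`Epochs`: a
``(n_trials, n_channels, n_samples)`` tensor with integer class labels in
``{1..7}``, a sampling rate, an ordered channel-name list, and the time of
the first sample relative to trial start.

The on-disk container is a single HDF5 file with fixed dataset names::

    /data      float32, (n_trials, n_channels, n_samples), microvolts
    /labels    int8, (n_trials,)
    /fs        scalar float, Hz
    /channels  variable-length UTF-8 strings, (n_channels,)
    /t0        scalar float, seconds

Preprocessing operations (:func:`common_average_reference`,
:func:`bandpass`, :func:`downsample`, :func:`crop_interval`) are pure:
each returns a new :class:`Epochs` and never mutates its input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

VALID_LABELS = frozenset(range(1, 8))


class EpochsFormatError(ValueError):
    """Raised when an epoch container is structurally malformed."""


class ValidationError(ValueError):
    """Raised when data violate an :class:`Epochs` invariant."""


@dataclass
class Epochs:
    """Labeled trial tensor with sampling and channel metadata.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal amplitudes in microvolts.
    labels : ndarray of int, shape (n_trials,)
        One class label per trial, each in ``{1..7}``.
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Ordered, unique channel names.
    t0 : float
        Time of the first sample relative to trial start, in seconds.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channels: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.channels = [str(c) for c in self.channels]
        if self.data.ndim != 3:
            raise ValidationError(f"data must be 3-D (trials, channels, samples); got shape {self.data.shape}")
        if self.labels.shape != (self.data.shape[0],):
            raise ValidationError("labels must have one entry per trial")
        bad = set(np.unique(self.labels)) - VALID_LABELS
        if bad:
            raise ValidationError(f"labels outside {{1..7}}: {sorted(bad)}")
        if not self.fs > 0:
            raise ValidationError("fs must be positive")
        if len(self.channels) != self.data.shape[1]:
            raise ValidationError("channel-name count does not match data")
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("channel names must be unique")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to trial start."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def class_trials(self, label: int) -> np.ndarray:
        """Data of all trials with the given label, (n, channels, samples)."""
        mask = self.labels == label
        if not mask.any():
            raise ValidationError(f"no trials with label {label}")
        return self.data[mask]

    def class_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def copy(self) -> "Epochs":
        return Epochs(self.data.copy(), self.labels.copy(), self.fs, list(self.channels), self.t0)


@dataclass
class ChannelLayout:
    """2-D scalp coordinates per channel, on the unit disc."""

    positions: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (x, y) in self.positions.items():
            if x * x + y * y > 1.0 + 1e-6:
                raise ValidationError(f"channel {name!r} lies outside the unit disc")

    def __contains__(self, name: str) -> bool:
        return name in self.positions

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.positions[name]

    def coords(self, channels: Sequence[str]) -> np.ndarray:
        """(n, 2) coordinate array in the given channel order."""
        missing = [c for c in channels if c not in self.positions]
        if missing:
            raise KeyError(f"channels missing from layout: {missing}")
        return np.array([self.positions[c] for c in channels], dtype=float)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChannelLayout":
        """Read a ``name,x,y`` CSV (header optional)."""
        positions: dict[str, tuple[float, float]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 3:
                raise EpochsFormatError(f"layout line must be 'name,x,y': {line!r}")
            try:
                x, y = float(parts[1]), float(parts[2])
            except ValueError:
                if parts[0].lower() in ("name", "channel"):
                    continue  # header row
                raise EpochsFormatError(f"non-numeric coordinates in layout: {line!r}") from None
            positions[parts[0]] = (x, y)
        return cls(positions)

    def to_csv(self, path: str | Path) -> None:
        lines = ["name,x,y"] + [f"{n},{x:.6f},{y:.6f}" for n, (x, y) in self.positions.items()]
        Path(path).write_text("\n".join(lines) + "\n")


# -- HDF5 container ----------------------------------------------------------


def save_epochs(epochs: Epochs, path: str | Path) -> None:
    """Write epochs to the HDF5 container (``/data`` stored as float32)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=np.asarray(epochs.data, dtype=np.float32))
        f.create_dataset("labels", data=np.asarray(epochs.labels, dtype=np.int8))
        f.create_dataset("fs", data=float(epochs.fs))
        f.create_dataset("channels", data=np.array(epochs.channels, dtype=h5py.string_dtype("utf-8")))
        f.create_dataset("t0", data=float(epochs.t0))


def load_epochs(path: str | Path, layout: ChannelLayout | None = None) -> Epochs:
    """Load epochs from the HDF5 container.

    Raises
    ------
    EpochsFormatError
        If a required dataset is missing.
    ValidationError
        If the contents violate an :class:`Epochs` invariant, or if
        `layout` is given and does not cover every channel.
    """
    with h5py.File(path, "r") as f:
        for key in ("data", "labels", "fs", "channels", "t0"):
            if key not in f:
                raise EpochsFormatError(f"missing dataset /{key} in {path}")
        data = f["data"][()]
        labels = f["labels"][()]
        fs = float(f["fs"][()])
        channels = [c.decode("utf-8") if isinstance(c, bytes) else str(c) for c in f["channels"][()]]
        t0 = float(f["t0"][()])
    epochs = Epochs(data=data, labels=labels, fs=fs, channels=channels, t0=t0)
    if layout is not None:
        missing = [c for c in channels if c not in layout]
        if missing:
            raise ValidationError(f"channels absent from layout: {missing}")
    return epochs


# -- preprocessing operations ------------------------------------------------


def common_average_reference(epochs: Epochs) -> Epochs:
    """Subtract the instantaneous mean over channels from every channel.

    Idempotent and invariant to common-mode offsets; requires >= 2 channels.
    """
    if epochs.n_channels < 2:
        raise ValidationError("common average reference requires at least 2 channels")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return replace(epochs, data=data)


def bandpass(epochs: Epochs, low: float, high: float, order: int = 5) -> Epochs:
    """Zero-phase Butterworth band-pass (applied forward and backward).

    The effective attenuation is the squared magnitude response of an
    `order`-th order Butterworth filter.
    """
    nyq = epochs.fs / 2.0
    if not 0 < low < high:
        raise ValidationError(f"need 0 < low < high; got ({low}, {high})")
    if high >= nyq:
        raise ValidationError(f"high edge {high} Hz must be below Nyquist {nyq} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=epochs.fs, output="sos")
    data = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return replace(epochs, data=data)


def downsample(epochs: Epochs, target_fs: float) -> Epochs:
    """Decimate to `target_fs` with anti-alias filtering.

    `fs` must be an integer multiple of `target_fs`. Uses an 8th-order
    Chebyshev-I anti-alias filter applied forward-backward before
    decimation (``scipy.signal.decimate`` with ``zero_phase=True``).
    """
    ratio = epochs.fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValidationError(f"fs={epochs.fs} is not an integer multiple of target_fs={target_fs}")
    if q == 1:
        return epochs.copy()
    data = signal.decimate(epochs.data, q, axis=-1, zero_phase=True)
    n_keep = int(np.floor(epochs.n_samples * target_fs / epochs.fs))
    data = data[..., :n_keep]
    return replace(epochs, data=data, fs=float(target_fs))


def crop_interval(epochs: Epochs, t_start: float, t_end: float) -> Epochs:
    """Keep samples in ``[t_start, t_end)`` (times relative to trial start)."""
    t_max = epochs.t0 + epochs.n_samples / epochs.fs
    if not (epochs.t0 - 1e-9 <= t_start < t_end <= t_max + 1e-9):
        raise ValidationError(
            f"crop [{t_start}, {t_end}] outside trial extent [{epochs.t0}, {t_max}]"
        )
    i0 = int(round((t_start - epochs.t0) * epochs.fs))
    n = int(round((t_end - t_start) * epochs.fs))
    n = min(n, epochs.n_samples - i0)
    data = epochs.data[..., i0 : i0 + n]
    return replace(epochs, data=data, t0=epochs.t0 + i0 / epochs.fs)


def preprocess_chain(
    epochs: Epochs,
    car: bool = True,
    band: tuple[float, float] | None = (1.0, 40.0),
    target_fs: float | None = 200.0,
    crop: tuple[float, float] | None = None,
) -> Epochs:
    """Apply the standard chain CAR -> band-pass -> downsample -> crop.

    Steps are applied in this fixed order; each applied step is logged.
    Pass ``None`` (or ``car=False``) to skip a step.
    """
    out = epochs
    if car:
        logger.info("preprocess: common average reference")
        out = common_average_reference(out)
    if band is not None:
        logger.info("preprocess: band-pass %.3g-%.3g Hz", *band)
        out = bandpass(out, band[0], band[1])
    if target_fs is not None and target_fs != out.fs:
        logger.info("preprocess: downsample %.6g -> %.6g Hz", out.fs, target_fs)
        out = downsample(out, target_fs)
    if crop is not None:
        logger.info("preprocess: crop [%.3g, %.3g] s", *crop)
        out = crop_interval(out, crop[0], crop[1])
    return out


def prepare_for_csp(
    epochs: Epochs,
    band: tuple[float, float] = (8.0, 30.0),
    interval: tuple[float, float] = (3.5, 6.5),
) -> Epochs:
    """Band-pass and crop epochs to the imagery analysis window used for CSP."""
    return crop_interval(bandpass(epochs, band[0], band[1]), interval[0], interval[1])
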