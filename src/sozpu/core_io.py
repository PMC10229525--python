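"""Domain containers and readers/writers for iEEG recordings and feature stores.

Conventions used throughout the package:

* time is in seconds from the start of the recording,
* signals are in microvolts, shaped ``(n_channels, n_samples)``,
* segments are indexed by ``(channel_id, t0)`` with half-open windows
  ``[t0, t0 + seg_seconds)`` and 0-based sample indexing,
* channel labels live in ``{"SOZ", "NONSOZ", "UNKNOWN"}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SOZ = "SOZ"
NONSOZ = "NONSOZ"
UNKNOWN = "UNKNOWN"
LABELS = (SOZ, NONSOZ, UNKNOWN)


class FormatError(ValueError):
    """A file or container violates the expected structure."""


class ConfigError(ValueError):
    """A parameter combination is invalid or incomplete."""


@dataclass
class Recording:
    """A multichannel iEEG recording.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_ids : list of str
        Unique channel names, one per row of ``signal``.
    channel_labels : list of str, optional
        Per-channel label in ``{"SOZ", "NONSOZ", "UNKNOWN"}``.
    start_time : float
        Offset of the first sample in seconds (default 0).
    """

    signal: np.ndarray
    fs: float
    channel_ids: list[str]
    channel_labels: list[str] | None = None
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise FormatError("signal must be a 2-D (channels x samples) array")
        if self.fs <= 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_ids) != self.signal.shape[0]:
            raise FormatError(
                f"{len(self.channel_ids)} channel ids for {self.signal.shape[0]} signal rows"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise FormatError("channel_ids must be unique")
        if self.channel_labels is not None:
            if len(self.channel_labels) != len(self.channel_ids):
                raise FormatError("channel_labels must align 1:1 with channels")
            bad = set(self.channel_labels) - set(LABELS)
            if bad:
                raise FormatError(f"unknown channel labels: {sorted(bad)}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def label_of(self, channel_id: str) -> str:
        if self.channel_labels is None:
            return UNKNOWN
        return self.channel_labels[self.channel_ids.index(channel_id)]


@dataclass
class Segment:
    """One channel x fixed-duration window of a recording."""

    samples: np.ndarray
    fs: float
    channel_id: str
    t0: float = 0.0
    label: str = UNKNOWN

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        if self.t0 < 0:
            raise ConfigError("t0 must be >= 0")
        if self.label not in LABELS:
            raise FormatError(f"unknown label {self.label!r}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class FeatureVector:
    """A flat feature vector with provenance back to its source segment."""

    values: np.ndarray
    names: list[str]
    segment_ref: tuple[str, float] = ("", 0.0)
    label: str = UNKNOWN

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != len(self.names):
            raise FormatError("values and names must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("feature values must be finite")


@dataclass
class DatasetSplit:
    """Disjoint train/test index lists into a feature collection."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    scheme: str = "kfold"
    fold: int | None = None

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise FormatError("train and test indices overlap")


# ---------------------------------------------------------------------------
# recording I/O


def _read_edf_header_n_samples(path: Path) -> list[int]:
    """Samples-per-record for each signal from the raw EDF header.

    Used as a structural pre-check: this package requires one uniform
    sampling rate across channels.
    """
    with open(path, "rb") as fh:
        header = fh.read(256)
        n_signals = int(header[252:256].decode("ascii").strip())
        fh.seek(256 + n_signals * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80))
        raw = fh.read(n_signals * 8)
    return [int(raw[i * 8:(i + 1) * 8].decode("ascii").strip()) for i in range(n_signals)]


def read_recording(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
    channel_labels: Sequence[str] | None = None,
) -> Recording:
    """Read a recording from an EDF/EDF+ file or a delimited text matrix.

    Parameters
    ----------
    path : path
        File to read.
    format : {"edf", "csv"}, optional
        Inferred from the extension when omitted.
    fs : float, optional
        Sampling rate; required for csv (the format has no standard field
        for it), ignored for EDF.
    channel_labels : sequence of str, optional
        Per-channel SOZ/NONSOZ/UNKNOWN labels to attach.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format is None:
        format = "edf" if path.suffix.lower() in (".edf", ".bdf") else "csv"

    if format == "edf":
        n_per_record = _read_edf_header_n_samples(path)
        if len(set(n_per_record)) > 1:
            raise FormatError(
                f"channels have differing samples per record {sorted(set(n_per_record))}; "
                "a single sampling rate is required"
            )
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        signal = raw.get_data() * 1e6  # mne returns volts for EEG channel types
        return Recording(
            signal=signal,
            fs=float(raw.info["sfreq"]),
            channel_ids=list(raw.ch_names),
            channel_labels=list(channel_labels) if channel_labels is not None else None,
        )
    if format == "csv":
        if fs is None:
            raise ConfigError("fs is required when reading a csv matrix")
        df = pd.read_csv(path)
        if df.isna().any().any():
            raise FormatError("csv columns have inconsistent lengths")
        return Recording(
            signal=df.to_numpy(dtype=float).T,
            fs=float(fs),
            channel_ids=[str(c) for c in df.columns],
            channel_labels=list(channel_labels) if channel_labels is not None else None,
        )
    raise ConfigError(f"unknown format {format!r}")


def write_recording_csv(rec: Recording, path: str | Path) -> None:
    """Write the signal matrix as a csv with one named column per channel."""
    pd.DataFrame(rec.signal.T, columns=rec.channel_ids).to_csv(path, index=False)


def segment_recording(rec: Recording, seg_seconds: float = 20.0) -> list[Segment]:
    """Cut each channel into non-overlapping ``seg_seconds`` windows from t=0.

    The trailing remainder shorter than ``seg_seconds`` is discarded, never
    padded, so a 120-minute recording yields exactly 360 segments per channel.
    Labels are inherited from ``rec.channel_labels``.
    """
    n_per_seg = seg_seconds * rec.fs
    if abs(n_per_seg - round(n_per_seg)) > 1e-9:
        raise ConfigError(
            f"seg_seconds * fs = {n_per_seg} is not an integer number of samples"
        )
    n_per_seg = int(round(n_per_seg))
    if rec.n_samples == 0 or rec.n_channels == 0:
        raise ConfigError("recording is empty")
    n_segs = rec.n_samples // n_per_seg
    out: list[Segment] = []
    for ci, cid in enumerate(rec.channel_ids):
        label = rec.channel_labels[ci] if rec.channel_labels is not None else UNKNOWN
        for k in range(n_segs):
            out.append(
                Segment(
                    samples=rec.signal[ci, k * n_per_seg:(k + 1) * n_per_seg],
                    fs=rec.fs,
                    channel_id=cid,
                    t0=k * seg_seconds,
                    label=label,
                )
            )
    return out


# ---------------------------------------------------------------------------
# feature store

_META_COLS = ["channel_id", "t0", "label"]


def write_features(features: Sequence[FeatureVector], path: str | Path) -> None:
    """Write feature vectors to a delimited table.

    One row per vector; columns are ``channel_id, t0, label`` followed by the
    feature names. All vectors must share the same feature names.
    """
    features = list(features)
    if features:
        names = features[0].names
        for f in features[1:]:
            if f.names != names:
                raise FormatError("heterogeneous feature names in feature list")
    else:
        names = []
    rows = [
        {"channel_id": f.segment_ref[0], "t0": f.segment_ref[1], "label": f.label,
         **dict(zip(f.names, f.values))}
        for f in features
    ]
    pd.DataFrame(rows, columns=_META_COLS + list(names)).to_csv(path, index=False)


def read_features(path: str | Path) -> list[FeatureVector]:
    """Read a feature table written by :func:`write_features` (lossless round trip)."""
    df = pd.read_csv(Path(path), float_precision="round_trip")
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"feature store missing columns {missing}")
    names = [c for c in df.columns if c not in _META_COLS]
    return [
        FeatureVector(
            values=row[names].to_numpy(dtype=float),
            names=names,
            segment_ref=(str(row["channel_id"]), float(row["t0"])),
            label=str(row["label"]),
        )
        for _, row in df.iterrows()
    ]


def features_to_matrix(
    features: Sequence[FeatureVector],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack feature vectors into ``(X, labels, names)`` for model fitting."""
    features = list(features)
    if not features:
        return np.empty((0, 0)), np.empty(0, dtype=object), []
    names = features[0].names
    X = np.vstack([f.values for f in features])
    y = np.array([f.label for f in features], dtype=object)
    return X, y, list(names)
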