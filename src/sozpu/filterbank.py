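"""Physiological band-pass filter bank.

Seven canonical iEEG bands (Delta 0.5-4, Theta 4-8, Alpha 8-13, Beta 13-30,
Gamma 30-80, Ripple 80-250, Fast Ripple 250-600 Hz), applied as zero-phase
4th-order Butterworth filters (forward-backward, effective order 8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core_io import ConfigError, Segment

NYQUIST_FRACTION = 0.99  # a band must fit below 0.99 * fs/2 to be applied


@dataclass(frozen=True)
class Band:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ConfigError(f"invalid band edges {self.lo}-{self.hi} Hz")


CANONICAL_BANDS: tuple[Band, ...] = (
    Band("Delta", 0.5, 4.0),
    Band("Theta", 4.0, 8.0),
    Band("Alpha", 8.0, 13.0),
    Band("Beta", 13.0, 30.0),
    Band("Gamma", 30.0, 80.0),
    Band("Ripple", 80.0, 250.0),
    Band("FastRipple", 250.0, 600.0),
)


def band_set(fs: float, data_bandlimit_hz: float | None = None) -> list[Band]:
    """The canonical bands applicable at sampling rate ``fs``.

    A band whose upper edge exceeds 0.99 x Nyquist is dropped entirely (its
    content cannot be represented at this rate). An explicit
    ``data_bandlimit_hz`` — data known to be band-limited upstream, e.g.
    recordings pre-filtered to 150 Hz — instead truncates: bands starting at
    or above the limit are dropped and the top remaining band's upper edge is
    cut to the limit (Ripple 80-250 becomes 80-150 at a 150 Hz limit).
    """
    if fs <= 1:
        raise ConfigError(f"fs={fs} Hz is too low for any band")
    nyq_limit = NYQUIST_FRACTION * fs / 2.0
    out: list[Band] = []
    for band in CANONICAL_BANDS:
        if band.hi > nyq_limit:
            continue
        if data_bandlimit_hz is not None:
            if band.lo >= data_bandlimit_hz:
                continue
            if band.hi > data_bandlimit_hz:
                band = Band(band.name, band.lo, float(data_bandlimit_hz))
        out.append(band)
    if not out:
        raise ConfigError(f"fs={fs} Hz is too low for even the Delta band")
    return out


def _band_sos(band: Band, fs: float) -> np.ndarray:
    nyq_limit = NYQUIST_FRACTION * fs / 2.0
    if band.hi > nyq_limit:
        raise ConfigError(
            f"band {band.name} ({band.lo}-{band.hi} Hz) invalid for fs={fs} Hz"
        )
    return sps.butter(4, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")


def apply_band(seg: Segment, band: Band) -> Segment:
    """Zero-phase band-pass one segment; output has the input's length.

    4th-order Butterworth run forward and backward (``sosfiltfilt``), so the
    net phase response is zero and an in-band sinusoid is not delayed.
    """
    sos = _band_sos(band, seg.fs)
    filtered = sps.sosfiltfilt(sos, seg.samples)
    return Segment(
        samples=filtered, fs=seg.fs, channel_id=seg.channel_id, t0=seg.t0, label=seg.label
    )


def apply_band_array(x: np.ndarray, fs: float, band: Band) -> np.ndarray:
    """:func:`apply_band` on a bare array (last axis is time)."""
    return sps.sosfiltfilt(_band_sos(band, fs), np.asarray(x, dtype=float), axis=-1)
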