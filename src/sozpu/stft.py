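"""STFT spectrogram features for the image-based classifier path.

Segments are framed with a 1-second Hann window at 80% overlap (96 frames
for a 20-s segment), transformed one-sided, and stored as dB magnitude.
For the convolutional classifier the frequency axis is resampled onto a
logarithmic grid and the image bilinearly resized to a fixed shape with
per-image min-max scaling to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from skimage.transform import resize as _resize
from sklearn.base import BaseEstimator, TransformerMixin

from .core_io import ConfigError, Segment
from .entropies import EntropyFeatureMatrix

_DB_EPS = 1e-12


@dataclass
class Spectrogram:
    """Time-frequency magnitude image of one segment (dB)."""

    magnitude: np.ndarray  # frames x freq_bins
    frame_times: np.ndarray
    freqs: np.ndarray
    segment_ref: tuple[str, float] = ("", 0.0)
    label: str = "UNKNOWN"

    def __post_init__(self) -> None:
        if self.magnitude.shape != (len(self.frame_times), len(self.freqs)):
            raise ConfigError("magnitude shape inconsistent with axes")


@dataclass
class CnnInputImage:
    """Fixed-size [0, 1] image fed to the convolutional classifier."""

    pixels: np.ndarray
    source: str = "stft"
    segment_ref: tuple[str, float] = ("", 0.0)
    label: str = "UNKNOWN"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ConfigError("image values must lie in [0, 1]")


def stft_spectrogram(
    seg: Segment, window_s: float = 1.0, overlap: float = 0.8
) -> Spectrogram:
    """One-sided Hann-window STFT magnitude in dB.

    Frame count follows floor((T - window)/hop) + 1 with hop =
    window * (1 - overlap); no zero-padding at the edges.
    """
    if not 0 <= overlap < 1:
        raise ConfigError("overlap must lie in [0, 1)")
    nperseg = window_s * seg.fs
    if abs(nperseg - round(nperseg)) > 1e-9:
        raise ConfigError("window_s * fs must be an integer number of samples")
    nperseg = int(round(nperseg))
    if len(seg.samples) < nperseg:
        raise ConfigError("segment shorter than the STFT window")
    noverlap = int(round(nperseg * overlap))
    freqs, times, zxx = sps.spectrogram(
        seg.samples,
        fs=seg.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        mode="complex",
    )
    # undo scipy's spectral-density scaling back to the raw windowed DFT
    win = sps.get_window("hann", nperseg)
    raw = np.abs(zxx) * np.sqrt(seg.fs * (win * win).sum())
    mag_db = 20.0 * np.log10(raw.T + _DB_EPS)
    return Spectrogram(
        magnitude=mag_db,
        frame_times=times,
        freqs=freqs,
        segment_ref=(seg.channel_id, seg.t0),
        label=seg.label,
    )


def _min_max(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    if hi - lo <= 0:
        warnings.warn("degenerate (constant) image; returning zeros")
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def to_cnn_image(
    spec: Spectrogram,
    out_hw: tuple[int, int] = (64, 64),
    freq_scale: str = "log",
) -> CnnInputImage:
    """Resample a spectrogram to a fixed (H, W) image in [0, 1].

    Rows are frequency (log-spaced from the first nonzero bin to fs/2 by
    default), columns are time; bilinear interpolation throughout.
    """
    mag = spec.magnitude.T  # freq x time
    freqs = spec.freqs
    if freq_scale == "log":
        f_min = freqs[freqs > 0].min()
        f_max = freqs.max()
        grid = np.geomspace(f_min, f_max, num=len(freqs))
        mag = np.vstack([np.interp(grid, freqs, mag[:, j]) for j in range(mag.shape[1])]).T
    elif freq_scale != "linear":
        raise ConfigError("freq_scale must be 'log' or 'linear'")
    img = _resize(mag, out_hw, order=1, mode="edge", anti_aliasing=False)
    return CnnInputImage(
        pixels=_min_max(img),
        source="stft",
        segment_ref=spec.segment_ref,
        label=spec.label,
    )


def entropy_matrix_to_image(m: EntropyFeatureMatrix) -> CnnInputImage:
    """Min-max scale an 8 x B entropy matrix into an image; no resizing."""
    return CnnInputImage(
        pixels=_min_max(m.values),
        source="entropy_matrix",
        segment_ref=m.segment_ref,
        label=m.label,
    )


class StftImageExtractor(BaseEstimator, TransformerMixin):
    """Transform segments into stacked (n, H, W) CNN input images."""

    def __init__(
        self,
        window_s: float = 1.0,
        overlap: float = 0.8,
        out_hw: tuple[int, int] = (64, 64),
        freq_scale: str = "log",
    ):
        self.window_s = window_s
        self.overlap = overlap
        self.out_hw = out_hw
        self.freq_scale = freq_scale

    def fit(self, segments=None, y=None):
        return self

    def transform(self, segments: list[Segment]) -> np.ndarray:
        imgs = [
            to_cnn_image(
                stft_spectrogram(s, self.window_s, self.overlap),
                self.out_hw,
                self.freq_scale,
            ).pixels
            for s in segments
        ]
        return np.stack(imgs) if imgs else np.empty((0, *self.out_hw))
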