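"""Eight entropy estimators and the entropies x bands feature extractor.

The eight measures, in fixed row order: Shannon, Rényi (order alpha),
generalized (Tsallis, order q), two phase entropies (analytic-signal phase
histogram and successive phase-difference histogram), approximate entropy,
sample entropy, and permutation entropy. All logarithms are natural; all
values are in nats (Tsallis is dimensionless).

Histogram measures bin the amplitudes into ``hist_bins`` equal-width bins
over [min, max] of the input. ApEn/SampEn use Chebyshev distance with
tolerance ``r = r_factor * SD``; permutation entropy uses Bandt-Pompe
ordinal patterns with stable (index-order) tie-breaking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import hilbert
from sklearn.base import BaseEstimator, TransformerMixin

from .core_io import ConfigError, Segment
from .filterbank import Band, apply_band, band_set

ENTROPY_NAMES = (
    "shannon",
    "renyi",
    "tsallis",
    "phase1",
    "phase2",
    "apen",
    "sampen",
    "permen",
)


@dataclass
class EntropyConfig:
    """Estimator parameters shared by all bands."""

    hist_bins: int = 128
    renyi_alpha: float = 2.0
    tsallis_q: float = 2.0
    apen_m: int = 2
    apen_r_factor: float = 0.2
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    perm_order: int = 3
    perm_delay: int = 1
    complexity_max_samples: int | None = 1024

    def __post_init__(self) -> None:
        if self.hist_bins < 2:
            raise ConfigError("hist_bins must be >= 2")
        if self.apen_m < 1 or self.sampen_m < 1 or self.perm_order < 1:
            raise ConfigError("embedding orders must be >= 1")
        if self.apen_r_factor <= 0 or self.sampen_r_factor <= 0:
            raise ConfigError("r factors must be > 0")


@dataclass
class EntropyFeatureMatrix:
    """Entropies x bands matrix for one segment; row-major flattening."""

    values: np.ndarray
    row_names: list[str]
    col_names: list[str]
    segment_ref: tuple[str, float] = ("", 0.0)
    label: str = "UNKNOWN"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_names), len(self.col_names)):
            raise ConfigError("matrix shape does not match row/col names")
        if not np.all(np.isfinite(self.values)):
            raise ConfigError("entropy features must be finite")

    def flatten(self) -> tuple[np.ndarray, list[str]]:
        """Row-major (entropy-major) flattening with ``<entropy>_<band>`` names."""
        names = [f"{e}_{b}" for e in self.row_names for b in self.col_names]
        return self.values.ravel(order="C"), names


# ---------------------------------------------------------------------------
# histogram measures


def _hist_probs(x: np.ndarray, bins: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 2:
        raise ConfigError("need at least 2 samples")
    if np.ptp(x) == 0:  # constant signal: single occupied bin
        return np.array([1.0])
    counts, _ = np.histogram(x, bins=bins)
    p = counts / counts.sum()
    return p[p > 0]


def shannon_entropy(x: np.ndarray, bins: int = 128) -> float:
    """Shannon entropy H = -sum p ln p of the amplitude histogram, in nats."""
    p = _hist_probs(x, bins)
    return float(-np.sum(p * np.log(p)))


def renyi_entropy(x: np.ndarray, alpha: float = 2.0, bins: int = 128) -> float:
    """Rényi entropy H_a = ln(sum p^a) / (1-a); tends to Shannon as a -> 1."""
    if alpha == 1:
        raise ConfigError("alpha=1 is the Shannon limit; use shannon_entropy")
    p = _hist_probs(x, bins)
    return float(np.log(np.sum(p**alpha)) / (1.0 - alpha))


def generalized_entropy(x: np.ndarray, q: float = 2.0, bins: int = 128) -> float:
    """Tsallis (generalized) entropy S_q = (1 - sum p^q) / (q-1)."""
    if q == 1:
        raise ConfigError("q=1 is the Shannon limit; use shannon_entropy")
    p = _hist_probs(x, bins)
    return float((1.0 - np.sum(p**q)) / (q - 1.0))


def _entropy_of_counts(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def phase_entropy(x: np.ndarray, which: int = 1, bins: int = 128) -> float:
    """Entropy of the analytic-signal instantaneous phase distribution.

    ``which=1``: histogram of the Hilbert phase over (-pi, pi].
    ``which=2``: histogram of successive phase differences (wrapped); a pure
    tone has a constant increment and entropy near zero, while broadband
    noise spreads the increments.
    """
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 16:
        raise ConfigError("need at least 16 samples for phase entropy")
    if np.ptp(x) == 0:
        warnings.warn("constant signal has undefined phase; returning 0")
        return 0.0
    phase = np.angle(hilbert(x - x.mean()))
    if which == 1:
        values = phase
    elif which == 2:
        d = np.diff(phase)
        values = np.mod(d + np.pi, 2 * np.pi) - np.pi  # wrap to (-pi, pi]
    else:
        raise ConfigError("which must be 1 or 2")
    counts, _ = np.histogram(values, bins=bins, range=(-np.pi, np.pi))
    return _entropy_of_counts(counts)


# ---------------------------------------------------------------------------
# template measures (ApEn / SampEn)


def _chebyshev_counts(x: np.ndarray, m: int, r: float, n_templates: int) -> np.ndarray:
    """For each of the first ``n_templates`` m-length templates, the number of
    templates within Chebyshev distance r (self included)."""
    d = np.abs(x[:n_templates, None] - x[None, :n_templates])
    for k in range(1, m):
        np.maximum(d, np.abs(x[k:k + n_templates, None] - x[None, k:k + n_templates]), out=d)
    return (d <= r).sum(axis=1)


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Pincus approximate entropy ApEn(m, r) = Phi_m - Phi_{m+1}.

    ``Phi_m`` is the mean log of the fraction of templates (self-matches
    included) within Chebyshev distance ``r``. Default ``r = 0.2 * SD(x)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if n <= m + 1:
        raise ConfigError(f"need more than m+1={m + 1} samples")
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        warnings.warn("zero tolerance (constant signal); ApEn set to 0")
        return 0.0

    def phi(mm: int) -> float:
        nt = n - mm + 1
        counts = _chebyshev_counts(x, mm, r, nt)
        return float(np.mean(np.log(counts / nt)))

    return phi(m) - phi(m + 1)


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Richman-Moorman sample entropy SampEn(m, r) = -ln(A/B).

    ``B`` and ``A`` count template pairs (i < j over the first N-m templates,
    self-matches excluded) matching within Chebyshev distance ``r`` at lengths
    m and m+1. When either count is zero the estimator saturates and the
    resolution bound ``ln((N-m)^2)`` is returned instead of infinity, keeping
    downstream feature vectors finite.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if n <= m + 1:
        raise ConfigError(f"need more than m+1={m + 1} samples")
    if r is None:
        r = 0.2 * float(np.std(x))
    guard = math.log(float(max(n - m, 2)) ** 2)
    if r <= 0:
        warnings.warn("zero tolerance (constant signal); SampEn guard value returned")
        return 0.0
    nt = n - m  # templates considered at both lengths
    counts_m = _chebyshev_counts(x, m, r, nt)
    b = int(counts_m.sum()) - nt  # remove self-matches; == 2 * (#pairs)
    counts_m1 = _chebyshev_counts(x, m + 1, r, nt)
    a = int(counts_m1.sum()) - nt
    if b == 0 or a == 0:
        warnings.warn("no template matches; returning SampEn resolution bound")
        return guard
    return float(-math.log(a / b))


def permutation_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Bandt-Pompe permutation entropy in nats, ties broken by index order."""
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < order * delay + 1:
        raise ConfigError("series too short for the requested order/delay")
    emb = sliding_window_view(x, (order - 1) * delay + 1)[:, ::delay]
    patterns = np.argsort(emb, axis=1, kind="stable")
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    return _entropy_of_counts(counts)


def _apen_sampen_fused(
    x: np.ndarray, m: int, r: float, dtype=np.float32
) -> tuple[float, float]:
    """ApEn and SampEn sharing one Chebyshev distance matrix.

    Identical counting rules to :func:`approximate_entropy` and
    :func:`sample_entropy`; used on long band-filtered signals where the two
    would otherwise each rebuild the same O(N^2) distance matrix. float32
    accumulation is ample for feature extraction (the reference functions
    stay float64).
    """
    x = np.asarray(x, dtype=dtype).ravel()
    n = len(x)
    if n <= m + 1:
        raise ConfigError(f"need more than m+1={m + 1} samples")
    guard = math.log(float(max(n - m, 2)) ** 2)
    if r <= 0:
        return 0.0, 0.0
    r = dtype(r)
    nt = n - m + 1
    d = np.abs(x[:nt, None] - x[None, :nt])
    for k in range(1, m):
        np.maximum(d, np.abs(x[k:k + nt, None] - x[None, k:k + nt]), out=d)
    phi_m = float(np.mean(np.log((d <= r).sum(axis=1) / nt)))
    nt1 = n - m
    d1 = d[:nt1, :nt1]
    b = int((d1 <= r).sum()) - nt1
    d2 = np.maximum(d1, np.abs(x[m:m + nt1, None] - x[None, m:m + nt1]))
    counts_m1 = (d2 <= r).sum(axis=1)
    phi_m1 = float(np.mean(np.log(counts_m1 / nt1)))
    a = int(counts_m1.sum()) - nt1
    apen = phi_m - phi_m1
    sampen = guard if (a == 0 or b == 0) else float(-math.log(a / b))
    return apen, sampen


# ---------------------------------------------------------------------------
# feature assembly


def _decimate_to(x: np.ndarray, max_samples: int | None) -> np.ndarray:
    if max_samples is None or len(x) <= max_samples:
        return x
    stride = int(math.ceil(len(x) / max_samples))
    return x[::stride]


def _entropy_row(x: np.ndarray, cfg: EntropyConfig) -> np.ndarray:
    """All eight entropies of one band-filtered signal, in ENTROPY_NAMES order."""
    xc = _decimate_to(x, cfg.complexity_max_samples)
    sd = float(np.std(xc))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if cfg.apen_m == cfg.sampen_m and cfg.apen_r_factor == cfg.sampen_r_factor:
            apen, sampen = _apen_sampen_fused(xc, cfg.apen_m, cfg.apen_r_factor * sd)
        else:
            apen = approximate_entropy(xc, cfg.apen_m, cfg.apen_r_factor * sd)
            sampen = sample_entropy(xc, cfg.sampen_m, cfg.sampen_r_factor * sd)
        return np.array(
            [
                shannon_entropy(x, cfg.hist_bins),
                renyi_entropy(x, cfg.renyi_alpha, cfg.hist_bins),
                generalized_entropy(x, cfg.tsallis_q, cfg.hist_bins),
                phase_entropy(x, 1, cfg.hist_bins),
                phase_entropy(x, 2, cfg.hist_bins),
                apen,
                sampen,
                permutation_entropy(x, cfg.perm_order, cfg.perm_delay),
            ]
        )


def extract_entropy_features(
    seg: Segment, bands: list[Band], cfg: EntropyConfig | None = None
) -> EntropyFeatureMatrix:
    """The 8 x B entropy feature matrix of one segment.

    Entry (i, j) is entropy_i of the segment band-passed through band_j.
    An all-zero segment yields an all-zero matrix (with a warning).
    """
    cfg = cfg or EntropyConfig()
    if np.ptp(seg.samples) == 0:
        warnings.warn("constant segment; all entropy features set to 0")
        values = np.zeros((len(ENTROPY_NAMES), len(bands)))
    else:
        cols = []
        for band in bands:
            filtered = apply_band(seg, band).samples
            cols.append(_entropy_row(filtered, cfg))
        values = np.column_stack(cols)
    return EntropyFeatureMatrix(
        values=values,
        row_names=list(ENTROPY_NAMES),
        col_names=[b.name for b in bands],
        segment_ref=(seg.channel_id, seg.t0),
        label=seg.label,
    )


class EntropyFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transform segments into flattened entropies-x-bands feature rows.

    With 7 bands the output has 56 columns, with 6 bands 48, matching the
    classifier input sizes downstream. Stateless apart from the band set
    resolved from the first segment's sampling rate at fit time.

    Parameters mirror :class:`EntropyConfig`; ``data_bandlimit_hz`` restricts
    the band set for data known to be band-limited upstream.
    """

    def __init__(
        self,
        hist_bins: int = 128,
        renyi_alpha: float = 2.0,
        tsallis_q: float = 2.0,
        apen_m: int = 2,
        apen_r_factor: float = 0.2,
        sampen_m: int = 2,
        sampen_r_factor: float = 0.2,
        perm_order: int = 3,
        perm_delay: int = 1,
        complexity_max_samples: int | None = 1024,
        data_bandlimit_hz: float | None = None,
    ):
        self.hist_bins = hist_bins
        self.renyi_alpha = renyi_alpha
        self.tsallis_q = tsallis_q
        self.apen_m = apen_m
        self.apen_r_factor = apen_r_factor
        self.sampen_m = sampen_m
        self.sampen_r_factor = sampen_r_factor
        self.perm_order = perm_order
        self.perm_delay = perm_delay
        self.complexity_max_samples = complexity_max_samples
        self.data_bandlimit_hz = data_bandlimit_hz

    def _config(self) -> EntropyConfig:
        return EntropyConfig(
            hist_bins=self.hist_bins,
            renyi_alpha=self.renyi_alpha,
            tsallis_q=self.tsallis_q,
            apen_m=self.apen_m,
            apen_r_factor=self.apen_r_factor,
            sampen_m=self.sampen_m,
            sampen_r_factor=self.sampen_r_factor,
            perm_order=self.perm_order,
            perm_delay=self.perm_delay,
            complexity_max_samples=self.complexity_max_samples,
        )

    def fit(self, segments: list[Segment], y=None) -> "EntropyFeatureExtractor":
        if not segments:
            raise ConfigError("need at least one segment to resolve the band set")
        self.bands_ = band_set(segments[0].fs, self.data_bandlimit_hz)
        self.feature_names_ = [
            f"{e}_{b.name}" for e in ENTROPY_NAMES for b in self.bands_
        ]
        return self

    def transform(self, segments: list[Segment]) -> np.ndarray:
        if not hasattr(self, "bands_"):
            self.fit(segments)
        rows = [
            extract_entropy_features(seg, self.bands_, self._config()).flatten()[0]
            for seg in segments
        ]
        return np.vstack(rows) if rows else np.empty((0, len(self.feature_names_)))

    def transform_matrices(self, segments: list[Segment]) -> list[EntropyFeatureMatrix]:
        """Like :meth:`transform` but keeping the 8 x B matrix structure."""
        if not hasattr(self, "bands_"):
            self.fit(segments)
        return [extract_entropy_features(s, self.bands_, self._config()) for s in segments]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
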