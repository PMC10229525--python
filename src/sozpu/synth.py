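"""Synthetic labeled iEEG generator.

Produces multichannel recordings made of colored-noise background (power
spectral density proportional to 1/f^beta) with optional narrowband
oscillations, onto which interictal epileptiform transients are added at a
higher rate on SOZ channels than on non-SOZ channels. Transient families
follow the standard clinical definitions: spikes (20 to under 70 ms), sharp
waves (70-200 ms), slow waves (> 1/8 s), spike-and-slow-wave and polyspike
complexes, and ripple-band HFO bursts (80-250 Hz carrier).

Everything is a pure function of the configuration, seed included, so the
ground-truth event log is exact and every downstream stage can be tested
without clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import ConfigError, NONSOZ, Recording, SOZ

TRANSIENT_KINDS = (
    "spike",
    "sharp_wave",
    "slow_wave",
    "spike_and_slow_wave",
    "polyspike",
    "polyspike_and_slow_wave",
    "hfo_burst",
)

# centre frequencies used when band oscillation amplitudes are requested
_BAND_RANGES = {
    "Delta": (0.5, 4.0),
    "Theta": (4.0, 8.0),
    "Alpha": (8.0, 13.0),
    "Beta": (13.0, 30.0),
    "Gamma": (30.0, 80.0),
}


@dataclass(frozen=True)
class TransientSpec:
    """One epileptiform transient.

    ``duration_ms`` is the duration of the spike/sharp/slow component itself;
    complexes append a slow wave of ``slow_ms`` and polyspikes repeat the
    spike ``n_spikes`` times, so the synthesized waveform length is the sum
    of the component durations.
    """

    kind: str
    duration_ms: float
    amplitude_uv: float
    polarity: int = 1
    slow_ms: float = 300.0
    n_spikes: int = 3
    carrier_hz: float = 120.0

    def __post_init__(self) -> None:
        if self.kind not in TRANSIENT_KINDS:
            raise ConfigError(f"unknown transient kind {self.kind!r}")
        if self.amplitude_uv <= 0:
            raise ConfigError("amplitude must be > 0")
        if self.polarity not in (-1, 1):
            raise ConfigError("polarity must be +1 or -1")
        d = self.duration_ms
        if self.kind in ("spike", "spike_and_slow_wave", "polyspike",
                         "polyspike_and_slow_wave"):
            if not 20.0 <= d < 70.0:
                raise ConfigError(f"spike duration must be in [20, 70) ms, got {d}")
        elif self.kind == "sharp_wave":
            if not 70.0 <= d <= 200.0:
                raise ConfigError(f"sharp wave duration must be in [70, 200] ms, got {d}")
        elif self.kind == "slow_wave":
            if d <= 125.0:
                raise ConfigError(f"slow wave duration must exceed 125 ms, got {d}")
        elif self.kind == "hfo_burst":
            if not 80.0 <= self.carrier_hz <= 250.0:
                raise ConfigError(
                    f"HFO carrier must lie in the 80-250 Hz ripple band, got {self.carrier_hz}"
                )
        if self.kind.endswith("slow_wave") and self.kind != "slow_wave":
            if self.slow_ms <= 125.0:
                raise ConfigError("slow-wave component must exceed 125 ms")
        if self.kind.startswith("polyspike") and self.n_spikes < 2:
            raise ConfigError("polyspike needs at least 2 spikes")

    @property
    def total_duration_ms(self) -> float:
        d = self.duration_ms
        if self.kind.startswith("polyspike"):
            d = d * self.n_spikes
        if self.kind.endswith("slow_wave") and self.kind != "slow_wave":
            d = d + self.slow_ms
        return d


@dataclass
class SynthConfig:
    """Study conditions for one synthetic recording.

    Defaults emulate a short clinical interictal run: 512 Hz sampling,
    10 minutes, 3 SOZ + 3 non-SOZ channels, ~6 epileptiform events per
    minute on SOZ channels against ~2 per minute of propagated/background
    transients on non-SOZ channels (so some 20-s SOZ windows are event-free
    and the classes genuinely overlap), 80 uV transients over a 1/f^2
    colored background of 20 uV SD with modest theta/alpha oscillations.
    """

    fs: float = 512.0
    duration_s: float = 600.0
    n_soz: int = 3
    n_nonsoz: int = 3
    soz_event_rate_per_min: float = 6.0
    nonsoz_event_rate_per_min: float = 2.0
    noise_exponent: float = 2.0
    band_amps: dict = field(default_factory=lambda: {"Theta": 4.0, "Alpha": 6.0})
    noise_sigma_uv: float = 20.0
    event_amp_uv: float = 80.0
    event_amp_jitter: float = 0.25
    kind_mixture: dict = field(
        default_factory=lambda: {
            "spike": 0.4,
            "sharp_wave": 0.2,
            "spike_and_slow_wave": 0.2,
            "polyspike": 0.1,
            "hfo_burst": 0.1,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.soz_event_rate_per_min < 0 or self.nonsoz_event_rate_per_min < 0:
            raise ConfigError("event rates must be >= 0")
        if self.soz_event_rate_per_min < self.nonsoz_event_rate_per_min:
            raise ConfigError("SOZ event rate must be >= non-SOZ rate (separability)")
        if self.noise_exponent < 0:
            raise ConfigError("noise exponent must be >= 0")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ConfigError("fs and duration must be positive")
        bad = set(self.kind_mixture) - set(TRANSIENT_KINDS)
        if bad:
            raise ConfigError(f"unknown kinds in mixture: {sorted(bad)}")


@dataclass
class EventLog:
    """Ground truth: every transient inserted into a recording."""

    events: list[tuple[str, float, TransientSpec]] = field(default_factory=list)

    def for_channel(self, channel_id: str) -> list[tuple[float, TransientSpec]]:
        return [(t, s) for c, t, s in self.events if c == channel_id]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c, _, _ in self.events:
            out[c] = out.get(c, 0) + 1
        return out


# ---------------------------------------------------------------------------
# waveform synthesis


def _n_samples(ms: float, fs: float) -> int:
    return int(round(ms / 1000.0 * fs))


def _spiky_peak(n: int) -> np.ndarray:
    """Smooth biphasic pointed peak: narrow positive minus broad negative Gaussian."""
    t = np.linspace(-1.0, 1.0, n)
    narrow = np.exp(-0.5 * (t / 0.18) ** 2)
    broad = np.exp(-0.5 * (t / 0.55) ** 2)
    w = narrow - 0.55 * broad
    return w


def _half_sine(n: int) -> np.ndarray:
    return np.sin(np.pi * np.arange(n) / max(n - 1, 1))


def make_transient(spec: TransientSpec, fs: float) -> np.ndarray:
    """Synthesize one transient waveform at sampling rate ``fs``.

    The returned length is the rounded sum of the component durations and the
    peak absolute amplitude equals ``spec.amplitude_uv`` (within rounding).
    """
    if spec.kind == "hfo_burst":
        min_fs = 2.0 * spec.carrier_hz
    else:
        min_fs = 2000.0 / spec.duration_ms  # need a few samples across the peak
    if fs < min_fs:
        raise ConfigError(f"fs={fs} too low for a {spec.kind} of {spec.duration_ms} ms")

    if spec.kind in ("spike", "sharp_wave"):
        w = _spiky_peak(_n_samples(spec.duration_ms, fs))
    elif spec.kind == "slow_wave":
        w = _half_sine(_n_samples(spec.duration_ms, fs))
    elif spec.kind == "spike_and_slow_wave":
        spike = _spiky_peak(_n_samples(spec.duration_ms, fs))
        slow = 0.5 * _half_sine(_n_samples(spec.slow_ms, fs))
        w = np.concatenate([spike, -slow])
    elif spec.kind == "polyspike":
        spike = _spiky_peak(_n_samples(spec.duration_ms, fs))
        w = np.concatenate([spike] * spec.n_spikes)
    elif spec.kind == "polyspike_and_slow_wave":
        spike = _spiky_peak(_n_samples(spec.duration_ms, fs))
        slow = 0.5 * _half_sine(_n_samples(spec.slow_ms, fs))
        w = np.concatenate([spike] * spec.n_spikes + [-slow])
    elif spec.kind == "hfo_burst":
        n = _n_samples(spec.duration_ms, fs)
        t = np.arange(n) / fs
        w = np.hanning(n) * np.sin(2 * np.pi * spec.carrier_hz * t)
    else:  # pragma: no cover - guarded in TransientSpec
        raise ConfigError(spec.kind)
    peak = np.max(np.abs(w))
    return spec.polarity * spec.amplitude_uv * w / peak


# ---------------------------------------------------------------------------
# background


def generate_background(
    fs: float,
    duration_s: float,
    beta: float = 2.0,
    band_amps: dict | None = None,
    sigma: float = 20.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Colored-noise background with optional narrowband oscillations.

    White Gaussian noise is spectrally shaped to a 1/f^beta power spectrum,
    rescaled to standard deviation ``sigma``, then sinusoids with random
    frequency (uniform within each named band) and phase are added with the
    requested amplitudes.
    """
    if beta < 0:
        raise ConfigError("beta must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    white = rng.standard_normal(n)
    if beta > 0:
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        scale = np.ones_like(freqs)
        nonzero = freqs > 0
        scale[nonzero] = freqs[nonzero] ** (-beta / 2.0)
        scale[0] = 0.0
        x = np.fft.irfft(spec * scale, n=n)
    else:
        x = white
    sd = np.std(x)
    if sd > 0:
        x = x * (sigma / sd)
    t = np.arange(n) / fs
    for name, amp in (band_amps or {}).items():
        lo, hi = _BAND_RANGES.get(name, (None, None))
        if lo is None:
            raise ConfigError(f"unknown oscillation band {name!r}")
        f = rng.uniform(lo, hi)
        phase = rng.uniform(0, 2 * np.pi)
        x = x + amp * np.sin(2 * np.pi * f * t + phase)
    return x


# ---------------------------------------------------------------------------
# full recording


def _draw_spec(cfg: SynthConfig, rng: np.random.Generator) -> TransientSpec:
    kinds = sorted(cfg.kind_mixture)
    probs = np.array([cfg.kind_mixture[k] for k in kinds], dtype=float)
    kind = kinds[rng.choice(len(kinds), p=probs / probs.sum())]
    amp = cfg.event_amp_uv * float(
        np.clip(1.0 + cfg.event_amp_jitter * rng.standard_normal(), 0.3, 3.0)
    )
    polarity = 1 if rng.random() < 0.7 else -1
    if kind == "sharp_wave":
        dur = rng.uniform(80.0, 180.0)
    elif kind == "slow_wave":
        dur = rng.uniform(150.0, 400.0)
    elif kind == "hfo_burst":
        dur = rng.uniform(60.0, 120.0)
    else:
        dur = rng.uniform(25.0, 65.0)
    carrier_cap = min(240.0, 0.4 * cfg.fs)
    return TransientSpec(
        kind=kind,
        duration_ms=dur,
        amplitude_uv=amp,
        polarity=polarity,
        slow_ms=rng.uniform(250.0, 350.0),
        n_spikes=int(rng.integers(2, 4)),
        carrier_hz=rng.uniform(90.0, max(91.0, carrier_cap)),
    )


def _place_events(
    x: np.ndarray,
    cfg: SynthConfig,
    rate_per_min: float,
    rng: np.random.Generator,
) -> list[tuple[float, TransientSpec]]:
    """Add Poisson-count events at uniform non-overlapping onsets, in place."""
    n = len(x)
    n_events = int(rng.poisson(rate_per_min * cfg.duration_s / 60.0))
    occupied: list[tuple[int, int]] = []
    placed: list[tuple[float, TransientSpec]] = []
    for _ in range(n_events):
        spec = _draw_spec(cfg, rng)
        w = make_transient(spec, cfg.fs)
        if len(w) >= n:
            continue
        for _try in range(200):
            i0 = int(rng.integers(0, n - len(w)))
            i1 = i0 + len(w)
            if all(i1 <= a or i0 >= b for a, b in occupied):
                x[i0:i1] += w
                occupied.append((i0, i1))
                placed.append((i0 / cfg.fs, spec))
                break
    placed.sort(key=lambda p: p[0])
    return placed


def generate_recording(cfg: SynthConfig) -> tuple[Recording, EventLog]:
    """Generate a labeled recording plus its exact ground-truth event log.

    Deterministic given ``cfg`` (seed included). SOZ channels come first in
    channel order, named ``soz0..`` / ``bg0..``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_ch = cfg.n_soz + cfg.n_nonsoz
    if n_ch < 1:
        raise ConfigError("need at least one channel")
    channel_ids = [f"soz{i}" for i in range(cfg.n_soz)] + [
        f"bg{i}" for i in range(cfg.n_nonsoz)
    ]
    labels = [SOZ] * cfg.n_soz + [NONSOZ] * cfg.n_nonsoz
    n = int(round(cfg.duration_s * cfg.fs))
    signal = np.empty((n_ch, n))
    log = EventLog()
    for ci, cid in enumerate(channel_ids):
        signal[ci] = generate_background(
            cfg.fs,
            cfg.duration_s,
            beta=cfg.noise_exponent,
            band_amps=cfg.band_amps,
            sigma=cfg.noise_sigma_uv,
            seed=rng,
        )
        rate = (
            cfg.soz_event_rate_per_min
            if labels[ci] == SOZ
            else cfg.nonsoz_event_rate_per_min
        )
        for onset, spec in _place_events(signal[ci], cfg, rate, rng):
            log.events.append((cid, onset, spec))
    rec = Recording(
        signal=signal, fs=cfg.fs, channel_ids=channel_ids, channel_labels=labels
    )
    return rec, log


def write_event_log(log: EventLog, path) -> None:
    """Persist an event log as a csv (channel, onset, kind, duration, amplitude)."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "channel_id": c,
                "onset_s": t,
                "kind": s.kind,
                "duration_ms": s.duration_ms,
                "amplitude_uv": s.amplitude_uv,
                "polarity": s.polarity,
            }
            for c, t, s in log.events
        ],
        columns=["channel_id", "onset_s", "kind", "duration_ms", "amplitude_uv", "polarity"],
    ).to_csv(path, index=False)
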