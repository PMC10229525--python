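"""Minimal EDF writer used only to construct test fixtures.

Writes plain EDF (16-bit) with one data record per second. Kept independent
of the package's reader so files act as an external oracle of the format.
"""

from __future__ import annotations

import numpy as np


def _pad(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path,
    signals: np.ndarray,
    fs: int,
    channel_names: list[str] | None = None,
    samples_per_record: list[int] | None = None,
) -> None:
    """Write ``signals`` (channels x samples) at integer ``fs`` Hz.

    ``samples_per_record`` overrides the per-signal samples in each 1-second
    record, allowing deliberately inconsistent files to be produced.
    """
    signals = np.asarray(signals, dtype=float)
    n_sig, n_samp = signals.shape
    if channel_names is None:
        channel_names = [f"EEG ch{i}" for i in range(n_sig)]
    if samples_per_record is None:
        samples_per_record = [fs] * n_sig
    n_records = n_samp // fs

    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767
    gain = (phys_max - phys_min) / (dig_max - dig_min)

    header = b"".join(
        [
            _pad("0", 8),
            _pad("synthetic test subject", 80),
            _pad("synthetic test recording", 80),
            _pad("01.01.20", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + n_sig)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(n_sig), 4),
        ]
    )
    fields = [
        (channel_names, 16),
        (["" for _ in range(n_sig)], 80),  # transducer
        (["uV"] * n_sig, 8),
        ([f"{phys_min:g}"] * n_sig, 8),
        ([f"{phys_max:g}"] * n_sig, 8),
        ([str(dig_min)] * n_sig, 8),
        ([str(dig_max)] * n_sig, 8),
        (["" for _ in range(n_sig)], 80),  # prefilter
        ([str(n) for n in samples_per_record], 8),
        (["" for _ in range(n_sig)], 32),
    ]
    sig_header = b"".join(
        b"".join(_pad(v, width) for v in values) for values, width in fields
    )

    digital = np.clip(np.round(signals / gain), dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for rec in range(n_records):
            for si in range(n_sig):
                nper = samples_per_record[si]
                chunk = digital[si, rec * nper:(rec + 1) * nper]
                if len(chunk) < nper:
                    chunk = np.pad(chunk, (0, nper - len(chunk)))
                fh.write(chunk.tobytes())
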