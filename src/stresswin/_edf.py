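"""Minimal plain-EDF (16-bit) writer and header utilities.

Only what :mod:`stresswin.eeg_io` needs: continuous equal-rate signals, one
physical dimension per channel, no EDF+ annotation channel.  Reading goes
through :mod:`mne`; this module only writes files and inspects headers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

# symmetric digital range so a physical zero is exactly representable
_DIG_MIN = -32767
_DIG_MAX = 32767
# largest physical-extreme magnitude that still fits the 8-char ASCII field
_MAX_PHYS = 9.9e7
# EDF recommendation: data records should stay below 61440 bytes
_MAX_RECORD_SAMPLES = 1536


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _num_field(value: float, width: int) -> bytes:
    for fmt in (f"{value:g}", f"{value:.{max(width - 6, 0)}g}", f"{value:.2g}"):
        if len(fmt) <= width:
            return fmt.ljust(width).encode("ascii")
    raise ValueError(f"cannot format {value} in {width} EDF header chars")


def _choose_record_size(n_samples: int) -> int:
    for spr in range(min(_MAX_RECORD_SAMPLES, n_samples), 0, -1):
        if n_samples % spr == 0:
            return spr
    return 1


def write_edf(
    path: str | Path,
    data: np.ndarray,
    sampling_rate: float,
    channel_names: list[str],
    physical_dimension: str = "uV",
) -> None:
    """Write ``data`` ([n_channels x n_samples], physical units) as 16-bit EDF.

    The physical range is set per file to cover the data symmetrically, so the
    quantisation step is ``range / 65535``.  Values too large for the header's
    8-character extreme fields raise instead of being clipped.
    """
    path = Path(path)
    data = np.asarray(data, dtype=np.float64)
    n_channels, n_samples = data.shape
    if len(channel_names) != n_channels:
        raise ValueError("channel_names length must match data")

    abs_max = float(np.max(np.abs(data))) if data.size else 0.0
    if abs_max > _MAX_PHYS:
        raise ValueError(
            f"signal amplitude {abs_max:g} {physical_dimension} exceeds the EDF-representable range"
        )
    phys_max = abs_max if abs_max > 0 else 1.0
    phys_min = -phys_max

    spr = _choose_record_size(n_samples)
    n_records = n_samples // spr
    record_duration = spr / sampling_rate

    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate X X X X", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 * (1 + n_channels)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _num_field(record_duration, 8),
            _field(str(n_channels), 4),
        ]
    )
    header += b"".join(_field(name, 16) for name in channel_names)
    header += b"".join(_field("", 80) for _ in channel_names)  # transducer
    header += b"".join(_field(physical_dimension, 8) for _ in channel_names)
    header += b"".join(_num_field(phys_min, 8) for _ in channel_names)
    header += b"".join(_num_field(phys_max, 8) for _ in channel_names)
    header += b"".join(_field(str(_DIG_MIN), 8) for _ in channel_names)
    header += b"".join(_field(str(_DIG_MAX), 8) for _ in channel_names)
    header += b"".join(_field("", 80) for _ in channel_names)  # prefiltering
    header += b"".join(_field(str(spr), 8) for _ in channel_names)
    header += b"".join(_field("", 32) for _ in channel_names)

    # physical -> digital, matching the EDF linear mapping readers invert
    scale = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.round((data - phys_min) * scale + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        # records are channel-major within each record
        records = digital.reshape(n_channels, n_records, spr)
        for r in range(n_records):
            fh.write(records[:, r, :].tobytes())


def read_physical_dimensions(path: str | Path) -> list[str]:
    """Return the per-channel physical-dimension strings from an EDF header."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_channels = int(head[252:256].decode("ascii").strip())
        sig = fh.read(256 * n_channels)
    off = (16 + 80) * n_channels
    dims = []
    for i in range(n_channels):
        raw = sig[off + 8 * i : off + 8 * (i + 1)]
        dims.append(raw.decode("ascii").strip())
    return dims
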