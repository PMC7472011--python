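"""Reading and writing multi-channel EEG recordings.

The package works on a fixed 19-channel subset of the international 10-20
montage.  Two on-disk formats are supported:

* **EDF** (European Data Format, 16-bit): read through :mod:`mne`, written by
  a small built-in plain-EDF encoder.  Subject id and condition annotations
  travel in a JSON sidecar next to the ``.edf`` file.
* **Delimited text**: one row per sample, one column per channel, header row
  of channel labels, with the same JSON sidecar carrying sampling rate,
  subject id and annotations.

All downstream modules consume only :class:`Recording`; the internal unit is
microvolts throughout.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import _edf

logger = logging.getLogger(__name__)

#: Canonical order of the 19 scalp electrodes used throughout the package.
CHANNELS_1020 = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "C3", "C4", "T3", "T4",
    "T5", "T6", "P3", "P4", "O1", "O2", "Fz", "Cz", "Pz",
)

#: Left/right homologous electrode pairs (midline electrodes have none).
LEFT_RIGHT_PAIRS = (
    ("Fp1", "Fp2"), ("F3", "F4"), ("F7", "F8"), ("C3", "C4"),
    ("T3", "T4"), ("T5", "T6"), ("P3", "P4"), ("O1", "O2"),
)

VALID_ANNOTATION_LABELS = ("relax", "stress_task")


@dataclass(frozen=True)
class Montage:
    """Ordered electrode set with its left/right homologue pairing."""

    channel_names: tuple[str, ...] = CHANNELS_1020
    left_right_pairs: tuple[tuple[str, str], ...] = LEFT_RIGHT_PAIRS

    def __post_init__(self) -> None:
        names = self.channel_names
        if len(names) != 19:
            raise ValueError(f"montage must have exactly 19 channels, got {len(names)}")
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        for required in ("Fp1", "Fp2"):
            if required not in names:
                raise ValueError(f"montage must contain {required}")
        for left, right in self.left_right_pairs:
            if left not in names or right not in names:
                raise ValueError(f"pair ({left}, {right}) not in montage")

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None


@dataclass
class Recording:
    """One subject's continuous 19-channel EEG in microvolts.

    ``data`` is ``[n_channels x n_samples]``; ``annotations`` is a list of
    ``(label, start_s, end_s)`` marking the relax / stress-task conditions.
    Absent annotations mean labels come solely from the alpha-asymmetry score.
    """

    subject_id: str
    data: np.ndarray
    sampling_rate: float = 500.0
    montage: Montage = field(default_factory=Montage)
    annotations: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.montage.channel_names):
            raise ValueError(
                f"data must be [{len(self.montage.channel_names)} x n_samples], got shape {self.data.shape}"
            )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf samples")
        duration = self.data.shape[1] / self.sampling_rate
        for label, start, end in self.annotations:
            if label not in VALID_ANNOTATION_LABELS:
                raise ValueError(f"unknown annotation label {label!r}")
            if not (0.0 <= start < end <= duration + 1e-9):
                raise ValueError(f"annotation ({label}, {start}, {end}) outside [0, {duration:.3f}]")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's samples by 10-20 label."""
        return self.data[self.montage.index(name)]

    def copy_with(self, **kwargs) -> "Recording":
        out = replace(self, **kwargs)
        return out


# ---------------------------------------------------------------------------
# sidecar metadata


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(rec: Recording, path: Path, extra: dict | None = None) -> None:
    meta = {
        "subject_id": rec.subject_id,
        "sampling_rate": rec.sampling_rate,
        "annotations": [[label, start, end] for label, start, end in rec.annotations],
    }
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if sc.exists():
        return json.loads(sc.read_text())
    return {}


# ---------------------------------------------------------------------------
# read / write


def write_recording(rec: Recording, path: str | Path, format: str = "edf") -> None:
    """Write a :class:`Recording` to ``path`` in ``edf`` or ``delimited`` format.

    EDF uses standard 16-bit encoding with a physical range covering the data;
    values outside the representable EDF range raise instead of clipping.
    """
    path = Path(path)
    if format == "edf":
        _edf.write_edf(
            path,
            rec.data,
            sampling_rate=rec.sampling_rate,
            channel_names=list(rec.montage.channel_names),
            physical_dimension="uV",
        )
        _write_sidecar(rec, path)
    elif format == "delimited":
        frame = pd.DataFrame(rec.data.T, columns=list(rec.montage.channel_names))
        frame.to_csv(path, index=False)
        _write_sidecar(rec, path)
    else:
        raise ValueError(f"unsupported format {format!r}; expected 'edf' or 'delimited'")


_UNIT_TO_UV = {"uv": 1.0, "µv": 1.0, "mv": 1e3, "v": 1e6}


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read an EDF or delimited recording into canonical montage order.

    Extra channels beyond the 19-channel montage are dropped with a warning;
    a *missing* montage channel is a hard error naming the absent labels.
    The sampling rate comes from the EDF header or from the sidecar metadata
    for delimited files; non-microvolt EDF physical dimensions (mV, V) are
    converted to microvolts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"

    meta = _read_sidecar(path)
    if format == "edf":
        data, sampling_rate, labels = _read_edf(path)
    elif format == "delimited":
        frame = pd.read_csv(path)
        labels = [str(c) for c in frame.columns]
        data = frame.to_numpy(dtype=np.float64).T
        if "sampling_rate" not in meta:
            raise ValueError(f"delimited recording {path} has no sidecar with sampling_rate")
        sampling_rate = float(meta["sampling_rate"])
    else:
        raise ValueError(f"unsupported format {format!r}; expected 'edf' or 'delimited'")

    montage = Montage()
    label_map = {lab.strip().lower(): i for i, lab in enumerate(labels)}
    missing = [name for name in montage.channel_names if name.lower() not in label_map]
    if missing:
        raise ValueError(f"recording {path} is missing montage channels: {', '.join(missing)}")
    extra = [lab for lab in labels if lab.strip().lower() not in {n.lower() for n in montage.channel_names}]
    if extra:
        logger.warning("dropping %d non-montage channels from %s: %s", len(extra), path, extra)

    order = [label_map[name.lower()] for name in montage.channel_names]
    data = data[order]

    annotations = [tuple(a) for a in meta.get("annotations", [])]
    annotations = [(str(lab), float(s), float(e)) for lab, s, e in annotations]
    return Recording(
        subject_id=str(meta.get("subject_id", path.stem)),
        data=data,
        sampling_rate=sampling_rate,
        montage=montage,
        annotations=annotations,
    )


def _read_edf(path: Path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file via mne; returns (data_uV, sfreq, labels).

    The EDF physical-dimension field is checked per channel: uV/mV/V are all
    converted to the package's internal microvolt unit; an unrecognised
    dimension is taken as already-microvolt raw units.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    sfreq = float(raw.info["sfreq"])
    dims = _edf.read_physical_dimensions(path)
    data_v = raw.get_data()  # volts for volt-family dims, raw units otherwise
    data = np.empty_like(data_v)
    for i, dim in enumerate(dims):
        key = dim.strip().lower()
        if key in _UNIT_TO_UV:
            data[i] = data_v[i] * 1e6  # volts -> microvolts
        else:
            data[i] = data_v[i]
    return data, sfreq, labels
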