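"""Recording / annotation data model and on-disk formats.

EEG recordings are held in memory as a channels x samples matrix in
microvolts together with the sampling rate, channel labels and named time
markers (e.g. the convulsant-injection time).  On disk, recordings are
stored as 16-bit EDF (European Data Format) with per-channel physical
min/max; annotations are a plain CSV with columns
``label,start_s,end_s,stage``.

Reading EDF goes through :mod:`mne`; writing is done by a small EDF writer
(integer-second records, one data record per second).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "AnnotationTable",
    "read_edf",
    "write_edf",
    "read_annotations",
    "write_annotations",
    "FormatError",
]

#: Electrode montage used throughout: bilateral hippocampus plus frontal and
#: occipital cortex screws.
DEFAULT_CHANNELS = ("Lt FC", "Lt HC", "Rt HC", "Rt OC")

RACINE_STAGES = frozenset(range(6))


class FormatError(ValueError):
    """Raised for malformed or unsupported on-disk files."""


@dataclass
class Recording:
    """A multichannel EEG recording in microvolts.

    Attributes
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        EEG in µV.
    fs : float
        Sampling rate in Hz.
    channels : tuple of str
        Channel labels.
    markers : list of (str, float)
        Named time points in seconds from recording start
        (e.g. ``("injection", 3600.0)``).
    start : datetime
        Wall-clock start time (defaults to a fixed epoch so synthetic
        recordings are reproducible byte-for-byte).
    """

    signal: np.ndarray
    fs: float
    channels: tuple = DEFAULT_CHANNELS
    markers: list = field(default_factory=list)
    start: _dt.datetime = _dt.datetime(2000, 1, 1, 9, 0, 0)

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.signal.shape[0]} signal rows but "
                f"{len(self.channels)} channel labels"
            )
        for label, t in self.markers:
            if not 0 <= t <= self.duration:
                raise ValueError(f"marker {label!r} at {t} s outside recording")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.signal.shape[1] / self.fs

    def marker_time(self, label: str) -> float:
        """Time of the first marker with the given label.

        Raises
        ------
        KeyError
            If no marker with that label exists.
        """
        for lab, t in self.markers:
            if lab == label:
                return float(t)
        raise KeyError(f"no marker {label!r} in recording")

    def segment(self, start_s: float, end_s: float) -> np.ndarray:
        """View of the signal between two times (seconds), all channels."""
        i0 = max(0, int(round(start_s * self.fs)))
        i1 = min(self.n_samples, int(round(end_s * self.fs)))
        return self.signal[:, i0:i1]

    def copy(self) -> "Recording":
        return replace(self, signal=self.signal.copy(),
                       markers=list(self.markers))


@dataclass
class AnnotationTable:
    """Behavioral annotations: labeled intervals with optional Racine stage.

    ``stage`` is an integer 0–5 or ``None`` for unknown.
    """

    rows: list = field(default_factory=list)  # (label, start_s, end_s, stage)

    def __post_init__(self):
        for label, start, end, stage in self.rows:
            if start < 0 or end < 0:
                raise ValueError(f"negative time in annotation {label!r}")
            if end < start:
                raise ValueError(
                    f"annotation {label!r}: end {end} < start {start}")
            if stage is not None and stage not in RACINE_STAGES:
                raise ValueError(f"Racine stage {stage!r} out of range")

    def __len__(self):
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def overlapping(self, start_s: float, end_s: float):
        """Annotations whose interval overlaps [start_s, end_s]."""
        return [r for r in self.rows if r[1] <= end_s and r[2] >= start_s]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["label", "start_s", "end_s", "stage"])


# ---------------------------------------------------------------------------
# EDF writing (16-bit, one-second data records)
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: Recording, path) -> None:
    """Write a recording as 16-bit EDF.

    Uses one-second data records, so the recording is zero-padded to a whole
    number of seconds.  Physical min/max are set per channel from the data
    (symmetric about zero), which fixes the quantization step at
    ``(phys_max - phys_min) / (2**16 - 1)`` µV.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec = int(np.ceil(rec.n_samples / fs))
    sig = np.zeros((rec.n_channels, n_rec * fs))
    sig[:, : rec.n_samples] = rec.signal

    dig_min, dig_max = -32768, 32767
    phys_max = np.maximum(np.abs(sig).max(axis=1), 1.0)
    phys_min = -phys_max

    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate X X X X", 80),
        _pad(rec.start.strftime("%d.%m.%y"), 8),
        _pad(rec.start.strftime("%H.%M.%S"), 8),
        _pad(str(256 * (1 + rec.n_channels)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(rec.n_channels), 4),
    ])
    per_sig = b"".join([
        b"".join(_pad(lab, 16) for lab in rec.channels),
        b"".join(_pad("EEG screw", 80) for _ in rec.channels),
        b"".join(_pad("uV", 8) for _ in rec.channels),
        b"".join(_pad(f"{phys_min[c]:.7g}"[:8], 8)
                 for c in range(rec.n_channels)),
        b"".join(_pad(f"{phys_max[c]:.7g}"[:8], 8)
                 for c in range(rec.n_channels)),
        b"".join(_pad(str(dig_min), 8) for _ in rec.channels),
        b"".join(_pad(str(dig_max), 8) for _ in rec.channels),
        b"".join(_pad("BP 1-100 Hz", 80) for _ in rec.channels),
        b"".join(_pad(str(fs), 8) for _ in rec.channels),
        b"".join(_pad("", 32) for _ in rec.channels),
    ])

    # physical -> digital, one record at a time
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((sig - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_sig)
        for r in range(n_rec):
            chunk = digital[:, r * fs: (r + 1) * fs]
            fh.write(chunk.tobytes())


def read_edf(path) -> Recording:
    """Read an EDF file into a :class:`Recording` (signal in µV)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size < 256:
        raise FormatError(f"{path} is not a valid EDF file (truncated header)")
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on bad headers
        raise FormatError(f"could not parse {path} as EDF: {exc}") from exc
    sfreqs = {int(round(raw.info["sfreq"]))}
    if len(sfreqs) != 1:
        raise FormatError("mixed per-channel sampling rates are unsupported")
    signal_uv = raw.get_data() * 1e6  # mne returns volts
    meas = raw.info.get("meas_date")
    start = (meas.replace(tzinfo=None) if meas is not None
             else _dt.datetime(2000, 1, 1))
    return Recording(
        signal=signal_uv,
        fs=float(raw.info["sfreq"]),
        channels=tuple(raw.ch_names),
        start=start,
    )


def edf_quantization_step(rec: Recording) -> np.ndarray:
    """Per-channel physical size of one digital unit for :func:`write_edf`."""
    phys_max = np.maximum(np.abs(rec.signal).max(axis=1), 1.0)
    return 2 * phys_max / (2 ** 16 - 1)


# ---------------------------------------------------------------------------
# Annotation CSV
# ---------------------------------------------------------------------------

def read_annotations(path) -> AnnotationTable:
    """Read an annotation CSV (``label,start_s,end_s[,stage]``).

    A missing or empty stage column yields unknown stages (``None``).
    """
    df = pd.read_csv(path)
    required = {"label", "start_s", "end_s"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"annotation file missing columns {sorted(required - set(df.columns))}")
    rows = []
    for _, row in df.iterrows():
        stage = None
        if "stage" in df.columns and pd.notna(row["stage"]):
            stage = int(row["stage"])
        rows.append((str(row["label"]), float(row["start_s"]),
                     float(row["end_s"]), stage))
    return AnnotationTable(rows)


def write_annotations(ann: AnnotationTable, path) -> None:
    ann.to_frame().to_csv(path, index=False)
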