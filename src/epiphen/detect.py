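"""Electrographic seizure detection.

A seizure is operationally defined as a period of rhythmic (>3 Hz)
deflections exceeding twice the standard deviation of the baseline, lasting
at least 10 s.  The rhythmicity criterion is implemented as a
suprathreshold-deflection *rate*: a sample is "active" on a channel when the
centered 1-s window around it contains more than ``rhythm_hz``
sign-alternating deflections beyond ``amp_k`` baseline SDs.  Active spans
are merged across short gaps per channel, combined across channels, and
filtered by the minimum duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .amplitude import deflection_times, mean_peak_to_trough
from .eeg_io import AnnotationTable, Recording

__all__ = [
    "BaselineStats",
    "DetectorParams",
    "SeizureEvent",
    "baseline_stats",
    "detect_seizures",
    "label_convulsive",
    "events_to_frame",
]


@dataclass(frozen=True)
class BaselineStats:
    """Per-channel baseline statistics from an artifact-free window."""

    mean: np.ndarray          # µV
    sd: np.ndarray            # µV
    mean_p2t: np.ndarray      # mean peak-to-trough amplitude, µV
    window: tuple             # (start_s, end_s)

    def __post_init__(self):
        if np.any(self.sd < 0):
            raise ValueError("baseline SD must be non-negative")


@dataclass(frozen=True)
class DetectorParams:
    """Seizure-detector thresholds.

    Defaults encode the operational definition: amplitude beyond 2 baseline
    SDs, deflection rate above 3 per second, and at least 10 s duration.
    """

    amp_k: float = 2.0
    rhythm_hz: float = 3.0
    min_dur_s: float = 10.0
    merge_gap_s: float = 2.0
    active_window_s: float = 1.0
    channel_rule: str = "any"      # "any" or "all"

    def __post_init__(self):
        for name in ("amp_k", "rhythm_hz", "min_dur_s", "merge_gap_s",
                     "active_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.channel_rule not in ("any", "all"):
            raise ValueError(f"unknown channel rule {self.channel_rule!r}")


@dataclass
class SeizureEvent:
    """A detected ictal interval."""

    onset_s: float
    offset_s: float
    channels: tuple = ()
    peak_uv: float = np.nan           # largest deflection from baseline mean
    deflection_rate_hz: float = np.nan
    stage: int | None = None          # Racine stage from annotations
    convulsive: bool = False

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def baseline_stats(rec: Recording, window: tuple,
                   annotations: AnnotationTable | None = None) -> BaselineStats:
    """Per-channel mean, SD and mean peak-to-trough over a baseline window.

    Parameters
    ----------
    window : (start_s, end_s)
        Artifact-free segment used as baseline.
    annotations : optional
        If given, the window is refused when it overlaps any annotated event.
    """
    start, end = window
    if not (0 <= start < end <= rec.duration + 1e-9):
        raise ValueError(f"baseline window {window} outside recording")
    if annotations is not None and annotations.overlapping(start, end):
        raise ValueError(
            f"baseline window {window} overlaps an annotated event")
    seg = rec.segment(start, end)
    p2t = np.array([mean_peak_to_trough(seg[c]) for c in range(rec.n_channels)])
    return BaselineStats(
        mean=seg.mean(axis=1),
        sd=seg.std(axis=1),
        mean_p2t=p2t,
        window=(float(start), float(end)),
    )


def _runs(mask: np.ndarray) -> np.ndarray:
    """(start, stop) index pairs of True runs; stop is exclusive."""
    if not mask.any():
        return np.empty((0, 2), dtype=np.intp)
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return edges.reshape(-1, 2)


def _merge_runs(runs: np.ndarray, max_gap: int) -> np.ndarray:
    """Merge runs separated by fewer than ``max_gap`` samples."""
    if len(runs) < 2:
        return runs
    merged = [list(runs[0])]
    for start, stop in runs[1:]:
        if start - merged[-1][1] < max_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    return np.asarray(merged, dtype=np.intp)


def _active_mask(x: np.ndarray, fs: float, mean: float, threshold: float,
                 rhythm_hz: float, window_s: float) -> tuple:
    """Boolean activity per sample plus the deflection index list."""
    defl = deflection_times(x, mean, threshold)
    n = x.size
    if defl.size == 0:
        return np.zeros(n, dtype=bool), defl
    half = int(round(window_s * fs / 2))
    t = np.arange(n)
    counts = (np.searchsorted(defl, t + half, side="right")
              - np.searchsorted(defl, t - half, side="left"))
    # one full rhythm cycle contributes two alternating deflections (one
    # above, one below the mean), so a rhythm frequency above rhythm_hz
    # corresponds to more than 2*rhythm_hz deflections per second
    return counts > 2 * rhythm_hz * window_s, defl


def detect_seizures(rec: Recording, base: BaselineStats,
                    params: DetectorParams = DetectorParams()) -> list:
    """Detect seizures in a recording given baseline statistics.

    Returns a time-ordered list of disjoint :class:`SeizureEvent`.

    Raises
    ------
    ValueError
        If any channel has zero baseline SD (a zero threshold would mark
        every wiggle suprathreshold).
    """
    if np.any(base.sd <= 0):
        raise ValueError("zero baseline SD on at least one channel; "
                         "choose a different baseline window")
    fs = rec.fs
    gap = int(round(params.merge_gap_s * fs))
    masks, defls = [], []
    for c in range(rec.n_channels):
        mask, defl = _active_mask(
            rec.signal[c], fs, base.mean[c], params.amp_k * base.sd[c],
            params.rhythm_hz, params.active_window_s)
        runs = _merge_runs(_runs(mask), gap)
        filled = np.zeros(rec.n_samples, dtype=bool)
        for s, e in runs:
            filled[s:e] = True
        masks.append(filled)
        defls.append(defl)
    masks = np.asarray(masks)
    combined = masks.all(axis=0) if params.channel_rule == "all" \
        else masks.any(axis=0)
    events = []
    for s, e in _merge_runs(_runs(combined), gap):
        dur = (e - s) / fs
        if dur < params.min_dur_s:
            continue
        chans = tuple(rec.channels[c] for c in range(rec.n_channels)
                      if masks[c, s:e].any())
        seg = rec.signal[:, s:e]
        peak = float(np.abs(seg - base.mean[:, None]).max())
        n_defl = max(int(np.searchsorted(d, e) - np.searchsorted(d, s))
                     for d in defls)
        events.append(SeizureEvent(
            onset_s=s / fs, offset_s=e / fs, channels=chans, peak_uv=peak,
            deflection_rate_hz=n_defl / dur))
    return events


def label_convulsive(events: list, ann: AnnotationTable) -> list:
    """Attach Racine stages and convulsive flags from behavioral annotations.

    An event is convulsive iff an annotation of stage 3–5 overlaps its
    interval; otherwise it is non-convulsive.  The recorded stage is the
    highest overlapping stage (``None`` when no staged annotation overlaps).
    """
    labeled = []
    for ev in events:
        stages = [r[3] for r in ann.overlapping(ev.onset_s, ev.offset_s)
                  if r[3] is not None]
        stage = max(stages) if stages else None
        labeled.append(replace(
            ev, stage=stage, convulsive=bool(stage is not None and stage >= 3)))
    return labeled


def events_to_frame(events: list) -> pd.DataFrame:
    """Tabulate events for CSV/JSON export."""
    return pd.DataFrame([{
        "onset_s": ev.onset_s,
        "offset_s": ev.offset_s,
        "duration_s": ev.duration_s,
        "channels": "|".join(ev.channels),
        "peak_uv": ev.peak_uv,
        "deflection_rate_hz": ev.deflection_rate_hz,
        "stage": ev.stage,
        "convulsive": ev.convulsive,
    } for ev in events])
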