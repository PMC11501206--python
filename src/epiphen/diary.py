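"""Chronic-seizure diary metrics.

After epilepsy is established, seizures are binned into 24-h days over the
3-week monitoring period.  From the per-day counts this module derives the
severity measures used to compare groups: total count, frequency
(seizures/day), number of days with seizures, the maximum seizure-free
interval (longest run of zero-count days), seizure clusters (>1 consecutive
day with ≥3 seizures/day), per-cluster durations, and intercluster
intervals (whole days strictly between consecutive clusters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Diary",
    "ClusterSet",
    "bin_events_to_days",
    "summarize",
    "find_clusters",
    "duration_summaries",
    "raster",
]

SECONDS_PER_DAY = 86400.0


@dataclass
class Diary:
    """Per-day seizure counts and per-seizure durations for one subject."""

    counts: np.ndarray                 # seizures per day
    durations_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    subject: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        self.durations_s = np.asarray(self.durations_s, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("negative seizure count")
        if self.durations_s.size and self.durations_s.size != self.counts.sum():
            raise ValueError(
                f"{self.durations_s.size} durations for "
                f"{self.counts.sum()} seizures")

    @property
    def n_days(self) -> int:
        return self.counts.size


@dataclass
class ClusterSet:
    """Clusters of consecutive high-seizure days.

    ``clusters`` holds inclusive (start_day, end_day) pairs, 0-based.
    ``max_intercluster_days`` is ``nan`` when fewer than two clusters were
    captured in the recording period.
    """

    clusters: list
    durations_days: list
    intercluster_days: list
    max_intercluster_days: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def bin_events_to_days(events, n_days: int, day0_s: float = 0.0) -> Diary:
    """Bin detected seizure events into 24-h days from ``day0_s``.

    Day *i* holds events with onset in ``[i*86400, (i+1)*86400)`` seconds
    after ``day0_s`` (half-open bins).  Events outside the diary span are
    ignored.
    """
    counts = np.zeros(n_days, dtype=int)
    durations = []
    for ev in events:
        day = math.floor((ev.onset_s - day0_s) / SECONDS_PER_DAY)
        if 0 <= day < n_days:
            counts[day] += 1
            durations.append(ev.duration_s)
    return Diary(counts=counts, durations_s=np.array(durations))


def _zero_runs(counts: np.ndarray):
    runs, run = [], 0
    for c in counts:
        if c == 0:
            run += 1
        else:
            if run:
                runs.append(run)
            run = 0
    if run:
        runs.append(run)
    return runs


def summarize(d: Diary) -> dict:
    """Severity summary of a diary.

    Returns total seizures, frequency per day, days with seizures, the
    maximum seizure-free interval in days, and the mean seizure duration
    (``nan`` when the diary holds no seizures).
    """
    if d.n_days < 1:
        raise ValueError("diary must span at least one day")
    total = int(d.counts.sum())
    zero_runs = _zero_runs(d.counts)
    return {
        "total": total,
        "frequency_per_day": total / d.n_days,
        "days_with_seizures": int((d.counts > 0).sum()),
        "max_seizure_free_days": max(zero_runs) if zero_runs else 0,
        "mean_duration_s": float(d.durations_s.mean())
        if d.durations_s.size else float("nan"),
    }


def find_clusters(d: Diary, threshold: int = 3, min_run: int = 2) -> ClusterSet:
    """Find seizure clusters: runs of ≥ ``min_run`` days with ≥ ``threshold``
    seizures each.

    The intercluster interval between consecutive clusters is the number of
    whole days strictly between them; the maximum interval is reported only
    when at least two clusters fit in the recording period.
    """
    if threshold < 1:
        raise ValueError("cluster threshold must be ≥ 1")
    high = d.counts >= threshold
    clusters = []
    start = None
    for i, h in enumerate(np.append(high, False)):
        if h and start is None:
            start = i
        elif not h and start is not None:
            if i - start >= min_run:
                clusters.append((start, i - 1))
            start = None
    durations = [e - s + 1 for s, e in clusters]
    gaps = [clusters[i + 1][0] - clusters[i][1] - 1
            for i in range(len(clusters) - 1)]
    return ClusterSet(
        clusters=clusters,
        durations_days=durations,
        intercluster_days=gaps,
        max_intercluster_days=float(max(gaps)) if gaps else float("nan"),
    )


def duration_summaries(events_by_subject: dict):
    """Per-mouse mean durations and the pooled per-seizure duration list.

    Severity of individual seizures is compared two ways: once with every
    mouse as a data point (its mean seizure duration) and once with every
    seizure as a data point.  Subjects with no seizures contribute to
    neither.

    Parameters
    ----------
    events_by_subject : dict
        Maps subject id to a sequence of seizure durations in seconds.
    """
    per_mouse, pooled = {}, []
    for subject, durations in events_by_subject.items():
        durations = list(durations)
        if not durations:
            continue
        per_mouse[subject] = float(np.mean(durations))
        pooled.extend(float(x) for x in durations)
    return per_mouse, pooled


def raster(d: Diary, threshold: int = 3) -> np.ndarray:
    """Day-by-day raster codes: 0 no seizures, 1 below-threshold day,
    2 day with ≥ ``threshold`` seizures (cluster-eligible)."""
    codes = np.zeros(d.n_days, dtype=int)
    codes[d.counts > 0] = 1
    codes[d.counts >= threshold] = 2
    return codes
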