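"""Status-epilepticus day metrics and postictal depression scoring.

Quantifies the induction day: latency from the convulsant injection to the
first seizure, the seizure count in the first 2 h, the bounds and duration
of status epilepticus (SE), spectral band power in 20-min bins, and — for
any seizure, induction-day or chronic — the postictal depression (PID)
score.

Operational definitions
-----------------------
* SE onset: continuous seizure activity persisting >5 min with the 10-s
  amplitude envelope above 3× the baseline mean peak-to-trough amplitude on
  all four channels.
* SE end: the earliest time after onset at which the envelope on at least
  three channels stays at or below 50% of that channel's first-hour peak
  envelope for at least 10 consecutive minutes; the reported end is the
  start of that sustained depression.  (An alternative reading — envelope
  down to twice the pre-SE baseline amplitude — is available via
  ``end_mode="twice_baseline"``.)
* PID: the mean peak-to-trough amplitude 25–30 s before the seizure is
  compared with the mean amplitude during the maximal post-ictal
  depression; depression of more than half (ratio strictly below 0.5)
  counts as PID.  The maximal depression is located as the minimum 5-s
  window within 3 min after the seizure, then widened to the contiguous
  span of windows below 75% of the pre-ictal amplitude, and the mean
  amplitude is taken over that span.  (Averaging over the episode rather
  than reporting the minimal window avoids the downward order-statistic
  bias of a minimum over noisy window means, which would systematically
  misclassify depressions near the 50% boundary.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .amplitude import envelope, mean_peak_to_trough
from .detect import BaselineStats, SeizureEvent
from .eeg_io import Recording

__all__ = [
    "SEEpisode",
    "PIDResult",
    "BANDS_HZ",
    "latency_to_first_seizure",
    "count_seizures_2hr",
    "se_bounds",
    "band_power",
    "pid_score",
]

#: EEG frequency bands in Hz.  The low-gamma lower edge is taken as 30 Hz
#: (contiguous with beta).
BANDS_HZ = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "beta": (8.0, 30.0),
    "low_gamma": (30.0, 80.0),
    "high_gamma": (80.0, 100.0),
}

INJECTION_MARKER = "injection"


@dataclass
class SEEpisode:
    """Bounds of a status-epilepticus episode."""

    onset_s: float
    end_s: float
    resolved: bool
    peak_envelope_uv: np.ndarray      # per channel, first hour of SE
    baseline_p2t_uv: np.ndarray       # per channel

    @property
    def duration_min(self) -> float:
        return (self.end_s - self.onset_s) / 60.0


@dataclass
class PIDResult:
    """Postictal depression score for one seizure."""

    onset_s: float
    offset_s: float
    channel: int
    a_pre_uv: float
    a_post_uv: float
    scorable: bool = True

    @property
    def ratio(self) -> float:
        return self.a_post_uv / self.a_pre_uv

    @property
    def pid(self) -> bool:
        """True when the post-ictal amplitude fell below half the
        pre-ictal amplitude (strict inequality)."""
        return bool(self.scorable and self.a_post_uv < 0.5 * self.a_pre_uv)


def latency_to_first_seizure(events: list, rec: Recording) -> float:
    """Minutes from the injection marker to the first seizure onset.

    Returns ``nan`` when no seizure followed the injection; raises if the
    recording has no injection marker.
    """
    t_inj = rec.marker_time(INJECTION_MARKER)
    onsets = [ev.onset_s for ev in events if ev.onset_s >= t_inj]
    if not onsets:
        return float("nan")
    return (min(onsets) - t_inj) / 60.0


def count_seizures_2hr(events: list, rec: Recording) -> int:
    """Seizures with onset within 2 h after the injection marker.

    The interval is ``(t_inj, t_inj + 7200]`` — closed on the right, for
    determinism at the boundary.
    """
    t_inj = rec.marker_time(INJECTION_MARKER)
    return sum(1 for ev in events if t_inj < ev.onset_s <= t_inj + 7200.0)


def _merge_spans(spans, max_gap):
    merged = []
    for s, e in sorted(spans):
        if merged and s - merged[-1][1] < max_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return merged


def se_bounds(rec: Recording, events: list, base: BaselineStats,
              merge_gap_s: float = 2.0, min_continuous_s: float = 300.0,
              onset_amp_mult: float = 3.0, end_frac: float = 0.5,
              end_channels: int = 3, end_sustain_s: float = 600.0,
              end_mode: str = "half_peak") -> SEEpisode | None:
    """Locate status epilepticus in a recording.

    Requires detection to have been run (``events``) and baseline
    statistics.  Returns ``None`` when no qualifying onset exists (a
    "no SE" result, distinct from an error).
    """
    if end_mode not in ("half_peak", "twice_baseline"):
        raise ValueError(f"unknown SE end mode {end_mode!r}")
    fs = rec.fs
    envs, times = [], None
    for c in range(rec.n_channels):
        t, e = envelope(rec.signal[c], fs, window_s=10.0, hop_s=1.0)
        envs.append(e)
        times = t
    envs = np.asarray(envs)
    high_all = np.all(envs > onset_amp_mult * base.mean_p2t[:, None], axis=0)

    # candidate spans: merged detected events persisting > 5 min
    spans = _merge_spans([[ev.onset_s, ev.offset_s] for ev in events],
                         merge_gap_s)
    onset = None
    for s, e in spans:
        if e - s <= min_continuous_s:
            continue
        sel = (times >= s) & (times <= s + min_continuous_s)
        if sel.any() and high_all[sel].mean() >= 0.9:
            onset = s
            break
    if onset is None:
        return None

    hour = (times >= onset) & (times <= onset + 3600.0)
    peak = envs[:, hour].max(axis=1)
    if end_mode == "half_peak":
        ref = end_frac * peak
    else:
        ref = 2.0 * base.mean_p2t
    depressed = (envs <= ref[:, None]).sum(axis=0) >= end_channels
    depressed &= times >= onset

    end, resolved = rec.duration, False
    hop = times[1] - times[0] if times.size > 1 else 1.0
    need = int(np.ceil(end_sustain_s / hop))
    run = 0
    for i, d in enumerate(depressed):
        run = run + 1 if d else 0
        if run >= need:
            end = times[i - run + 1]
            resolved = True
            break
    # a depression running into the end of the recording also resolves the
    # episode only if it already lasted the required time; otherwise the
    # episode is unresolved and the end is the recording end
    return SEEpisode(onset_s=float(onset), end_s=float(end),
                     resolved=resolved, peak_envelope_uv=peak,
                     baseline_p2t_uv=base.mean_p2t.copy())


def band_power(rec: Recording, bin_s: float = 1200.0,
               start_s: float = 0.0, end_s: float | None = None,
               baseline_window: tuple | None = None,
               bands: dict = BANDS_HZ) -> pd.DataFrame:
    """Band power per consecutive time bin, channel and frequency band.

    Power is the integrated Welch power spectral density (2-s segments,
    50% overlap) over each band, in µV².  With ``baseline_window`` a
    baseline row (bin index −1) is computed identically on that window.
    """
    end_s = rec.duration if end_s is None else end_s
    rows = []

    def psd_rows(seg, bin_index):
        nper = int(round(2 * rec.fs))
        for c in range(rec.n_channels):
            f, pxx = sps.welch(seg[c], fs=rec.fs, nperseg=nper,
                               noverlap=nper // 2)
            df = f[1] - f[0]
            for name, (lo, hi) in bands.items():
                sel = (f >= lo) & (f < hi)
                rows.append({
                    "bin": bin_index, "channel": rec.channels[c],
                    "band": name, "power_uv2": float(pxx[sel].sum() * df),
                })

    if baseline_window is not None:
        psd_rows(rec.segment(*baseline_window), -1)
    nbins = int(np.floor((end_s - start_s) / bin_s))
    for b in range(nbins):
        seg = rec.segment(start_s + b * bin_s, start_s + (b + 1) * bin_s)
        psd_rows(seg, b)
    return pd.DataFrame(rows)


def pid_score(rec: Recording, event: SeizureEvent, all_events: list = (),
              pre_offset_s: tuple = (30.0, 25.0), search_s: float = 180.0,
              window_s: float = 5.0, depress_frac: float = 0.75,
              channel: int | None = None) -> PIDResult:
    """Score postictal depression for one seizure.

    ``a_pre`` is the mean peak-to-trough amplitude over the 25–30 s window
    before seizure onset.  ``a_post`` is the mean amplitude during the
    maximal depression within 3 min after seizure offset: consecutive 5-s
    windows of mean peak-to-trough amplitude locate the minimal window,
    which is widened to the contiguous run of windows below
    ``depress_frac`` × ``a_pre``, and ``a_post`` averages over that run.

    Postictal suppression is generalized, so by default amplitudes are
    averaged across all channels (``channel=None``), which roughly halves
    the sampling noise of the 5-s pre-ictal estimate; pass a channel index
    to score a single channel.  The result is marked unscorable when the
    pre-ictal window leaves the recording, overlaps another seizure, or is
    flat.
    """
    pre_start = event.onset_s - pre_offset_s[0]
    pre_end = event.onset_s - pre_offset_s[1]
    unscorable = PIDResult(event.onset_s, event.offset_s, channel=-1,
                           a_pre_uv=np.nan, a_post_uv=np.nan, scorable=False)
    if pre_start < 0 or event.offset_s + window_s > rec.duration:
        return unscorable
    for other in all_events:
        if other is event:
            continue
        if other.onset_s < pre_end and other.offset_s > pre_start:
            return unscorable

    chans = range(rec.n_channels) if channel is None else [channel]

    def amp(t_start, t_stop):
        j0, j1 = int(t_start * rec.fs), int(t_stop * rec.fs)
        return float(np.mean([mean_peak_to_trough(rec.signal[c, j0:j1])
                              for c in chans]))

    a_pre = amp(pre_start, pre_end)
    if a_pre <= 0:
        return unscorable

    t0 = event.offset_s
    t_end = min(t0 + search_s, rec.duration)
    window_amps, window_starts = [], []
    t = t0
    while t + window_s <= t_end + 1e-9:
        window_amps.append(amp(t, t + window_s))
        window_starts.append(t)
        t += window_s
    if not window_amps:
        return unscorable
    window_amps = np.asarray(window_amps)
    i_min = int(np.argmin(window_amps))
    depressed = window_amps < depress_frac * a_pre
    lo = hi = i_min
    if depressed[i_min]:
        while lo > 0 and depressed[lo - 1]:
            lo -= 1
        while hi < len(window_amps) - 1 and depressed[hi + 1]:
            hi += 1
    a_post = amp(window_starts[lo], window_starts[hi] + window_s)
    return PIDResult(event.onset_s, event.offset_s,
                     channel=-1 if channel is None else channel,
                     a_pre_uv=a_pre, a_post_uv=a_post)
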