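"""Peak-to-trough amplitude primitives.

The amplitude measure used throughout is the *peak-to-trough excursion*: the
vertical distance between consecutive local extrema of the raw trace.  Its
mean over a window serves as the amplitude envelope, and suprathreshold
excursions that alternate in sign about the baseline mean are the
"deflections" counted by the seizure detector.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "local_extrema",
    "excursions",
    "mean_peak_to_trough",
    "envelope",
    "deflection_times",
]


def local_extrema(x: np.ndarray) -> np.ndarray:
    """Indices of local extrema (turning points) of a 1-D signal.

    Plateaus count once, at the sample where the monotone run ends.  A
    constant signal has no extrema.
    """
    x = np.asarray(x, dtype=float)
    d = np.diff(x)
    nz = np.flatnonzero(d)
    if nz.size < 2:
        return np.empty(0, dtype=np.intp)
    s = np.sign(d[nz])
    turn = np.flatnonzero(s[1:] != s[:-1])
    return nz[turn] + 1


def excursions(x: np.ndarray):
    """Consecutive max→min / min→max excursion amplitudes of a 1-D signal.

    Returns
    -------
    idx : ndarray of int
        Sample index of the *end* extremum of each excursion.
    amp : ndarray of float
        Absolute vertical distance between the two extrema.
    """
    ext = local_extrema(x)
    if ext.size < 2:
        return np.empty(0, dtype=np.intp), np.empty(0)
    vals = x[ext]
    return ext[1:], np.abs(np.diff(vals))


def mean_peak_to_trough(x: np.ndarray) -> float:
    """Mean peak-to-trough excursion amplitude of a 1-D signal.

    Returns 0.0 for signals with fewer than two extrema (e.g. constant or
    monotone segments).
    """
    _, amp = excursions(np.asarray(x, dtype=float))
    return float(amp.mean()) if amp.size else 0.0


def envelope(x: np.ndarray, fs: float, window_s: float = 10.0,
             hop_s: float = 1.0):
    """Sliding-window mean peak-to-trough amplitude of a 1-D signal.

    Windows of ``window_s`` seconds are centered on a grid with ``hop_s``
    spacing.  Windows containing no excursion get amplitude 0.

    Returns
    -------
    times : ndarray
        Window-center times in seconds.
    amp : ndarray
        Mean excursion amplitude per window.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    idx, amp = excursions(x)
    t_exc = idx / fs
    centers = np.arange(window_s / 2, n / fs - window_s / 2 + 1e-9, hop_s)
    if centers.size == 0:
        centers = np.array([n / fs / 2])
    lo = np.searchsorted(t_exc, centers - window_s / 2)
    hi = np.searchsorted(t_exc, centers + window_s / 2)
    csum = np.concatenate([[0.0], np.cumsum(amp)])
    count = (hi - lo).astype(float)
    total = csum[hi] - csum[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return centers, mean


def deflection_times(x: np.ndarray, mean: float, threshold: float) -> np.ndarray:
    """Sample indices of suprathreshold, sign-alternating deflections.

    A deflection is a local extremum whose distance from the baseline mean
    exceeds ``threshold`` *and* whose side of the mean differs from the
    previous counted deflection — the sign-alternation rule prevents a DC
    shift or one-sided drift from registering as rhythmic activity.
    """
    ext = local_extrema(np.asarray(x, dtype=float))
    if ext.size == 0:
        return np.empty(0, dtype=np.intp)
    v = x[ext] - mean
    supra = np.abs(v) > threshold
    ext, v = ext[supra], v[supra]
    if ext.size == 0:
        return ext
    s = np.sign(v)
    keep = np.concatenate([[True], s[1:] != s[:-1]])
    return ext[keep]
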