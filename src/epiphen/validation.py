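"""Seeded end-to-end validation suites against generator ground truth.

Each suite simulates recordings (or diaries, or images) with known truth,
runs the corresponding analysis stage, and reports aggregate recovery
statistics.  They are the basis of the package's acceptance checks and are
reusable for regression testing at other problem sizes.
"""

from __future__ import annotations

import numpy as np

from .detect import DetectorParams, baseline_stats, detect_seizures
from .diary import find_clusters
from .episode import pid_score, se_bounds
from .histo import count_particles
from .synth import (SynthConfig, gen_background, gen_diary, gen_histo_image,
                    gen_se, inject_seizure, inject_suppression)

__all__ = [
    "detector_suite",
    "background_false_positives",
    "se_suite",
    "pid_suite",
    "diary_cluster_suite",
    "histo_truth_suite",
]


def detector_suite(n_trials: int = 50, duration_s: float = 3600.0,
                   events_per_trial: int = 3, seed: int = 0) -> dict:
    """Detection recall/precision and onset accuracy on injected events.

    Events are sampled in the clearly-detectable regime (amplitude
    ≥5 SD, frequency ≥5 Hz, duration ≥12 s) at well-separated onsets.
    """
    rng = np.random.default_rng(seed)
    n_inject = n_detect = n_match = 0
    onset_errors = []
    for trial in range(n_trials):
        rec, man = gen_background(SynthConfig(
            duration_s=duration_s, seed=int(rng.integers(2 ** 31))))
        onsets = np.linspace(400, duration_s - 100, events_per_trial)
        for onset in onsets:
            inject_seizure(
                rec, man, onset_s=float(onset),
                duration_s=float(rng.uniform(12, 30)),
                freq_hz=float(rng.uniform(5, 9)),
                amp_mult=float(rng.uniform(5, 8)))
        base = baseline_stats(rec, (0.0, 300.0))
        events = detect_seizures(rec, base, DetectorParams())
        n_inject += events_per_trial
        n_detect += len(events)
        for truth in man.events:
            hits = [e for e in events if e.onset_s < truth.offset_s
                    and e.offset_s > truth.onset_s]
            if hits:
                n_match += 1
                onset_errors.append(abs(hits[0].onset_s - truth.onset_s))
    onset_errors = np.asarray(onset_errors)
    return {
        "recall": n_match / n_inject,
        "precision": n_match / n_detect if n_detect else float("nan"),
        "onset_error_mean_s": float(onset_errors.mean()),
        "onset_error_max_s": float(onset_errors.max()),
        "n_events": n_inject,
    }


def background_false_positives(n_hours: int = 20, seed: int = 0) -> int:
    """Detected events over event-free background recordings."""
    rng = np.random.default_rng(seed)
    false_positives = 0
    for _ in range(n_hours):
        rec, _ = gen_background(SynthConfig(
            duration_s=3600.0, seed=int(rng.integers(2 ** 31))))
        base = baseline_stats(rec, (0.0, 300.0))
        false_positives += len(detect_seizures(rec, base))
    return false_positives


def se_suite(n_episodes: int = 20, continuous_range_min=(20.0, 90.0),
             seed: int = 0) -> dict:
    """SE duration recovery over randomized continuous-phase lengths."""
    rng = np.random.default_rng(seed)
    errors_min = []
    for _ in range(n_episodes):
        continuous_s = 60.0 * rng.uniform(*continuous_range_min)
        rec, man = gen_se(SynthConfig(seed=int(rng.integers(2 ** 31))),
                          onset_s=300.0, continuous_s=continuous_s,
                          post_s=900.0)
        base = baseline_stats(rec, (0.0, 240.0))
        events = detect_seizures(rec, base)
        episode = se_bounds(rec, events, base)
        truth = man.events_of("SE")[0]
        if episode is None:
            errors_min.append(float("inf"))
            continue
        errors_min.append(abs(episode.duration_min - truth.duration_s / 60))
    errors_min = np.asarray(errors_min)
    return {
        "max_abs_error_min": float(errors_min.max()),
        "mean_abs_error_min": float(errors_min.mean()),
        "n_episodes": n_episodes,
    }


def pid_suite(scales=(0.2, 0.4, 0.45, 0.55, 0.7), seeds_per_scale: int = 3,
              seed: int = 0) -> dict:
    """PID classification against the suppression-scale ground truth."""
    rng = np.random.default_rng(seed)
    n_correct = n_total = 0
    for scale in scales:
        for _ in range(seeds_per_scale):
            rec, man = gen_background(SynthConfig(
                duration_s=420.0, seed=int(rng.integers(2 ** 31))))
            inject_seizure(rec, man, onset_s=120.0, duration_s=30.0)
            inject_suppression(rec, man, onset_s=150.5, duration_s=60.0,
                               scale=scale)
            base = baseline_stats(rec, (0.0, 80.0))
            events = detect_seizures(rec, base)
            result = pid_score(rec, events[0], events)
            n_total += 1
            n_correct += (result.scorable and result.pid == (scale < 0.5))
    return {"accuracy": n_correct / n_total, "n_cases": n_total}


def diary_cluster_suite(n_diaries: int = 100, n_days: int = 21,
                        base_rate: float = 0.3, cluster_rate: float = 10.0,
                        cluster_days=(5, 7), seed: int = 0) -> dict:
    """Exact cluster day-range recovery on generated diaries."""
    rng = np.random.default_rng(seed)
    matches = 0
    for _ in range(n_diaries):
        d, truth = gen_diary(n_days, base_rate,
                             [(*cluster_days, cluster_rate)],
                             seed=int(rng.integers(2 ** 31)))
        clusters = find_clusters(d)
        matches += clusters.clusters == [tuple(c) for c in truth["clusters"]]
    return {"exact_match_rate": matches / n_diaries, "n_diaries": n_diaries}


def histo_truth_suite(n_images: int = 10, seed: int = 0) -> dict:
    """Recovery of exact area fraction and interior particle counts."""
    rng = np.random.default_rng(seed)
    af_err = 0.0
    count_err = 0
    for _ in range(n_images):
        n_particles = int(rng.integers(5, 30))
        img, roi, truth = gen_histo_image(
            [12.0] * n_particles, n_border=int(rng.integers(0, 3)),
            seed=int(rng.integers(2 ** 31)))
        res = count_particles(img, roi, threshold=128.0)
        af_err = max(af_err, abs(res.area_fraction_pct
                                 - truth["area_fraction_pct"]))
        count_err += abs(res.particle_count - truth["interior_count"])
    return {"max_area_fraction_error_pct": af_err,
            "total_count_error": count_err, "n_images": n_images}
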