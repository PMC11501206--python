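"""Ground-truth synthetic data: EEG, seizure diaries, histology images.

Every downstream stage of the pipeline is validated against data generated
here, where the truth is known by construction:

* **EEG background** is band-limited 1/f-family noise (default power
  spectral slope 2, the Brownian-like falloff typical of mammalian
  EEG/LFP), 1–100 Hz to match the acquisition band-pass, scaled per
  channel to an exact sample SD.  A slope of exactly 1 spreads so much
  power into the upper band that a Gaussian background crosses ±2 SD on
  alternating sides more than 3 times per second — i.e. the amplitude+
  rhythmicity seizure definition would fire on noise continuously — so it
  is not a usable default for false-positive testing.
* **Seizures** are rhythmic sinusoids (default 6 Hz) with raised-cosine
  on/off ramps whose peak deflection is a stated multiple of the background
  SD — deliberately unambiguous in rhythmicity and amplitude.
* **Status epilepticus** is a long continuous high-amplitude phase followed
  by a step-down to decaying intermittent spiking, so the true SE end is
  exact.
* **Diaries** draw per-day seizure counts from Poisson distributions, with
  designated cluster day-ranges at an elevated mean.
* **Histology images** contain disc-like blobs of exact pixel area on a
  noisy background, with exact area-fraction and particle-count truth.

A :class:`Manifest` records every injected event and serializes to JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .diary import Diary
from .eeg_io import DEFAULT_CHANNELS, Recording
from .histo import HistoImage, ROIMask

__all__ = [
    "SynthConfig",
    "Manifest",
    "ManifestEvent",
    "gen_background",
    "inject_seizure",
    "inject_suppression",
    "inject_se",
    "gen_se",
    "gen_diary",
    "gen_histo_image",
]


@dataclass(frozen=True)
class SynthConfig:
    """EEG generator settings.

    ``background_sd`` is a free parameter (no physical value is implied by
    the recording setup); 20 µV is a plausible rodent cortical screw-EEG
    scale and is only a scale factor for everything downstream.
    """

    fs: float = 500.0
    n_channels: int = 4
    duration_s: float = 600.0
    background_sd: float = 20.0
    spectral_exponent: float = 2.0
    band_hz: tuple = (1.0, 100.0)
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0 or self.duration_s <= 0 or self.n_channels < 1:
            raise ValueError("fs, duration and channel count must be positive")
        if self.background_sd < 0:
            raise ValueError("background SD must be non-negative")
        if self.band_hz[1] >= self.fs / 2:
            raise ValueError("band edge must be below Nyquist")


@dataclass
class ManifestEvent:
    kind: str                  # "seizure" | "SE" | "suppression"
    channels: tuple
    onset_s: float
    duration_s: float
    freq_hz: float | None = None
    amp_mult: float | None = None       # peak deflection / background SD
    scale: float | None = None          # suppression factor
    resolved: bool | None = None        # SE only

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class Manifest:
    """Ground truth for one synthetic subject."""

    config: SynthConfig
    events: list = field(default_factory=list)
    diary_truth: dict | None = None
    image_truth: dict | None = None

    def events_of(self, kind: str):
        return [e for e in self.events if e.kind == kind]

    def to_json(self, path=None) -> str:
        payload = {
            "config": asdict(self.config),
            "events": [asdict(e) for e in self.events],
            "diary_truth": self.diary_truth,
            "image_truth": self.image_truth,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "Manifest":
        if isinstance(source, Path) or (
                isinstance(source, str) and not source.lstrip().startswith("{")):
            source = Path(source).read_text()
        payload = json.loads(source)
        cfg = payload["config"]
        cfg["band_hz"] = tuple(cfg["band_hz"])
        events = []
        for e in payload["events"]:
            e["channels"] = tuple(e["channels"])
            events.append(ManifestEvent(**e))
        return cls(config=SynthConfig(**cfg), events=events,
                   diary_truth=payload["diary_truth"],
                   image_truth=payload["image_truth"])


# ---------------------------------------------------------------------------
# EEG background and event injection
# ---------------------------------------------------------------------------

def _pink_noise(n: int, fs: float, exponent: float, band: tuple,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f^exponent noise restricted to a frequency band."""
    freqs = np.fft.rfftfreq(n, d=1 / fs)
    spec = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    shaping = np.zeros_like(freqs)
    inband = (freqs >= band[0]) & (freqs <= band[1])
    shaping[inband] = freqs[inband] ** (-exponent / 2)
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_background(cfg: SynthConfig) -> tuple:
    """Generate an event-free background recording.

    Returns ``(Recording, Manifest)``.  Each channel is independent pink
    noise scaled so its sample SD equals ``cfg.background_sd`` exactly;
    SD 0 yields an all-zero recording.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    signal = np.empty((cfg.n_channels, n))
    for c in range(cfg.n_channels):
        signal[c] = cfg.background_sd * _pink_noise(
            n, cfg.fs, cfg.spectral_exponent, cfg.band_hz, rng)
    channels = (DEFAULT_CHANNELS[:cfg.n_channels]
                if cfg.n_channels <= len(DEFAULT_CHANNELS)
                else tuple(f"ch{i}" for i in range(cfg.n_channels)))
    rec = Recording(signal=signal, fs=cfg.fs, channels=channels)
    return rec, Manifest(config=cfg)


def _ramped_sine(fs: float, duration_s: float, freq_hz: float,
                 amplitude: float, ramp_s: float = 0.5) -> np.ndarray:
    """Sinusoid with raised-cosine on/off ramps."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    wave = amplitude * np.sin(2 * np.pi * freq_hz * t)
    ramp_n = min(int(round(ramp_s * fs)), n // 2)
    if ramp_n:
        win = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        wave[:ramp_n] *= win
        wave[-ramp_n:] *= win[::-1]
    return wave


def _sample_span(rec: Recording, onset_s: float, duration_s: float):
    if duration_s <= 0:
        raise ValueError("event duration must be positive")
    if onset_s < 0 or onset_s + duration_s > rec.duration + 1e-9:
        raise ValueError(
            f"event [{onset_s}, {onset_s + duration_s}] s outside recording")
    i0 = int(round(onset_s * rec.fs))
    return i0, i0 + int(round(duration_s * rec.fs))


def inject_seizure(rec: Recording, manifest: Manifest, onset_s: float,
                   duration_s: float, freq_hz: float = 6.0,
                   amp_mult: float = 5.0, channels=None) -> ManifestEvent:
    """Add a rhythmic oscillation to the recording (in place).

    The oscillation's peak deflection is ``amp_mult`` × background SD, so
    its peak-to-trough amplitude is twice that.  ``channels`` selects
    channel indices (default: all).
    """
    if freq_hz >= rec.fs / 2:
        raise ValueError("oscillation frequency must be below Nyquist")
    i0, i1 = _sample_span(rec, onset_s, duration_s)
    wave = _ramped_sine(rec.fs, duration_s, freq_hz,
                        amp_mult * manifest.config.background_sd)[: i1 - i0]
    chan_idx = tuple(range(rec.n_channels)) if channels is None \
        else tuple(channels)
    for c in chan_idx:
        rec.signal[c, i0:i1] += wave
    event = ManifestEvent(
        kind="seizure", channels=tuple(rec.channels[c] for c in chan_idx),
        onset_s=float(onset_s), duration_s=float(duration_s),
        freq_hz=float(freq_hz), amp_mult=float(amp_mult))
    manifest.events.append(event)
    return event


def inject_suppression(rec: Recording, manifest: Manifest, onset_s: float,
                       duration_s: float, scale: float) -> ManifestEvent:
    """Scale the signal down over an interval on all channels (in place).

    Emulates postictal amplitude suppression; requires ``0 ≤ scale < 1``.
    """
    if not 0 <= scale < 1:
        raise ValueError(f"suppression scale must be in [0, 1), got {scale}")
    i0, i1 = _sample_span(rec, onset_s, duration_s)
    rec.signal[:, i0:i1] *= scale
    event = ManifestEvent(
        kind="suppression", channels=tuple(rec.channels),
        onset_s=float(onset_s), duration_s=float(duration_s),
        scale=float(scale))
    manifest.events.append(event)
    return event


def inject_se(rec: Recording, manifest: Manifest, onset_s: float,
              continuous_s: float, amp_mult: float = 15.0,
              post_amp_frac: float = 0.35, freq_hz: float = 7.0,
              spike_period_s: float = 3.0, spike_width_s: float = 0.5,
              decay_tau_s: float = 3600.0) -> ManifestEvent:
    """Add a status-epilepticus episode to a recording (in place).

    A continuous high-amplitude oscillatory phase of ``continuous_s``
    seconds starts at ``onset_s`` on all channels, followed by a step-down
    to intermittent oscillation bursts whose amplitude starts at
    ``post_amp_frac`` of the continuous phase and decays exponentially
    until the end of the recording.  The true SE end is the step-down
    time.  If the continuous phase reaches the end of the recording there
    is no step-down and the manifest marks the episode unresolved.

    Only one SE per recording is modelled; a second call raises.
    """
    if manifest.events_of("SE"):
        raise ValueError("single-SE model: an SE episode already exists")
    if continuous_s <= 300.0:
        raise ValueError("continuous phase must exceed 5 min")
    fs, sd = rec.fs, manifest.config.background_sd
    total = rec.duration

    i0, i1 = _sample_span(rec, onset_s, continuous_s)
    wave = _ramped_sine(fs, continuous_s, freq_hz, amp_mult * sd)[: i1 - i0]
    rec.signal[:, i0:i1] += wave[None, :]

    step = onset_s + continuous_s
    resolved = step < total - 1e-9
    if resolved:
        # decaying intermittent spiking after the step-down
        t = step
        while t + spike_width_s < total:
            j0, j1 = _sample_span(rec, t, spike_width_s)
            amp = (post_amp_frac * amp_mult * sd
                   * np.exp(-(t - step) / decay_tau_s))
            burst = _ramped_sine(fs, spike_width_s, freq_hz, amp,
                                 ramp_s=0.1)[: j1 - j0]
            rec.signal[:, j0:j1] += burst[None, :]
            t += spike_period_s

    rec.markers.append(("injection", max(0.0, onset_s - 60.0)))
    event = ManifestEvent(
        kind="SE", channels=tuple(rec.channels), onset_s=float(onset_s),
        duration_s=float(continuous_s), freq_hz=float(freq_hz),
        amp_mult=float(amp_mult), resolved=resolved)
    manifest.events.append(event)
    return event


def gen_se(cfg: SynthConfig, onset_s: float, continuous_s: float,
           post_s: float = 3600.0, **se_kwargs) -> tuple:
    """Generate a recording containing one SE episode with exact truth.

    Background runs until ``onset_s``; the recording ends ``post_s``
    seconds after the continuous phase (``post_s = 0`` leaves the episode
    unresolved).  See :func:`inject_se` for the episode parameters.

    Returns ``(Recording, Manifest)``.
    """
    total = onset_s + continuous_s + post_s
    cfg = SynthConfig(**{**asdict(cfg), "duration_s": float(total)})
    rec, manifest = gen_background(cfg)
    inject_se(rec, manifest, onset_s, continuous_s, **se_kwargs)
    return rec, manifest


# ---------------------------------------------------------------------------
# Seizure diaries
# ---------------------------------------------------------------------------

#: Diary defaults used for cohort simulation: a 3-week recording period, a
#: quiet off-cluster background, and high-contrast clusters.
DIARY_DEFAULTS = dict(n_days=21, base_rate=0.3, cluster_rate=10.0,
                      cluster_days=3)

#: Per-seizure durations: gamma with mean ≈45 s, SD ≈15 s, matching the
#: scale of convulsive seizures in chronic epilepsy.
DURATION_SHAPE, DURATION_SCALE = 9.0, 5.0


def gen_diary(n_days: int, base_rate: float, cluster_specs=(),
              seed: int = 0, subject: str = "") -> tuple:
    """Generate a per-day seizure diary with known cluster structure.

    ``cluster_specs`` is a sequence of ``(start_day, end_day, rate)`` with
    inclusive 0-based day ranges; those days draw counts from
    Poisson(rate), all other days from Poisson(base_rate).  Per-seizure
    durations are drawn from a gamma distribution.

    Returns ``(Diary, truth)`` where ``truth`` records the intended
    cluster day-ranges and rates.
    """
    if n_days < 1:
        raise ValueError("diary needs at least one day")
    if base_rate < 0 or any(r < 0 for _, _, r in cluster_specs):
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    rates = np.full(n_days, float(base_rate))
    for start, end, rate in cluster_specs:
        if not 0 <= start <= end < n_days:
            raise ValueError(f"cluster days {start}-{end} outside diary")
        rates[start: end + 1] = rate
    counts = rng.poisson(rates)
    durations = rng.gamma(DURATION_SHAPE, DURATION_SCALE, size=counts.sum())
    truth = {
        "clusters": [(int(s), int(e)) for s, e, _ in cluster_specs],
        "cluster_rates": [float(r) for _, _, r in cluster_specs],
        "base_rate": float(base_rate),
    }
    return Diary(counts=counts, durations_s=durations, subject=subject), truth


# ---------------------------------------------------------------------------
# Histology images
# ---------------------------------------------------------------------------

def _blob_pixels(center, n_px: int, shape) -> np.ndarray | None:
    """The ``n_px`` pixels nearest to ``center`` (a connected disc-like
    blob of exact pixel count), or None if it would leave the image."""
    cy, cx = center
    r = int(np.ceil(np.sqrt(n_px / np.pi))) + 2
    yy, xx = np.mgrid[cy - r: cy + r + 1, cx - r: cx + r + 1]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    order = np.lexsort((xx.ravel(), yy.ravel(), d2.ravel()))
    take = order[:n_px]
    ys, xs = yy.ravel()[take], xx.ravel()[take]
    if ys.min() < 0 or xs.min() < 0 or ys.max() >= shape[0] \
            or xs.max() >= shape[1]:
        return None
    return np.stack([ys, xs], axis=1)


def gen_histo_image(areas_um2, shape=(256, 256), pixel_size_um: float = 1.0,
                    roi: str = "full", background: float = 40.0,
                    noise_sd: float = 5.0, foreground: float = 200.0,
                    n_border: int = 0, seed: int = 0) -> tuple:
    """Generate a blob image with exact particle and area-fraction truth.

    Parameters
    ----------
    areas_um2 : sequence of float
        Requested physical area of each interior particle; converted to a
        pixel count by round-to-nearest, so the *realized* area recorded in
        the truth is exact.
    roi : "full" or "left"
        Whole image, or the left half of it.
    n_border : int
        Number of additional 12-px blobs placed straddling the ROI border
        (counted in the area fraction but excluded from particle counts by
        the completeness rule).

    Returns ``(HistoImage, ROIMask, truth)``; ``truth`` holds the interior
    particle count, realized per-particle areas, and the exact area
    fraction of the ROI in percent.  Particles are non-overlapping and
    non-adjacent by construction.
    """
    rng = np.random.default_rng(seed)
    mask = np.ones(shape, dtype=bool)
    if roi == "left":
        mask[:, shape[1] // 2:] = False
    elif roi != "full":
        raise ValueError(f"unknown ROI spec {roi!r}")

    px_area = pixel_size_um ** 2
    occupied = np.zeros(shape, dtype=bool)   # blobs + 1-px moat
    fg = np.zeros(shape, dtype=bool)

    # ROI border pixels (image edge or 8-adjacent to outside-ROI)
    interior = np.zeros_like(mask)
    interior[1:-1, 1:-1] = (
        mask[1:-1, 1:-1]
        & mask[:-2, :-2] & mask[:-2, 1:-1] & mask[:-2, 2:]
        & mask[1:-1, :-2] & mask[1:-1, 2:]
        & mask[2:, :-2] & mask[2:, 1:-1] & mask[2:, 2:])

    def place(n_px: int, want_border: bool) -> np.ndarray:
        for _ in range(10000):
            cy = int(rng.integers(0, shape[0]))
            cx = int(rng.integers(0, shape[1]))
            px = _blob_pixels((cy, cx), n_px, shape)
            if px is None:
                continue
            ys, xs = px[:, 0], px[:, 1]
            if not mask[ys, xs].all():
                continue
            if occupied[ys, xs].any():
                continue
            on_border = bool((~interior[ys, xs]).any())
            if on_border != want_border:
                continue
            fg[ys, xs] = True
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    occupied[np.clip(ys + dy, 0, shape[0] - 1),
                             np.clip(xs + dx, 0, shape[1] - 1)] = True
            return px
        raise RuntimeError("could not place particle; image too crowded")

    realized = []
    for a in areas_um2:
        n_px = max(1, int(round(a / px_area)))
        place(n_px, want_border=False)
        realized.append(n_px * px_area)
    for _ in range(n_border):
        place(12, want_border=True)

    pixels = background + noise_sd * rng.standard_normal(shape)
    # keep background strictly separable from foreground
    pixels = np.clip(pixels, 0, background + 6 * noise_sd + 1)
    pixels[fg] = foreground
    img = HistoImage(pixels=pixels, pixel_size_um=pixel_size_um)
    truth = {
        "interior_count": len(realized),
        "areas_um2": realized,
        "area_fraction_pct": 100.0 * (fg & mask).sum() / mask.sum(),
        "n_border": int(n_border),
    }
    return img, ROIMask(mask=mask, region=roi), truth
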