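"""Generator calibration and ground-truth bookkeeping."""

import json

import numpy as np
import pytest

from epiphen.amplitude import envelope, mean_peak_to_trough
from epiphen.synth import (Manifest, SynthConfig, gen_background, gen_diary,
                           gen_histo_image, gen_se, inject_se, inject_seizure,
                           inject_suppression)


def fitted_peak_to_trough(x, fs, freq_hz):
    """Peak-to-trough of the oscillatory component via sine regression."""
    t = np.arange(x.size) / fs
    c = np.cos(2 * np.pi * freq_hz * t)
    s = np.sin(2 * np.pi * freq_hz * t)
    a = 2 * np.mean(x * c)
    b = 2 * np.mean(x * s)
    return 2 * np.hypot(a, b)


class TestBackground:
    def test_sd_calibration(self):
        rec, _ = gen_background(SynthConfig(fs=500, duration_s=600,
                                            background_sd=20.0, seed=1))
        sds = rec.signal.std(axis=1)
        assert np.all((sds > 19.0) & (sds < 21.0))

    def test_zero_sd_gives_silence(self):
        rec, _ = gen_background(SynthConfig(duration_s=10, background_sd=0.0))
        assert not rec.signal.any()

    def test_seed_determinism(self):
        cfg = SynthConfig(duration_s=20, seed=7)
        a, _ = gen_background(cfg)
        b, _ = gen_background(cfg)
        assert a.signal.tobytes() == b.signal.tobytes()

    def test_band_limits(self):
        """Spectral content stays inside the 1-100 Hz acquisition band."""
        rec, _ = gen_background(SynthConfig(duration_s=60, seed=3))
        spec = np.abs(np.fft.rfft(rec.signal[0])) ** 2
        f = np.fft.rfftfreq(rec.n_samples, 1 / rec.fs)
        out_of_band = spec[(f < 0.9) | (f > 101)].sum()
        assert out_of_band < 1e-9 * spec.sum()

    @pytest.mark.parametrize("bad", [
        dict(fs=-1), dict(duration_s=0), dict(background_sd=-5),
        dict(band_hz=(1.0, 300.0)),
    ])
    def test_invalid_config(self, bad):
        with pytest.raises(ValueError):
            SynthConfig(**bad)


class TestInjectSeizure:
    def test_amplitude_calibration(self, bg600_copy):
        """Injected oscillation peak-to-trough is 2 x amp_mult x SD (10%)."""
        rec, man = bg600_copy
        inject_seizure(rec, man, onset_s=60, duration_s=15, freq_hz=6,
                       amp_mult=5)
        mid = rec.segment(62, 73)[0]   # plateau, away from the ramps
        p2t = fitted_peak_to_trough(mid, rec.fs, 6.0)
        assert p2t == pytest.approx(2 * 5 * 20.0, rel=0.10)

    def test_zero_duration_rejected(self, bg600_copy):
        rec, man = bg600_copy
        with pytest.raises(ValueError):
            inject_seizure(rec, man, onset_s=60, duration_s=0.0)
        assert not man.events

    def test_out_of_range_rejected(self, bg600_copy):
        rec, man = bg600_copy
        with pytest.raises(ValueError):
            inject_seizure(rec, man, onset_s=595, duration_s=10)

    def test_slow_rhythm_bookkeeping(self, bg600_copy):
        """A 2-Hz event is recorded faithfully so non-detection can be
        asserted downstream."""
        rec, man = bg600_copy
        ev = inject_seizure(rec, man, onset_s=100, duration_s=20, freq_hz=2,
                            amp_mult=8)
        assert ev.freq_hz == 2.0
        assert man.events_of("seizure")[0] is ev

    def test_manifest_complete(self, bg600_copy):
        rec, man = bg600_copy
        inject_seizure(rec, man, onset_s=50, duration_s=12)
        inject_seizure(rec, man, onset_s=200, duration_s=15)
        assert len(man.events) == 2
        assert [e.onset_s for e in man.events] == [50, 200]


class TestSuppression:
    def test_sd_scaling(self, bg600_copy):
        rec, man = bg600_copy
        pre_sd = rec.segment(100, 160)[0].std()
        inject_suppression(rec, man, onset_s=100, duration_s=60, scale=0.4)
        post_sd = rec.segment(100, 160)[0].std()
        assert post_sd / pre_sd == pytest.approx(0.4, rel=1e-9)

    @pytest.mark.parametrize("scale", [1.0, 1.5, -0.1])
    def test_invalid_scale(self, bg600_copy, scale):
        rec, man = bg600_copy
        with pytest.raises(ValueError):
            inject_suppression(rec, man, onset_s=10, duration_s=5, scale=scale)

    def test_zero_scale_flattens(self, bg600_copy):
        rec, man = bg600_copy
        inject_suppression(rec, man, onset_s=10, duration_s=5, scale=0.0)
        assert not rec.segment(10, 15).any()


class TestSE:
    def test_truth_duration_and_resolution(self):
        rec, man = gen_se(SynthConfig(seed=2), onset_s=120,
                          continuous_s=600, post_s=300)
        se = man.events_of("SE")[0]
        assert se.onset_s == 120 and se.duration_s == 600
        assert se.resolved

    def test_unresolved_without_stepdown(self):
        rec, man = gen_se(SynthConfig(seed=2), onset_s=120,
                          continuous_s=600, post_s=0)
        assert not man.events_of("SE")[0].resolved

    def test_single_se_model(self):
        rec, man = gen_se(SynthConfig(seed=2), onset_s=120,
                          continuous_s=400, post_s=600)
        with pytest.raises(ValueError):
            inject_se(rec, man, onset_s=900, continuous_s=400)

    def test_short_continuous_phase_rejected(self):
        with pytest.raises(ValueError):
            gen_se(SynthConfig(seed=2), onset_s=60, continuous_s=200)

    def test_continuous_envelope_above_threshold(self):
        """During the continuous phase every channel's envelope exceeds
        3 x the background mean peak-to-trough amplitude."""
        rec, man = gen_se(SynthConfig(seed=4), onset_s=120,
                          continuous_s=400, post_s=300)
        base_amp = [mean_peak_to_trough(rec.segment(0, 110)[c])
                    for c in range(rec.n_channels)]
        for c in range(rec.n_channels):
            t, env = envelope(rec.signal[c], rec.fs)
            during = env[(t > 140) & (t < 500)]
            assert np.all(during > 3 * base_amp[c])

    def test_post_phase_envelope_below_half_peak(self):
        rec, man = gen_se(SynthConfig(seed=4), onset_s=120,
                          continuous_s=400, post_s=300)
        t, env = envelope(rec.signal[0], rec.fs)
        peak = env[(t >= 120) & (t <= 520)].max()
        after = env[(t > 540) & (t < 800)]
        assert np.all(after < 0.5 * peak)


class TestDiary:
    def test_zero_rate_all_zero(self):
        d, _ = gen_diary(21, 0.0, seed=0)
        assert d.counts.sum() == 0 and d.n_days == 21

    def test_determinism(self):
        a, _ = gen_diary(21, 1.0, [(5, 7, 5.0)], seed=11)
        b, _ = gen_diary(21, 1.0, [(5, 7, 5.0)], seed=11)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.durations_s, b.durations_s)

    def test_monte_carlo_means(self):
        """Counts average the base rate off-cluster and the elevated rate
        in-cluster (1000 seeds, 10%)."""
        on = off = 0.0
        for seed in range(1000):
            d, _ = gen_diary(21, 1.0, [(5, 7, 5.0)], seed=seed)
            on += d.counts[5:8].mean()
            off += np.delete(d.counts, slice(5, 8)).mean()
        assert on / 1000 == pytest.approx(5.0, rel=0.10)
        assert off / 1000 == pytest.approx(1.0, rel=0.10)

    def test_cluster_days_nearly_always_high(self):
        """High-contrast cluster days (mean 7/day) reach >=3 seizures with
        probability >=0.95."""
        hits = n = 0
        for seed in range(500):
            d, _ = gen_diary(10, 0.3, [(4, 6, 7.0)], seed=seed)
            hits += (d.counts[4:7] >= 3).sum()
            n += 3
        assert hits / n >= 0.95

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            gen_diary(0, 1.0)
        with pytest.raises(ValueError):
            gen_diary(10, -1.0)
        with pytest.raises(ValueError):
            gen_diary(10, 1.0, [(5, 12, 4.0)])


class TestHistoImage:
    def test_truth_count_and_area_fraction(self):
        img, roi, truth = gen_histo_image([12.0] * 25, seed=0)
        assert truth["interior_count"] == 25
        assert truth["areas_um2"] == [12.0] * 25
        # 25 blobs x 12 px over a 256x256 ROI
        assert truth["area_fraction_pct"] == pytest.approx(
            100 * 25 * 12 / 256 ** 2)

    def test_small_areas_recorded_for_cutoff_tests(self):
        img, roi, truth = gen_histo_image([8.0, 12.0, 15.0], seed=1)
        assert truth["areas_um2"] == [8.0, 12.0, 15.0]

    def test_half_image_roi(self):
        img, roi, truth = gen_histo_image([12.0] * 10, roi="left", seed=2)
        assert roi.mask.sum() == 256 * 256 // 2
        assert truth["area_fraction_pct"] == pytest.approx(
            100 * 120 / (256 * 256 / 2))

    def test_blobs_disjoint_and_exact(self):
        img, roi, truth = gen_histo_image([12.0] * 30, seed=3)
        fg = img.pixels == 200.0
        assert fg.sum() == 30 * 12

    def test_determinism(self):
        a = gen_histo_image([10.0] * 5, seed=9)[0]
        b = gen_histo_image([10.0] * 5, seed=9)[0]
        assert np.array_equal(a.pixels, b.pixels)


class TestManifestSerialization:
    def test_round_trip(self, bg600_copy, tmp_path):
        rec, man = bg600_copy
        inject_seizure(rec, man, onset_s=60, duration_s=15)
        inject_suppression(rec, man, onset_s=80, duration_s=30, scale=0.4)
        man.diary_truth = {"clusters": [[5, 7]]}
        path = tmp_path / "manifest.json"
        man.to_json(path)
        back = Manifest.from_json(path)
        assert back.config == man.config
        assert back.events == man.events
        assert back.diary_truth == man.diary_truth

    def test_json_is_valid(self, bg600_copy):
        rec, man = bg600_copy
        inject_seizure(rec, man, onset_s=60, duration_s=15)
        payload = json.loads(man.to_json())
        assert payload["events"][0]["kind"] == "seizure"
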