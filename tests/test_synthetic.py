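"""Synthetic ECG generator: morphology, noise spectra, labelled composition."""

import numpy as np
import pytest
from scipy.signal import periodogram

from ecgsqa.rules import NoiseEvent, NoiseKind, QualityClass, label_segment
from ecgsqa.synthetic import (
    FS_HZ,
    SEGMENT_SAMPLES,
    CleanEcgParams,
    DatasetSpec,
    WaveParams,
    compose_segment,
    generate_clean_segment,
    generate_dataset,
    generate_motion_artifact,
    generate_myoelectric_noise,
)


def count_r_peaks(x, height, min_sep_s=0.25):
    """Strict local maxima above `height` separated by >= min_sep_s."""
    idx = [i for i in range(1, len(x) - 1)
           if x[i] > x[i - 1] and x[i] > x[i + 1] and x[i] > height]
    kept = []
    for i in idx:
        if not kept or (i - kept[-1]) >= min_sep_s * FS_HZ:
            kept.append(i)
    return len(kept)


class TestCleanSegment:
    def test_beat_count_matches_heart_rate(self):
        seg = generate_clean_segment(CleanEcgParams(heart_rate_bpm=60.0), seed=1)
        assert seg.samples.shape == (SEGMENT_SAMPLES,)
        assert seg.true_class is QualityClass.LOW
        assert seg.events == ()
        n = count_r_peaks(seg.samples, 0.5 * seg.r_height_mv)
        assert abs(n - 4) <= 1

    @pytest.mark.parametrize("bpm,expected", [(40, 40 * 4 / 60), (120, 8), (180, 12)])
    def test_beat_count_scales(self, bpm, expected):
        seg = generate_clean_segment(CleanEcgParams(heart_rate_bpm=bpm), seed=3)
        n = count_r_peaks(seg.samples, 0.5 * seg.r_height_mv,
                          min_sep_s=0.25 * 60 / bpm)
        assert abs(n - expected) <= 1

    def test_r_height_tracks_requested_amplitude(self):
        for amp in [0.3, 1.0, 2.5]:
            seg = generate_clean_segment(CleanEcgParams(r_amplitude_mv=amp), seed=5)
            assert seg.r_height_mv == pytest.approx(amp, rel=0.05)

    def test_zero_amplitude_gives_flatline(self):
        seg = generate_clean_segment(CleanEcgParams(r_amplitude_mv=0.0), seed=1)
        assert np.all(seg.samples == 0.0)

    def test_seeded_determinism(self):
        p = CleanEcgParams()
        a = generate_clean_segment(p, seed=9).samples
        b = generate_clean_segment(p, seed=9).samples
        assert np.array_equal(a, b)
        c = generate_clean_segment(p, seed=10).samples
        assert not np.array_equal(a, c)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CleanEcgParams(heart_rate_bpm=20.0)
        with pytest.raises(ValueError):
            CleanEcgParams(r_amplitude_mv=-1.0)
        with pytest.raises(ValueError):
            WaveParams(0.1, -0.01, 0.0)


class TestNoiseGenerators:
    def test_motion_artifact_contract(self):
        x = generate_motion_artifact(3.0, 0.5, seed=2)
        assert len(x) == 384
        assert np.abs(x).max() == pytest.approx(0.5, rel=0.01)
        f, p = periodogram(x, fs=FS_HZ)
        assert p[f < 7.0].sum() / p.sum() >= 0.95

    def test_myoelectric_noise_contract(self):
        x = generate_myoelectric_noise(2.5, 0.3, seed=2)
        assert len(x) == 320
        assert np.abs(x).max() == pytest.approx(0.3, rel=0.01)
        f, p = periodogram(x, fs=FS_HZ)
        assert p[(f >= 30.0) & (f <= 63.0)].sum() / p.sum() >= 0.90

    @pytest.mark.parametrize("gen", [generate_motion_artifact, generate_myoelectric_noise])
    def test_zero_peak_gives_zeros(self, gen):
        assert np.all(gen(1.0, 0.0, seed=1) == 0.0)

    @pytest.mark.parametrize("gen", [generate_motion_artifact, generate_myoelectric_noise])
    def test_linear_amplitude_scaling(self, gen):
        a = gen(2.0, 0.25, seed=4)
        b = gen(2.0, 0.50, seed=4)
        np.testing.assert_allclose(b, 2.0 * a, rtol=1e-12)

    @pytest.mark.parametrize("gen", [generate_motion_artifact, generate_myoelectric_noise])
    def test_different_seeds_differ(self, gen):
        a, b = gen(1.0, 0.1, seed=1), gen(1.0, 0.1, seed=2)
        assert len(a) == len(b)
        assert not np.array_equal(a, b)

    @pytest.mark.parametrize("gen", [generate_motion_artifact, generate_myoelectric_noise])
    def test_nonpositive_duration_rejected(self, gen):
        with pytest.raises(ValueError):
            gen(0.0, 0.1, seed=1)

    def test_spectral_separation_over_many_seeds(self):
        """Mean periodogram centroid: motion < 7 Hz < myoelectric."""
        mot, myo = [], []
        for s in range(100):
            for gen, acc in [(generate_motion_artifact, mot),
                             (generate_myoelectric_noise, myo)]:
                x = gen(2.0, 1.0, seed=s)
                f, p = periodogram(x, fs=FS_HZ)
                acc.append(float((f * p).sum() / p.sum()))
        assert np.mean(mot) < 7.0 < np.mean(myo)


class TestComposeSegment:
    def make_clean(self, seed=1):
        return generate_clean_segment(CleanEcgParams(), seed=seed)

    def test_no_events_stays_low(self):
        clean = self.make_clean()
        seg = compose_segment(clean, [], seed=2)
        assert seg.true_class is QualityClass.LOW
        assert np.array_equal(seg.samples, clean.samples)

    def test_mild_myoelectric_label(self):
        clean = self.make_clean()
        evs = [NoiseEvent(NoiseKind.MYOELECTRIC, 0.5, 3.5, 0.4)]
        assert compose_segment(clean, evs, seed=2).true_class is QualityClass.MILD_MYO

    def test_severe_motion_label(self):
        clean = self.make_clean()
        evs = [NoiseEvent(NoiseKind.MOTION, 1.0, 3.5, 0.8)]
        assert compose_segment(clean, evs, seed=2).true_class is QualityClass.SEVERE_MOTION

    def test_amplitude_contract(self):
        """Measured peak of the added noise is within 1% of the requested
        ratio times the R height."""
        clean = self.make_clean()
        for ratio in [0.2, 0.5, 0.9]:
            evs = [NoiseEvent(NoiseKind.MYOELECTRIC, 0.5, 3.5, ratio)]
            seg = compose_segment(clean, evs, seed=3)
            added = seg.samples - clean.samples
            assert np.abs(added).max() == pytest.approx(
                ratio * clean.r_height_mv, rel=0.01)
            i0, i1 = int(0.5 * FS_HZ), int(3.5 * FS_HZ)
            assert np.all(added[:i0] == 0.0) and np.all(added[i1:] == 0.0)

    def test_overlapping_events_rejected(self):
        clean = self.make_clean()
        evs = [NoiseEvent(NoiseKind.MOTION, 0.0, 2.5, 0.3),
               NoiseEvent(NoiseKind.MYOELECTRIC, 2.0, 4.0, 0.3)]
        with pytest.raises(ValueError):
            compose_segment(clean, evs, seed=1)


class TestGenerateDataset:
    def test_counts_and_roundtrip_labels(self, small_dataset):
        labels = [s.true_class for s in small_dataset]
        for c in QualityClass:
            assert labels.count(c) == 10
        for s in small_dataset:
            if s.events:
                assert label_segment(s.events, s.r_height_mv) is s.true_class

    def test_reproducible_from_master_seed(self):
        spec = DatasetSpec(counts={QualityClass.LOW: 2,
                                   QualityClass.SEVERE_MYO: 2}, seed=5)
        a = generate_dataset(spec)
        b = generate_dataset(spec)
        assert all(np.array_equal(x.samples, y.samples) for x, y in zip(a, b))

    def test_empty_spec(self):
        assert generate_dataset(DatasetSpec(counts={}, seed=0)) == []

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            DatasetSpec(counts={}, mild_ratio_range=(0.2, 0.6))
        with pytest.raises(ValueError):
            DatasetSpec(counts={}, severe_ratio_range=(0.3, 0.9))
        with pytest.raises(ValueError):
            DatasetSpec(counts={QualityClass.LOW: -1})
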