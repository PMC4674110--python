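"""Envelope computation, threshold segmentation, gap and amplitude
measurement, and cross-recording normalization."""

import numpy as np
import pytest

import songgaps as sg
from songgaps.segment import (
    Envelope,
    SyllableInterval,
    compute_envelope,
    estimate_baseline,
    measure_gaps,
    normalize_across_recordings,
    platform_normalize,
    refine_intervals,
    rms_amplitude,
    segment_syllables,
)


class TestEnvelope:
    def test_constant_signal_gives_constant_envelope(self):
        env = compute_envelope(np.full(32000, 0.3), 32000)
        interior = env.values[10:-10]
        assert np.allclose(interior, 0.3, rtol=1e-6)

    def test_sine_envelope_is_mean_rectified_value(self):
        # mean of |A sin| is 2A/pi
        t = np.arange(32000) / 32000
        env = compute_envelope(0.8 * np.sin(2 * np.pi * 2000 * t), 32000)
        assert np.allclose(env.values[20:-20], 2 * 0.8 / np.pi, rtol=0.02)

    def test_length_is_ceil_duration_times_1khz(self):
        assert len(compute_envelope(np.ones(32000), 32000).values) == 1000
        assert len(compute_envelope(np.ones(44100), 44100).values) == 1000
        assert len(compute_envelope(np.ones(44101), 44100).values) == 1001

    def test_rates_agree_on_same_signal(self):
        # both recording platforms (32 and 44.1 kHz) yield the same envelope
        f = 3123.0
        envs = []
        for rate in (32000, 44100):
            t = np.arange(rate) / rate
            x = 0.5 * np.sin(2 * np.pi * f * t) * np.hanning(rate)
            envs.append(compute_envelope(x, rate).values)
        a, b = envs[0][5:-5], envs[1][5:-5]
        assert np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(a**2)) < 0.02

    def test_all_zero_audio_is_valid(self):
        env = compute_envelope(np.zeros(16000), 16000)
        assert np.all(env.values == 0)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            compute_envelope(np.array([]), 32000)
        with pytest.raises(ValueError):
            compute_envelope(np.ones(100), 4000)


class TestSegmentation:
    def square(self, on_ms, off_ms, n_ms=400):
        v = np.zeros(n_ms)
        v[on_ms:off_ms] = 1.0
        return Envelope(v, 1000)

    def test_single_square_syllable(self):
        segs = segment_syllables(self.square(100, 180), 0.5)
        assert len(segs) == 1
        assert segs[0][0] == pytest.approx(0.100, abs=6e-4)
        assert segs[0][1] == pytest.approx(0.180, abs=6e-4)

    @pytest.mark.parametrize("silence_ms,n_expected", [(3, 1), (4, 1), (5, 2), (8, 2)])
    def test_five_ms_silence_rule(self, silence_ms, n_expected):
        # syllables must be separated by >= 5 ms of silence; shorter
        # interruptions merge
        v = np.zeros(400)
        v[100:150] = 1.0
        v[150 + silence_ms : 210] = 1.0
        segs = segment_syllables(Envelope(v, 1000), 0.5)
        assert len(segs) == n_expected

    def test_short_candidates_discarded(self):
        v = np.zeros(200)
        v[50:56] = 1.0  # 6 ms blip < 10 ms minimum
        v[100:150] = 1.0
        segs = segment_syllables(Envelope(v, 1000), 0.5, min_syllable_ms=10)
        assert len(segs) == 1

    def test_threshold_above_envelope_gives_empty_list(self):
        assert segment_syllables(self.square(100, 180), 2.0) == []

    def test_scale_invariance_with_fractional_threshold(self):
        rng = np.random.default_rng(0)
        v = np.abs(rng.normal(0, 0.05, 500))
        v[100:170] += 1.0
        v[220:300] += 0.7
        env1, env2 = Envelope(v, 1000), Envelope(3.7 * v, 1000)
        s1 = segment_syllables(env1, 0.1 * env1.values.max())
        s2 = segment_syllables(env2, 0.1 * env2.values.max())
        assert s1 == s2


class TestGaps:
    def iv(self, label, on, off):
        return SyllableInterval(label, on, off, rendition_id="r1")

    def test_gap_is_offset_to_onset(self):
        gaps = measure_gaps([self.iv("a", 0.9, 1.0), self.iv("f", 1.1026, 1.18)])
        assert gaps[0].gap_ms == pytest.approx(102.6)
        assert (gaps[0].context, gaps[0].target) == ("a", "f")

    def test_minimum_legal_gap(self):
        gaps = measure_gaps([self.iv("a", 0.0, 0.1), self.iv("b", 0.105, 0.2)])
        assert gaps[0].gap_ms == pytest.approx(5.0)

    def test_overlap_raises(self):
        with pytest.raises(ValueError, match="overlap"):
            measure_gaps([self.iv("a", 0.0, 0.11), self.iv("b", 0.105, 0.2)])

    def test_gap_count_is_transitions_minus_renditions(self, small_corpus):
        corpus, _ = small_corpus
        n_syll = sum(len(r.labels) for b in corpus.birds for r in b.renditions)
        n_rend = sum(len(b.renditions) for b in corpus.birds)
        n_gaps = sum(len(r.gaps_ms) for b in corpus.birds for r in b.renditions)
        assert n_gaps == n_syll - n_rend


class TestRoundTrip:
    def test_boundaries_recovered_from_rendered_audio(self):
        # synthesis -> envelope -> threshold recovers every nominal boundary
        cfg = sg.default_config(n_birds=2, renditions_per_bird=3, seed=21)
        corpus, _ = sg.generate_corpus(cfg)
        peaks, items = [], []
        for bird_id, rid, samples, bounds, labels in sg.simulate.render_corpus(corpus):
            env = compute_envelope(samples, cfg.waveform.rate)
            items.append((env, bounds))
            for on, off in bounds:
                peaks.append(env.values[int(on * 1000) : int(np.ceil(off * 1000))].max())
        thr = 0.1 * np.median(peaks)
        for env, bounds in items:
            segs = segment_syllables(env, thr)
            assert len(segs) == len(bounds)
            for (on, off), (son, soff) in zip(bounds, segs):
                assert abs(son - on) < 0.002
                assert abs(soff - off) < 0.002

    def test_noise_free_recovery_within_one_envelope_sample(self):
        spec = sg.WaveformSpec(noise_floor=0.0)
        x, bounds = sg.synthesize_waveform(
            ["a", "b", "c"], [60.0, 90.0], [0.5, 0.4, 0.6], spec,
            [80.0, 70.0, 90.0], [3000.0, 4000.0, 2500.0],
        )
        env = compute_envelope(x, spec.rate)
        segs = segment_syllables(env, 0.05 * env.values.max())
        assert len(segs) == 3
        for (on, off), (son, soff) in zip(bounds, segs):
            assert abs(son - on) <= 0.001
            assert abs(soff - off) <= 0.001

    def test_label_refinement_snaps_to_envelope(self):
        spec = sg.WaveformSpec(noise_floor=0.0)
        x, bounds = sg.synthesize_waveform(
            ["a", "b"], [80.0], [0.5, 0.5], spec, [80.0, 80.0], [3000.0, 3000.0]
        )
        env = compute_envelope(x, spec.rate)
        rough = [
            SyllableInterval("a", bounds[0][0] - 0.004, bounds[0][1] + 0.006),
            SyllableInterval("b", bounds[1][0] + 0.005, bounds[1][1] - 0.003),
        ]
        refined = refine_intervals(env, rough, 0.1 * env.values.max())
        for iv, (on, off) in zip(refined, bounds):
            assert abs(iv.onset - on) <= 0.0015
            assert abs(iv.offset - off) <= 0.0015


class TestRms:
    def test_constant_signal(self):
        assert rms_amplitude(np.full(1000, 0.4), 1000, 0.1, 0.9) == pytest.approx(0.4)

    def test_sine_over_whole_periods(self):
        t = np.arange(32000) / 32000
        x = 0.6 * np.sin(2 * np.pi * 1000 * t)
        assert rms_amplitude(x, 32000, 0.0, 1.0) == pytest.approx(
            0.6 / np.sqrt(2), abs=1e-6
        )

    def test_baseline_subtraction(self):
        x = np.full(1000, 0.5)
        assert rms_amplitude(x, 1000, 0.0, 1.0, baseline=0.5) == pytest.approx(0.0)

    def test_window_outside_waveform_raises(self):
        with pytest.raises(ValueError):
            rms_amplitude(np.ones(100), 1000, 0.05, 0.2)

    def test_platform_normalization_peaks_at_one(self):
        norm = platform_normalize({"a": 0.2, "b": 0.5, "c": 0.35})
        assert norm["b"] == 1.0
        assert norm["a"] == pytest.approx(0.4)

    def test_baseline_estimate_uses_silent_regions(self):
        v = np.full(300, 0.02)
        v[100:150] = 1.0
        env = Envelope(v, 1000)
        iv = SyllableInterval("a", 0.100, 0.150)
        assert estimate_baseline(env, [iv]) == pytest.approx(0.02)


class TestNormalizeAcrossRecordings:
    def pair_envelope(self, gap_ms, scale=1.0, peak2=0.6):
        # branch syllable at [20, 80) ms, transition syllable after the gap
        n = 300
        v = np.zeros(n)
        v[20:80] = 1.0
        s2 = 80 + int(round(gap_ms))
        v[s2 : s2 + 60] = peak2
        return scale * v

    def test_scale_invariance(self):
        a = [self.pair_envelope(100.0) for _ in range(5)]
        b = [self.pair_envelope(100.0, scale=2.0) for _ in range(5)]
        env_a, env_b, gap_a, gap_b = normalize_across_recordings(a, b)
        assert np.allclose(env_a, env_b)
        assert gap_a == pytest.approx(gap_b)

    def test_median_of_identical_instances_is_instance(self):
        inst = self.pair_envelope(90.0)
        env_a, _env_b, _ga, _gb = normalize_across_recordings(
            [inst] * 5, [inst * 3.0] * 5
        )
        assert np.allclose(env_a, inst[: len(env_a)])

    def test_gap_change_recovered_under_amplitude_drift(self):
        a = [self.pair_envelope(100.0) for _ in range(6)]
        b = [self.pair_envelope(90.0, scale=1.5) for _ in range(6)]
        _ea, _eb, gap_a, gap_b = normalize_across_recordings(a, b)
        assert gap_b - gap_a == pytest.approx(-10.0, abs=2.0)

    def test_instance_filter_enforced(self):
        a = [self.pair_envelope(100.0) for _ in range(4)]
        with pytest.raises(ValueError, match="instances"):
            normalize_across_recordings(a, a)

    def test_zero_peak_raises(self):
        z = [np.zeros(300)] * 5
        with pytest.raises(ValueError):
            normalize_across_recordings(z, z)
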