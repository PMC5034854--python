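"""Feature surrogates: closed-form checks on constructed signals and
closure against the generator's ground truth."""

import numpy as np
import pytest

from neoictal import features as F
from neoictal.core import EEGRecord, SeizureAnnotation
from neoictal.simulate import SeizureSpec

from conftest import FS, embed_seizure, make_tone_record


class TestPeakAmplitude:
    @pytest.mark.parametrize("freq", [0.5, 1.0, 2.0, 6.0, 10.0, 13.0])
    def test_pure_tone_within_one_percent(self, freq):
        rec, ann = make_tone_record(freq, amplitude_uV=50.0)
        assert F.peak_amplitude(rec, ann) == pytest.approx(100.0, rel=0.01)

    def test_flat_zero_measures_zero(self):
        rec = EEGRecord(np.zeros((8, int(80 * FS))), FS)
        assert F.peak_amplitude(rec, SeizureAnnotation(20, 40)) == 0.0

    def test_rendered_seizure_closure(self):
        spec = SeizureSpec(onset_s=60, duration_s=90, peak_amplitude_uV=123.0,
                           channels_onset=2, channels_peak=4,
                           freq_start=2.2, freq_mid=1.8, freq_end=1.4)
        rec, ann = embed_seizure(spec, seed=21)
        assert F.peak_amplitude(rec, ann) == pytest.approx(123.0, rel=0.1)

    def test_window_outside_record_rejected(self):
        rec = EEGRecord(np.zeros((8, int(30 * FS))), FS)
        with pytest.raises(F.FeatureError):
            F.peak_amplitude(rec, SeizureAnnotation(10, 40))


class TestSegmentFrequency:
    def test_pure_tone_any_segment(self):
        rec, ann = make_tone_record(6.0, 60.0)
        for seg in ("start", "mid", "end"):
            assert F.segment_frequency(rec, ann, seg) == pytest.approx(6.0, abs=0.25)

    def test_rendered_sweep_closure(self):
        spec = SeizureSpec(onset_s=60, duration_s=80, peak_amplitude_uV=150.0,
                           channels_onset=2, channels_peak=3,
                           freq_start=2.0, freq_mid=1.5, freq_end=1.0,
                           rhythmicity_jitter=0.03)
        rec, ann = embed_seizure(spec, seed=22)
        for seg, expected in (("start", 2.0), ("mid", 1.5), ("end", 1.0)):
            assert F.segment_frequency(rec, ann, seg) == pytest.approx(expected, abs=0.25)

    def test_white_noise_flags_low_confidence(self):
        rng = np.random.default_rng(0)
        rec = EEGRecord(rng.standard_normal((8, int(80 * FS))), FS)
        _, confident = F.segment_frequency(rec, SeizureAnnotation(20, 40),
                                           "start", return_confidence=True)
        assert not confident

    def test_spike_train_rate(self):
        spec = SeizureSpec(onset_s=60, duration_s=80, peak_amplitude_uV=140.0,
                           morphology_onset=4, morphology_peak=4,
                           channels_onset=2, channels_peak=3,
                           freq_start=1.5, freq_mid=1.4, freq_end=1.2,
                           rhythmicity_jitter=0.08)
        rec, ann = embed_seizure(spec, seed=23)
        assert F.segment_frequency(rec, ann, "start") == pytest.approx(1.5, abs=0.25)


class TestFrequencyVariability:
    def test_rendered_sweep_closed_form(self):
        spec = SeizureSpec(onset_s=60, duration_s=80, peak_amplitude_uV=150.0,
                           channels_onset=2, channels_peak=3,
                           freq_start=2.0, freq_mid=1.5, freq_end=1.0,
                           rhythmicity_jitter=0.03)
        rec, ann = embed_seizure(spec, seed=24)
        # sample SD (n-1) of (2, 1.5, 1) is exactly 0.5
        assert F.frequency_variability(rec, ann) == pytest.approx(0.5, abs=0.15)

    def test_constant_frequency_near_zero(self):
        rec, ann = make_tone_record(4.0, 60.0)
        assert F.frequency_variability(rec, ann) == pytest.approx(0.0, abs=0.05)


class TestMorphology:
    def test_band_rules_on_tones(self):
        for freq, cat in ((2.0, 1), (6.0, 2), (10.0, 3)):
            rec, ann = make_tone_record(freq, 80.0)
            assert F.classify_morphology(rec, ann, "onset") == cat
            assert F.classify_morphology(rec, ann, "peak") == cat

    @pytest.mark.parametrize("morph", [4, 5])
    def test_transient_morphologies_closure(self, morph):
        spec = SeizureSpec(onset_s=60, duration_s=80, peak_amplitude_uV=130.0,
                           morphology_onset=morph, morphology_peak=morph,
                           channels_onset=2, channels_peak=4,
                           freq_start=1.5, freq_mid=1.3, freq_end=1.1,
                           rhythmicity_jitter=0.08)
        rec, ann = embed_seizure(spec, seed=25 + morph)
        assert F.classify_morphology(rec, ann, "peak") == morph

    def test_change_flag(self):
        assert F.morphology_change(1, 1) is False
        assert F.morphology_change(1, 2) is True
        with pytest.raises(ValueError):
            F.morphology_change(0, 2)

    def test_flat_window_signalled(self):
        rec = EEGRecord(np.zeros((8, int(80 * FS))), FS)
        with pytest.raises(F.NoInvolvedChannelError):
            F.classify_morphology(rec, SeizureAnnotation(20, 40), "onset")


class TestRhythmicity:
    @pytest.mark.parametrize("jitter,expected", [(0.0, 3), (0.25, 2), (0.5, 1)])
    @pytest.mark.parametrize("seed", [31, 32])
    def test_injected_jitter_recovered(self, jitter, expected, seed):
        spec = SeizureSpec(onset_s=60, duration_s=100, peak_amplitude_uV=150.0,
                           channels_onset=2, channels_peak=4,
                           freq_start=2.0, freq_mid=1.9, freq_end=1.8,
                           rhythmicity_jitter=jitter)
        rec, ann = embed_seizure(spec, seed=seed)
        assert F.rhythmicity_score(rec, ann) == expected

    def test_too_few_cycles_signalled(self):
        rec, ann = make_tone_record(0.5, 60.0, onset_s=20, duration_s=6,
                                    total_s=60)
        with pytest.raises(F.FeatureError):
            F.rhythmicity_score(rec, ann)


class TestBackgroundScore:
    @pytest.mark.parametrize("grade", [1, 2, 3, 4])
    def test_generated_grades_recovered(self, grade):
        from neoictal.simulate import BackgroundSpec, generate_background

        rec = generate_background(BackgroundSpec.for_grade(grade), 360, seed=grade)
        assert F.background_score(rec) == grade

    def test_insufficient_background_signalled(self):
        from neoictal.simulate import BackgroundSpec, generate_background

        rec = generate_background(BackgroundSpec.for_grade(1), 200, seed=0)
        with pytest.raises(F.FeatureError):
            F.background_score(rec, SeizureAnnotation(10, 150))


class TestChannelsInvolved:
    def test_rendered_spread_recovered(self):
        spec = SeizureSpec(onset_s=60, duration_s=90, peak_amplitude_uV=150.0,
                           channels_onset=1, channels_peak=5,
                           freq_start=2.0, freq_mid=1.6, freq_end=1.2)
        rec, ann = embed_seizure(spec, seed=33)
        assert F.channels_involved(rec, ann, "onset") == 1
        assert F.channels_involved(rec, ann, "peak") == 5

    def test_noiseless_render_exact(self):
        spec = SeizureSpec(onset_s=30, duration_s=60, peak_amplitude_uV=80.0,
                           channels_onset=2, channels_peak=6,
                           freq_start=2.5, freq_mid=2.0, freq_end=1.5)
        from neoictal.simulate import render_seizure

        wav = render_seizure(spec, seed=34)
        data = np.zeros((8, int(150 * FS)))
        data[:, int(30 * FS): int(30 * FS) + wav.shape[1]] = wav
        rec = EEGRecord(data, FS)
        ann = SeizureAnnotation(30, 60)
        assert F.channels_involved(rec, ann, "onset") == 2
        assert F.channels_involved(rec, ann, "peak") == 6

    def test_background_only_counts_zero(self):
        from neoictal.simulate import BackgroundSpec, generate_background

        rec = generate_background(BackgroundSpec.for_grade(1), 300, seed=7)
        ann = SeizureAnnotation(200, 60)  # nothing ictal there
        assert F.channels_involved(rec, ann, "peak") == 0


class TestExtractAll:
    def test_closure_on_rendered_seizure(self):
        spec = SeizureSpec(onset_s=90, duration_s=80, peak_amplitude_uV=140.0,
                           morphology_onset=1, morphology_peak=2,
                           channels_onset=2, channels_peak=4,
                           freq_start=2.5, freq_mid=4.8, freq_end=4.2,
                           rhythmicity_jitter=0.04)
        rec, ann = embed_seizure(spec, total_s=500, seed=35)
        out = F.extract_all(rec, ann)
        assert out.errors == {}
        assert out.peak_amplitude_uV == pytest.approx(140.0, rel=0.1)
        assert out.duration_s == ann.duration_s
        assert out.morphology_onset == 1
        assert out.morphology_peak == 2
        assert out.morphology_changed is True
        assert out.channels_onset == 2
        assert out.channels_peak == 4
        assert out.background_score == 1

    def test_zero_duration_rejected(self):
        rec = EEGRecord(np.zeros((8, int(60 * FS))), FS)
        with pytest.raises(F.FeatureError):
            F.extract_all(rec, SeizureAnnotation(10, 0))

    def test_deterministic(self):
        spec = SeizureSpec(onset_s=60, duration_s=70, peak_amplitude_uV=120.0,
                           channels_onset=2, channels_peak=3)
        rec, ann = embed_seizure(spec, seed=36)
        a, b = F.extract_all(rec, ann), F.extract_all(rec, ann)
        assert a == b

    @pytest.mark.parametrize("c", [0.5, 2.0, 5.0])
    def test_scale_equivariance(self, c):
        spec = SeizureSpec(onset_s=60, duration_s=80, peak_amplitude_uV=120.0,
                           channels_onset=2, channels_peak=4,
                           freq_start=2.0, freq_mid=1.6, freq_end=1.3)
        rec, ann = embed_seizure(spec, seed=37)
        base = F.extract_all(rec, ann)
        scaled_rec = rec.copy()
        scaled_rec.data *= c
        scaled = F.extract_all(scaled_rec, ann)
        assert scaled.peak_amplitude_uV == pytest.approx(
            c * base.peak_amplitude_uV, rel=0.02)
        for attr in ("morphology_onset", "morphology_peak", "rhythmicity_score",
                     "channels_onset", "channels_peak", "background_score"):
            assert getattr(scaled, attr) == getattr(base, attr)
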