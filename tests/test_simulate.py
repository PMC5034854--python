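"""Generator contracts: graded backgrounds, controllable ictal waveforms,
paired drug-effect cohorts, determinism."""

import numpy as np
import pytest
from scipy import signal as sps

from neoictal.io import write_annotations
from neoictal.simulate import (BackgroundSpec, DrugEffect, SeizureSpec,
                               SubjectSim, draw_subject_sim,
                               generate_background, generate_cohort,
                               generate_subject, render_seizure)

FS = 250.0


def quiet_runs(record, threshold_uV=15.0, min_s=2.0):
    """Independent inter-burst measurement: moving-RMS envelope threshold."""
    w = int(0.5 * FS)
    env = np.sqrt(np.convolve(np.mean(record.data**2, axis=0),
                              np.ones(w) / w, mode="same"))
    quiet = 4.0 * env < threshold_uV
    runs, start = [], None
    for i, q in enumerate(quiet):
        if q and start is None:
            start = i
        elif not q and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(quiet)))
    return [(a / FS, b / FS) for a, b in runs if (b - a) / FS >= min_s]


class TestBackground:
    def test_grade1_is_continuous(self):
        rec = generate_background(BackgroundSpec.for_grade(1), 60, seed=0)
        assert rec.n_channels == 8
        assert quiet_runs(rec) == []

    def test_grade3_ibis_in_range(self):
        rec = generate_background(BackgroundSpec.for_grade(3), 300, seed=1)
        runs = [(a, b) for a, b in quiet_runs(rec)
                if a > 1.0 and b < rec.duration_s - 1.0]  # interior gaps only
        assert runs, "grade 3 background must be discontinuous"
        for a, b in runs:
            assert 10.0 <= b - a <= 60.0

    def test_grade4_quiet_and_long_ibis(self):
        rec = generate_background(BackgroundSpec.for_grade(4), 300, seed=2)
        runs = [(a, b) for a, b in quiet_runs(rec) if a > 1.0 and b < 299.0]
        assert runs
        w = int(0.5 * FS)
        env_pp = 4.0 * np.sqrt(np.convolve(np.mean(rec.data**2, axis=0),
                                           np.ones(w) / w, mode="same"))
        for a, b in runs:
            assert b - a > 60.0
            assert np.median(env_pp[int(a * FS): int(b * FS)]) < 10.0

    def test_band_limited(self):
        rec = generate_background(BackgroundSpec.for_grade(1), 120, seed=3)
        f, p = sps.welch(rec.data[0], fs=FS, nperseg=4096)
        inband = np.mean(p[(f >= 1) & (f <= 60)])
        outband = np.mean(p[f >= 90])
        assert outband < inband / 100.0

    @pytest.mark.parametrize("kwargs", [
        dict(grade=5),
        dict(grade=2, ibi_s=12.0, interburst_amplitude_uV=10),
        dict(grade=3, ibi_s=5.0),
        dict(grade=4, ibi_s=80.0, interburst_amplitude_uV=12.0),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BackgroundSpec(burst_amplitude_uV=40.0, **kwargs)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_background(BackgroundSpec.for_grade(1), 0.0)


class TestRenderSeizure:
    def test_midpoint_amplitude(self):
        spec = SeizureSpec(onset_s=0, duration_s=100, peak_amplitude_uV=100,
                           channels_onset=1, channels_peak=3,
                           freq_start=2.0, freq_mid=1.8, freq_end=1.5,
                           rhythmicity_jitter=0.0)
        wav = render_seizure(spec, seed=4)
        mid = wav[:, int(45 * FS): int(55 * FS)]
        best = np.argmax(np.max(np.abs(mid), axis=1))
        x = mid[best]
        # max cycle peak-to-trough via extrema of the clean waveform
        pp = x.max() - x.min()
        assert pp == pytest.approx(100, rel=0.10)

    def test_channel_recruitment(self):
        spec = SeizureSpec(onset_s=0, duration_s=90, peak_amplitude_uV=120,
                           channels_onset=1, channels_peak=5,
                           freq_start=2.0, freq_mid=1.5, freq_end=1.0)
        wav = render_seizure(spec, seed=5)
        onset_active = np.sum(np.ptp(wav[:, : int(10 * FS)], axis=1) > 1.0)
        mid_active = np.sum(np.ptp(wav[:, int(40 * FS): int(50 * FS)], axis=1) > 1.0)
        assert onset_active == 1
        assert mid_active == 5

    def test_frequency_sweep(self):
        spec = SeizureSpec(onset_s=0, duration_s=60, peak_amplitude_uV=100,
                           channels_onset=2, channels_peak=2,
                           freq_start=2.0, freq_mid=1.5, freq_end=1.0,
                           rhythmicity_jitter=0.0)
        wav = render_seizure(spec, seed=6)
        best = np.argmax(np.ptp(wav, axis=1))
        for t0, expected in ((0.0, 2.0), (27.5, 1.5), (55.0, 1.0)):
            seg = wav[best, int(t0 * FS): int((t0 + 5) * FS)]
            f, p = sps.periodogram(seg, fs=FS, nfft=1 << 16)
            sel = (f >= 0.5) & (f <= 13)
            assert f[sel][np.argmax(p[sel])] == pytest.approx(expected, abs=0.25)

    def test_too_many_channels_rejected(self, montage):
        spec = SeizureSpec(onset_s=0, duration_s=30, channels_onset=1,
                           channels_peak=8)
        render_seizure(spec, montage, seed=0)  # 8 is the montage size: fine
        with pytest.raises(ValueError):
            SeizureSpec(onset_s=0, duration_s=30, channels_onset=1,
                        channels_peak=9)


class TestDrugEffect:
    def test_identity_effect_preserves_render(self):
        sim = draw_subject_sim("a", 7, drug_effect=DrugEffect(), max_count=2,
                               record_duration_s=500.0)
        pre, post, _ = generate_subject(sim)
        assert np.array_equal(pre.data, post.data)

    def test_amplitude_scaling_matches_measured_effect(self):
        spec = SeizureSpec(onset_s=0, duration_s=60, peak_amplitude_uV=123.0,
                           channels_onset=2, channels_peak=4)
        out = DrugEffect(amplitude_scale=0.435, channel_delta=0).apply(spec)
        assert out.peak_amplitude_uV == pytest.approx(53.5, abs=0.01)

    def test_channel_reduction_floors_at_one(self):
        spec = SeizureSpec(onset_s=0, duration_s=60, channels_onset=1,
                           channels_peak=4)
        assert DrugEffect(channel_delta=1).apply(spec).channels_peak == 3
        assert DrugEffect(channel_delta=7).apply(spec).channels_peak == 1
        assert DrugEffect(channel_delta=7).apply(spec).channels_onset == 1


class TestCohort:
    def test_deterministic_annotations(self, tmp_path):
        paths = []
        for run in (1, 2):
            sample = generate_cohort(5, DrugEffect(0.435, 1), seed=42,
                                     render=False)
            p = tmp_path / f"ann{run}.tsv"
            write_annotations(sample.annotations, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_counts_within_observed_range(self):
        sample = generate_cohort(18, DrugEffect(), seed=3, render=False,
                                 record_duration_s=1e9)
        for sim in sample.sims:
            assert 1 <= len(sim.pre_seizures) <= 68

    def test_subject_without_seizures_rejected(self):
        with pytest.raises(ValueError):
            SubjectSim(subject_id="x", background=BackgroundSpec.for_grade(1),
                       pre_seizures=[], post_seizures=[], rng_seed=0)

    def test_overlapping_seizures_rejected(self):
        s1 = SeizureSpec(onset_s=10, duration_s=60)
        s2 = SeizureSpec(onset_s=40, duration_s=30)
        with pytest.raises(ValueError):
            SubjectSim(subject_id="x", background=BackgroundSpec.for_grade(1),
                       pre_seizures=[s1, s2], post_seizures=[s1], rng_seed=0)

    def test_onset_channels_never_exceed_peak(self):
        sample = generate_cohort(12, DrugEffect(0.435, 1), seed=9, render=False)
        for sim in sample.sims:
            for s in sim.pre_seizures + sim.post_seizures:
                assert 1 <= s.channels_onset <= s.channels_peak <= 8
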