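import warnings

import numpy as np
import pytest

from neoictal.core import EEGRecord, SeizureAnnotation
from neoictal.montage import default_montage
from neoictal.simulate import (BackgroundSpec, DrugEffect, SeizureSpec,
                               generate_background, generate_cohort,
                               render_seizure)

warnings.filterwarnings("ignore", category=RuntimeWarning)

FS = 250.0


@pytest.fixture(scope="session")
def montage():
    return default_montage()


def make_tone_record(freq_hz: float, amplitude_uV: float,
                     onset_s: float = 20.0, duration_s: float = 40.0,
                     total_s: float = 80.0, channel: int = 0,
                     n_channels: int = 8) -> tuple[EEGRecord, SeizureAnnotation]:
    """A record that is zero except for a pure tone during the annotation."""
    n = int(total_s * FS)
    t = np.arange(n) / FS
    data = np.zeros((n_channels, n))
    i0, i1 = int(onset_s * FS), int((onset_s + duration_s) * FS)
    data[channel, i0:i1] = amplitude_uV * np.sin(2 * np.pi * freq_hz * t[i0:i1])
    rec = EEGRecord(data, FS, [f"ch{i}" for i in range(n_channels)])
    return rec, SeizureAnnotation(onset_s, duration_s)


def embed_seizure(spec: SeizureSpec, bg_grade: int = 1, total_s: float = 240.0,
                  seed: int = 0):
    """Background record with one rendered seizure added at its onset."""
    bg = generate_background(BackgroundSpec.for_grade(bg_grade), total_s, seed=seed)
    wav = render_seizure(spec, seed=seed + 1000)
    i0 = int(spec.onset_s * FS)
    bg.data[:, i0: i0 + wav.shape[1]] += wav[:, : bg.n_samples - i0]
    return bg, SeizureAnnotation(spec.onset_s, spec.duration_s)


@pytest.fixture(scope="session")
def demo_cohort():
    """Small rendered cohort shared by closure and detector tests."""
    return generate_cohort(4, DrugEffect(amplitude_scale=0.435, channel_delta=1),
                           seed=11, max_count=3, record_duration_s=700.0)


@pytest.fixture(scope="session")
def trained_model(demo_cohort):
    """Detector trained on a disjoint small cohort (slow: ~40 s, shared)."""
    from neoictal.detector import train

    sample = generate_cohort(3, DrugEffect(), seed=901, max_count=3,
                             record_duration_s=500.0)
    records, anns = [], []
    for (sid, period), rec in sample.records.items():
        records.append(rec)
        anns.append([a for a in sample.annotations
                     if a.subject_id == sid and a.period == period])
    return train(records, anns, seed=5)
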