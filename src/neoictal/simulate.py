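"""Synthetic neonatal EEG cohorts with known ground-truth seizure parameters.

The generator emulates the kind of data produced by cot-side video-EEG
monitoring of term neonates: an 8-channel bipolar record whose background
ranges from continuous mixed-frequency activity to an inactive
burst-suppression pattern, interrupted by electrographic seizures.  Each
seizure is synthesised cycle by cycle so that every quantity the feature
module later measures — peak-to-trough amplitude, discharge frequency in
the first/middle/last segments, discharge-interval jitter, waveform
morphology at onset and peak, and the number of channels recruited — is an
explicit, recoverable ground-truth parameter.

A configurable anticonvulsant effect transforms post-dose seizures by
scaling their amplitude and reducing the number of channels involved,
mimicking the measured action of a phenobarbital loading dose.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .core import EEGRecord, SeizureAnnotation
from .montage import MontageSpec, default_montage

__all__ = [
    "BackgroundSpec",
    "SeizureSpec",
    "DrugEffect",
    "SubjectSim",
    "CohortSample",
    "generate_background",
    "render_seizure",
    "generate_subject",
    "draw_subject_sim",
    "generate_cohort",
]

#: Ictal morphology categories (dominant discharge waveform).
MORPH_RDD = 1   # rhythmic delta (0.5 – <4 Hz)
MORPH_RDT = 2   # rhythmic theta (4 – <8 Hz)
MORPH_RDA = 3   # rhythmic alpha (8 – 13 Hz)
MORPH_SPIKE = 4  # spikes / sharp waves (transients < 200 ms)
MORPH_SPW = 5   # spike-and-wave / sharp-and-slow-wave complexes

#: Frequency band (Hz) for each rhythmic morphology; standard clinical edges.
MORPH_BANDS = {MORPH_RDD: (0.5, 4.0), MORPH_RDT: (4.0, 8.0), MORPH_RDA: (8.0, 13.0)}

_TRANSIENT_MORPHS = (MORPH_SPIKE, MORPH_SPW)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackgroundSpec:
    """Background EEG abnormality grade with burst/inter-burst structure.

    Grades follow the 4-point neonatal background score: 1 normal/mildly
    abnormal continuous EEG, 2 moderate abnormality (inter-burst interval
    < 10 s), 3 severe abnormality (IBI 10–60 s), 4 inactive trace
    (background < 10 μV, IBI > 60 s).
    """

    grade: int = 1
    burst_amplitude_uV: float = 30.0     # peak-to-peak envelope of bursts
    ibi_s: float = 0.0                   # mean inter-burst interval (grades 2-4)
    interburst_amplitude_uV: float = 0.0  # peak-to-peak envelope between bursts

    def __post_init__(self) -> None:
        if self.grade not in (1, 2, 3, 4):
            raise ValueError(f"background grade must be 1-4, got {self.grade}")
        if self.burst_amplitude_uV <= 0:
            raise ValueError("burst_amplitude_uV must be positive")
        if self.grade == 2 and not (0 < self.ibi_s < 10):
            raise ValueError("grade 2 requires inter-burst interval < 10 s")
        if self.grade == 3 and not (10 <= self.ibi_s <= 60):
            raise ValueError("grade 3 requires inter-burst interval in [10, 60] s")
        if self.grade == 4:
            if self.ibi_s <= 60:
                raise ValueError("grade 4 requires inter-burst interval > 60 s")
            if self.interburst_amplitude_uV >= 10:
                raise ValueError("grade 4 requires inter-burst amplitude < 10 μV")

    @classmethod
    def for_grade(cls, grade: int) -> "BackgroundSpec":
        """Representative defaults for each background grade."""
        if grade == 1:
            return cls(1, burst_amplitude_uV=30.0)
        if grade == 2:
            return cls(2, burst_amplitude_uV=50.0, ibi_s=6.0, interburst_amplitude_uV=12.0)
        if grade == 3:
            return cls(3, burst_amplitude_uV=60.0, ibi_s=30.0, interburst_amplitude_uV=8.0)
        if grade == 4:
            return cls(4, burst_amplitude_uV=40.0, ibi_s=80.0, interburst_amplitude_uV=5.0)
        raise ValueError(f"background grade must be 1-4, got {grade}")


@dataclass(frozen=True)
class SeizureSpec:
    """Ground-truth parameters of one synthetic electrographic seizure.

    ``peak_amplitude_uV`` is the peak-to-trough amplitude of the highest
    amplitude discharge at the temporal midpoint, on the most involved
    channel.  ``freq_start/mid/end`` give the discharge frequency (Hz for
    rhythmic morphologies, transients per second for spike morphologies)
    in the first, middle and final analysis segments.
    ``rhythmicity_jitter`` is the coefficient of variation of successive
    cycle periods (0 = metronomic).
    """

    onset_s: float
    duration_s: float
    morphology_onset: int = MORPH_RDD
    morphology_peak: int = MORPH_RDD
    freq_start: float = 2.0
    freq_mid: float = 1.5
    freq_end: float = 1.0
    peak_amplitude_uV: float = 120.0
    channels_onset: int = 2
    channels_peak: int = 4
    rhythmicity_jitter: float = 0.1

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for m in (self.morphology_onset, self.morphology_peak):
            if m not in (1, 2, 3, 4, 5):
                raise ValueError(f"morphology category must be 1-5, got {m}")
        for f in (self.freq_start, self.freq_mid, self.freq_end):
            if f <= 0:
                raise ValueError("discharge frequencies must be positive")
        if self.peak_amplitude_uV <= 0:
            raise ValueError("peak_amplitude_uV must be positive")
        if not (1 <= self.channels_onset <= 8 and 1 <= self.channels_peak <= 8):
            raise ValueError("channel counts must be in 1-8")
        if self.channels_onset > self.channels_peak:
            raise ValueError("channels_onset must not exceed channels_peak "
                             "(seizures spread, they do not shrink, onset→peak)")
        if self.rhythmicity_jitter < 0 or self.rhythmicity_jitter > 0.55:
            raise ValueError("rhythmicity_jitter must be in [0, 0.55]")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class DrugEffect:
    """Multiplicative amplitude scaling and channel-count reduction applied
    to post-dose seizures (floor of one channel)."""

    amplitude_scale: float = 1.0
    channel_delta: int = 0
    applies_to: str = "post"

    def __post_init__(self) -> None:
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")
        if self.channel_delta < 0:
            raise ValueError("channel_delta must be non-negative")

    def apply(self, spec: SeizureSpec) -> SeizureSpec:
        ch_on = max(1, spec.channels_onset - self.channel_delta)
        ch_pk = max(1, spec.channels_peak - self.channel_delta)
        return replace(
            spec,
            peak_amplitude_uV=spec.peak_amplitude_uV * self.amplitude_scale,
            channels_onset=min(ch_on, ch_pk),
            channels_peak=ch_pk,
        )


#: Phenobarbital loading-dose effect measured in the 18-infant cohort:
#: 56.5 % median amplitude drop and one fewer channel recruited at peak.
PHENOBARBITAL_EFFECT = DrugEffect(amplitude_scale=0.435, channel_delta=1)


@dataclass
class SubjectSim:
    """Full ground truth for one simulated subject (both periods)."""

    subject_id: str
    background: BackgroundSpec
    pre_seizures: list[SeizureSpec]
    post_seizures: list[SeizureSpec]
    drug_effect: DrugEffect = field(default_factory=DrugEffect)
    rng_seed: int = 0
    record_duration_s: float = 1200.0

    def __post_init__(self) -> None:
        if not self.pre_seizures or not self.post_seizures:
            raise ValueError("subjects must seize in both periods "
                             "(inclusion requires seizures pre and post dose)")
        for sz_list in (self.pre_seizures, self.post_seizures):
            _check_non_overlapping(sz_list)


def _check_non_overlapping(seizures: list[SeizureSpec]) -> None:
    ordered = sorted(seizures, key=lambda s: s.onset_s)
    for a, b in zip(ordered, ordered[1:]):
        if a.end_s > b.onset_s:
            raise ValueError(
                f"seizures overlap: [{a.onset_s}, {a.end_s}) and [{b.onset_s}, {b.end_s})"
            )


# ---------------------------------------------------------------------------
# background synthesis
# ---------------------------------------------------------------------------

_noise_sos_cache: dict = {}


def _noise_sos(fs: float, band: tuple[float, float]) -> np.ndarray:
    """IIR cascade: pink (≈1/f power) shaping shelves + band-limiting."""
    key = (fs, band)
    if key not in _noise_sos_cache:
        sections = []
        # first-order pole/zero shelves, poles a factor ~2.2 below their
        # zeros, log-spaced across the band: ≈ −10 dB/decade overall
        for fp, fz in ((0.7, 1.55), (3.5, 7.8), (17.5, 39.0)):
            wp, wz = 2 * np.pi * fp, 2 * np.pi * fz
            b, a = sps.bilinear([1.0 / wz, 1.0], [1.0 / wp, 1.0], fs)
            sections.append(sps.tf2sos(b, a)[0])
        lo, hi = band
        hi = min(hi, fs / 2 * 0.95)
        bp = sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
        _noise_sos_cache[key] = np.vstack([np.asarray(sections), bp])
    return _noise_sos_cache[key]


def _colored_noise(rng: np.random.Generator, n: int, fs: float,
                   band: tuple[float, float] = (0.5, 70.0)) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band`` with ≈1/f power."""
    warmup = int(round(2.0 * fs))  # discard the filter start-up transient
    white = rng.standard_normal(n + warmup)
    x = sps.sosfilt(_noise_sos(fs, band), white)[warmup:]
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


# Peak-to-peak envelope ≈ 4 sigma for Gaussian noise.
_PP_PER_SIGMA = 4.0

_BURST_DUR_RANGE = {2: (2.0, 6.0), 3: (1.0, 4.0), 4: (1.0, 3.0)}
_IBI_HARD_RANGE = {2: (1.5, 9.5), 3: (11.0, 58.0), 4: (62.0, 240.0)}
_RAMP_S = 0.3  # cosine ramp between burst and inter-burst states


def _burst_envelope(rng: np.random.Generator, n: int, fs: float,
                    spec: BackgroundSpec) -> np.ndarray:
    """Multiplicative envelope alternating bursts (1) and quiet gaps (q)."""
    q = spec.interburst_amplitude_uV / spec.burst_amplitude_uV
    lo, hi = _IBI_HARD_RANGE[spec.grade]
    ibi_lo = max(lo, 0.7 * spec.ibi_s)
    ibi_hi = max(ibi_lo + 0.1, min(hi, 1.3 * spec.ibi_s))
    b_lo, b_hi = _BURST_DUR_RANGE[spec.grade]
    env = np.full(n, q)
    ramp = int(round(_RAMP_S * fs))
    t = 0.0
    in_burst = True
    while t * fs < n:
        if in_burst:
            seg = rng.uniform(b_lo, b_hi)
            i0, i1 = int(round(t * fs)), min(n, int(round((t + seg) * fs)))
            env[i0:i1] = 1.0
            # cosine shoulders live inside the burst so the measured quiet
            # gap equals the drawn inter-burst interval exactly
            m = min(ramp, (i1 - i0) // 2)
            if m > 1:
                shoulder = 0.5 - 0.5 * np.cos(np.linspace(0, np.pi, m))
                env[i0:i0 + m] = q + (1.0 - q) * shoulder
                env[i1 - m:i1] = q + (1.0 - q) * shoulder[::-1]
        else:
            seg = rng.uniform(ibi_lo, ibi_hi)
        t += seg
        in_burst = not in_burst
    return env


def generate_background(spec: BackgroundSpec, duration_s: float,
                        montage: MontageSpec | None = None,
                        seed: int | np.random.Generator = 0) -> EEGRecord:
    """Render graded background EEG for every channel of the montage.

    Grade 1 is continuous mixed-frequency activity; grades 2–4 alternate
    bursts with quiet inter-burst gaps whose durations fall inside the
    grade's defining IBI range.  All activity is band-limited to 0.5–70 Hz,
    matching the acquisition filter bandwidth of the ICU monitors.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    montage = montage or default_montage()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fs = montage.sampling_rate
    n = int(round(duration_s * fs))
    sigma = spec.burst_amplitude_uV / _PP_PER_SIGMA
    data = np.empty((montage.n_channels, n))
    if spec.grade == 1:
        for c in range(montage.n_channels):
            data[c] = sigma * _colored_noise(rng, n, fs)
    else:
        # one burst/quiet schedule shared across channels (burst suppression
        # is synchronous over the scalp), independent noise carriers per channel
        env = _burst_envelope(rng, n, fs, spec)
        for c in range(montage.n_channels):
            data[c] = sigma * env * _colored_noise(rng, n, fs)
    return EEGRecord(data=data, sampling_rate=fs, channel_labels=montage.channel_labels)


# ---------------------------------------------------------------------------
# ictal waveform synthesis
# ---------------------------------------------------------------------------

def _freq_profile(spec: SeizureSpec):
    """Piecewise hold–ramp–hold instantaneous discharge frequency.

    The start/mid/end frequencies are held constant over the analysis
    segments that the feature module later measures (first segment, a
    plateau around the midpoint, and the final segment), with linear ramps
    in between, so the rendered sweep is recoverable segment by segment.
    """
    T = spec.duration_s
    seg = min(5.0, T / 3.0)          # analysis segment length
    half = min(5.0, T / 6.0)         # half-width of the mid plateau
    knots_t = np.array([0.0, seg, T / 2 - half, T / 2 + half, T - seg, T])
    knots_f = np.array([spec.freq_start, spec.freq_start, spec.freq_mid,
                        spec.freq_mid, spec.freq_end, spec.freq_end])

    def f_of_t(t: float) -> float:
        return float(np.interp(t, knots_t, knots_f))

    return f_of_t


def _spike_template(n: int) -> np.ndarray:
    """Biphasic sharp transient, peak-to-trough normalised to 2."""
    u = np.linspace(0.0, 1.0, n, endpoint=False)
    w = np.sin(2 * np.pi * u) * np.hanning(n)
    span = w.max() - w.min()
    return 2.0 * w / span if span > 0 else w


def _render_cycle(morph: int, n: int, spike_n: int) -> np.ndarray:
    """One discharge cycle of ``n`` samples, peak-to-trough 2."""
    if morph in MORPH_BANDS:
        u = np.arange(n) / n
        return np.sin(2 * np.pi * u)
    if n < 8:  # truncated stub cycle at the seizure edge
        u = np.arange(n) / max(n, 1)
        return np.sin(2 * np.pi * u)
    spike_n = min(spike_n, max(4, n // 2))
    cyc = np.zeros(n)
    cyc[:spike_n] = _spike_template(spike_n)
    if morph == MORPH_SPW:
        # slow wave of opposite polarity filling the rest of the cycle,
        # comparable in size to the spike as in clinical complexes; the
        # whole complex is normalised so its overall peak-to-trough
        # (spike peak to wave trough) is 2
        rest = n - spike_n
        if rest > 4:
            cyc[spike_n:] = -1.2 * np.sin(np.pi * np.arange(rest) / rest)
        span = cyc.max() - cyc.min()
        cyc *= 2.0 / span
    return cyc


def _amp_envelope(t: np.ndarray, T: float) -> np.ndarray:
    """Amplitude build-up peaking at the temporal midpoint (0.6 edge, 1 mid)."""
    env = 0.6 + 0.4 * np.sin(np.pi * np.clip(t, 0, T) / T)
    taper = min(2.0, T / 10.0)
    env *= np.clip(t / taper, 0, 1) * np.clip((T - t) / taper, 0, 1)
    return np.clip(env, 0, 1)


def render_seizure(spec: SeizureSpec, montage: MontageSpec | None = None,
                   seed: int | np.random.Generator = 0) -> np.ndarray:
    """Render one seizure as a ``(n_channels, n_samples)`` ictal waveform in μV.

    The waveform is built cycle by cycle: each cycle's period is the
    instantaneous discharge period at its start time, perturbed by a
    uniform jitter whose coefficient of variation equals
    ``rhythmicity_jitter``.  The first ``channels_onset`` channels (in a
    random recruitment order) are active from onset; channels recruited
    later switch on after the onset analysis window and are fully involved
    by the middle third.  The returned array is the ictal component only —
    add it to a background record to obtain a realistic raw trace.
    """
    montage = montage or default_montage()
    if spec.channels_peak > montage.n_channels:
        raise ValueError(
            f"channels_peak={spec.channels_peak} exceeds montage size {montage.n_channels}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fs = montage.sampling_rate
    T = spec.duration_s
    n = int(round(T * fs))
    f_of_t = _freq_profile(spec)

    # morphology switches from the onset to the peak category ahead of the
    # peak analysis window
    switch_t = T / 3.0 if T < 30 else max(10.0, 0.35 * T)
    spike_w = rng.uniform(0.05, 0.09)            # transient duration, < 200 ms
    spike_n = max(4, int(round(spike_w * fs)))
    a = min(0.9, np.sqrt(3.0) * spec.rhythmicity_jitter)  # uniform jitter half-width

    base = np.zeros(n)
    t = 0.0
    while t < T:
        f = f_of_t(t)
        period = (1.0 / f) * (1.0 + (rng.uniform(-a, a) if a > 0 else 0.0))
        i0 = int(round(t * fs))
        i1 = min(n, int(round((t + period) * fs)))
        if i1 <= i0:
            break
        morph = spec.morphology_onset if t < switch_t else spec.morphology_peak
        base[i0:i1] = _render_cycle(morph, i1 - i0, spike_n)
        t += period

    tt = np.arange(n) / fs
    env = _amp_envelope(tt, T)

    # channel recruitment: random order, onset channels active throughout,
    # later channels ramp in after the onset window
    order = rng.permutation(montage.n_channels)
    onset_win = min(10.0, T / 3.0)
    out = np.zeros((montage.n_channels, n))
    for rank in range(spec.channels_peak):
        ch = order[rank]
        scale = 1.0 if rank == 0 else rng.uniform(0.75, 0.95)
        polarity = 1.0 if rank == 0 else rng.choice([-1.0, 1.0])
        lag = int(round(rng.uniform(0, 0.08) * fs)) if rank > 0 else 0
        sig = np.roll(base, lag) if lag else base
        act = np.ones(n)
        if rank >= spec.channels_onset:
            t_on = onset_win
            t_full = max(T / 3.0, t_on + min(5.0, T / 6.0))
            act = np.clip((tt - t_on) / max(t_full - t_on, 1e-6), 0.0, 1.0)
        out[ch] = (spec.peak_amplitude_uV / 2.0) * scale * polarity * env * act * sig
    return out


# ---------------------------------------------------------------------------
# subjects and cohorts
# ---------------------------------------------------------------------------

def _assemble_record(background: EEGRecord, seizures: list[SeizureSpec],
                     montage: MontageSpec, rng: np.random.Generator) -> EEGRecord:
    rec = background.copy()
    fs = rec.sampling_rate
    for spec in seizures:
        wav = render_seizure(spec, montage, rng)
        i0 = int(round(spec.onset_s * fs))
        i1 = min(rec.n_samples, i0 + wav.shape[1])
        if i0 >= rec.n_samples:
            raise ValueError(f"seizure onset {spec.onset_s}s beyond record end")
        rec.data[:, i0:i1] += wav[:, : i1 - i0]
    return rec


def generate_subject(sim: SubjectSim, montage: MontageSpec | None = None
                     ) -> tuple[EEGRecord, EEGRecord, list[SeizureAnnotation]]:
    """Render both periods of one subject: background plus seizures.

    Returns ``(pre_record, post_record, annotations)`` where the annotation
    list covers both periods and mirrors the seizure specs exactly.
    """
    montage = montage or default_montage()
    records = []
    annotations: list[SeizureAnnotation] = []
    for period, seizures in (("pre", sim.pre_seizures), ("post", sim.post_seizures)):
        needed = max((s.end_s for s in seizures), default=0.0) + 30.0
        dur = max(sim.record_duration_s, needed)
        # common random numbers across periods: with an identity drug
        # effect the post record renders identically to the pre record,
        # so the configured effect is the only systematic difference
        bg_rng = np.random.default_rng((sim.rng_seed, 11))
        sz_rng = np.random.default_rng((sim.rng_seed, 13))
        bg = generate_background(sim.background, dur, montage, bg_rng)
        records.append(_assemble_record(bg, seizures, montage, sz_rng))
        annotations.extend(
            SeizureAnnotation(s.onset_s, s.duration_s, sim.subject_id, period)
            for s in seizures
        )
    return records[0], records[1], annotations


# -- cohort-level defaults: the study conditions -----------------------------

#: Probability of each ictal morphology at seizure onset (RDD and RDT
#: dominate neonatal seizures; alpha-frequency discharges are rare).
_MORPH_PROBS = {MORPH_RDD: 0.45, MORPH_RDT: 0.25, MORPH_RDA: 0.05,
                MORPH_SPIKE: 0.10, MORPH_SPW: 0.15}

#: Probability that the dominant morphology differs between onset and peak.
_P_MORPH_CHANGE = 0.45

_FREQ_DRAW = {  # (low, high) Hz for the start frequency of each morphology
    MORPH_RDD: (1.0, 3.4), MORPH_RDT: (4.3, 6.8), MORPH_RDA: (8.5, 12.0),
    MORPH_SPIKE: (0.8, 2.5), MORPH_SPW: (0.8, 2.2),
}


def _draw_freq_for(morph: int, rng: np.random.Generator) -> float:
    lo, hi = _FREQ_DRAW[morph]
    return float(rng.uniform(lo, hi))


def _draw_seizure(rng: np.random.Generator, onset_s: float,
                  amplitude_median: float, amplitude_sigma_ln: float,
                  duration_median: float, duration_sigma_ln: float) -> SeizureSpec:
    dur = float(np.clip(duration_median * np.exp(rng.normal(0, duration_sigma_ln)), 20, 400))
    amp = float(np.clip(amplitude_median * np.exp(rng.normal(0, amplitude_sigma_ln)), 40, 500))
    morphs, probs = zip(*_MORPH_PROBS.items())
    m_on = int(rng.choice(morphs, p=probs))
    if rng.uniform() < _P_MORPH_CHANGE:
        others = [m for m in morphs if m != m_on]
        m_pk = int(rng.choice(others))
    else:
        m_pk = m_on
    f_start = _draw_freq_for(m_on, rng)
    if m_pk in MORPH_BANDS:
        lo, hi = MORPH_BANDS[m_pk]
        f_mid = float(rng.uniform(lo + 0.4, min(hi - 0.4, max(lo + 0.5, f_start))))
    else:
        f_mid = _draw_freq_for(m_pk, rng)
    f_end = float(max(0.6, f_mid * rng.uniform(0.6, 0.95)))
    ch_pk = int(rng.integers(2, 9))        # 2-8 channels at peak
    ch_on = int(rng.integers(1, ch_pk + 1))
    # most neonatal seizures are highly rhythmic; spike trains jitter more,
    # and their repetition rate is measured by interval counting, which
    # tolerates it
    if m_on in _TRANSIENT_MORPHS and m_pk in _TRANSIENT_MORPHS:
        jitter = float(rng.uniform(0.05, 0.15))
    else:
        jitter = float(rng.uniform(0.02, 0.07))
    return SeizureSpec(
        onset_s=onset_s, duration_s=dur,
        morphology_onset=m_on, morphology_peak=m_pk,
        freq_start=f_start, freq_mid=f_mid, freq_end=f_end,
        peak_amplitude_uV=amp, channels_onset=ch_on, channels_peak=ch_pk,
        rhythmicity_jitter=jitter,
    )


def _truncated_geometric(rng: np.random.Generator, p: float,
                         lo: int, hi: int) -> int:
    """Geometric count on {lo..hi}; matches the long right tail of observed
    per-infant seizure counts."""
    while True:
        k = lo + rng.geometric(p) - 1
        if k <= hi:
            return int(k)


def draw_subject_sim(subject_id: str, seed: int, *,
                     drug_effect: DrugEffect = PHENOBARBITAL_EFFECT,
                     count_p: float = 0.15, count_range: tuple[int, int] = (1, 68),
                     max_count: int | None = None,
                     record_duration_s: float = 1200.0,
                     amplitude_median: float = 123.0, amplitude_sigma_ln: float = 0.95,
                     duration_median: float = 103.0, duration_sigma_ln: float = 0.7,
                     background_grade: int | None = None,
                     paired: bool = True) -> SubjectSim:
    """Draw the full ground truth for one subject.

    In paired mode (the default) post-dose seizures are the pre-dose specs
    transformed by ``drug_effect``, so the drug effect is the only
    systematic pre/post difference.  Seizure counts follow a truncated
    geometric law on ``count_range``; ``max_count`` additionally caps the
    number rendered (counts beyond what a record can hold are truncated to
    fit, echoing how only the first matched seizures enter the analysis).
    """
    rng = np.random.default_rng(seed)
    if background_grade is None:
        background_grade = int(rng.choice([1, 2, 3, 4], p=[0.5, 0.2, 0.2, 0.1]))
    background = BackgroundSpec.for_grade(background_grade)

    n = _truncated_geometric(rng, count_p, *count_range)
    if max_count is not None:
        n = min(n, max_count)

    def place(n_seiz: int, sub_rng: np.random.Generator) -> list[SeizureSpec]:
        specs, t = [], float(sub_rng.uniform(60, 120))
        for _ in range(n_seiz):
            s = _draw_seizure(sub_rng, t, amplitude_median, amplitude_sigma_ln,
                              duration_median, duration_sigma_ln)
            if s.end_s + 40 > record_duration_s and specs:
                break  # record full; keep only the seizures that fit
            specs.append(s)
            t = s.end_s + float(sub_rng.uniform(30, 120))
        return specs

    pre = place(n, np.random.default_rng((seed, 1)))
    if paired:
        post = [replace(drug_effect.apply(s)) for s in pre]
    else:
        post = place(n, np.random.default_rng((seed, 2)))
    return SubjectSim(subject_id=subject_id, background=background,
                      pre_seizures=pre, post_seizures=post,
                      drug_effect=drug_effect, rng_seed=seed,
                      record_duration_s=record_duration_s)


@dataclass
class CohortSample:
    """A rendered cohort: ground truth, records and gold annotations."""

    sims: list[SubjectSim]
    records: dict[tuple[str, str], EEGRecord]      # (subject_id, period) -> record
    annotations: list[SeizureAnnotation]


def generate_cohort(n_subjects: int = 18,
                    effect: DrugEffect = PHENOBARBITAL_EFFECT,
                    seed: int = 0,
                    montage: MontageSpec | None = None,
                    out_dir=None,
                    render: bool = True,
                    **subject_kwargs) -> CohortSample:
    """Generate a full pre/post cohort; optionally write EDF + annotations.

    Deterministic given ``seed``.  When ``out_dir`` is given, one EDF file
    per subject per period plus a single tab-separated annotation file are
    written there.  ``render=False`` returns ground truth only (no EEG),
    which is enough for analyses that resample many cohorts.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    montage = montage or default_montage()
    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31 - 1, size=n_subjects)
    sims, records, annotations = [], {}, []
    for i in range(n_subjects):
        sid = f"s{i + 1:02d}"
        sim = draw_subject_sim(sid, int(sub_seeds[i]), drug_effect=effect,
                               **subject_kwargs)
        sims.append(sim)
        if render:
            pre, post, anns = generate_subject(sim, montage)
            records[(sid, "pre")] = pre
            records[(sid, "post")] = post
            annotations.extend(anns)
        else:
            annotations.extend(
                SeizureAnnotation(s.onset_s, s.duration_s, sid, period)
                for period, lst in (("pre", sim.pre_seizures), ("post", sim.post_seizures))
                for s in lst
            )
    sample = CohortSample(sims=sims, records=records, annotations=annotations)
    if out_dir is not None:
        from . import io as _io
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (sid, period), rec in records.items():
            _io.write_edf(rec, out / f"{sid}_{period}.edf")
        _io.write_annotations(annotations, out / "gold_annotations.tsv")
    return sample
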