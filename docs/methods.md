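# Methods

## The study design being emulated

Eighteen term neonates with electrographic seizures both before and after
a phenobarbital loading dose (20 mg/kg). Per subject, seizure counts are
matched by truncating both periods to the smaller count in temporal
order; each of ten seizure variables is reduced to one value per subject
per period; pre/post differences are tested with the two-sided Wilcoxon
signed-rank test at α = 0.05. The recordings themselves are not publicly
deposited, so the package pairs the published per-infant summary values
(shipped as TSV fixtures) with a synthetic-EEG generator whose ground
truth makes every measurement verifiable.

## Synthetic EEG generator

**Montage and acquisition.** Nine scalp electrodes of the neonatal
10–20 reduction (F4, F3, T4, C4, Cz, C3, T3, O2, O1) in eight bipolar
chains (F4-C4, C4-O2, F3-C3, C3-O1, T4-C4, C4-Cz, Cz-C3, C3-T3); the
source montage names the electrodes but not the derivations, and eight
channels is the maximum channel count observed per seizure. Sampling
rate 250 or 256 Hz; all activity band-limited to 0.5–70 Hz, matching the
acquisition filters of the ICU monitors.

**Background.** Gaussian noise with an approximately 1/f power spectrum
inside 0.5–70 Hz, synthesised by an O(n) IIR cascade (three pole/zero
shelves ≈ −10 dB/decade, then a band-limiting Butterworth). Grade 1 is
continuous at 30 μV peak-to-peak; grades 2–4 alternate bursts with quiet
gaps whose drawn lengths respect the grade's defining inter-burst
interval range (grade 2: < 10 s; grade 3: 10–60 s; grade 4: > 60 s with
inter-burst amplitude < 10 μV). Background peak-to-peak envelope is
taken as 4σ of the noise. Cohort grades are drawn with probabilities
(0.5, 0.2, 0.2, 0.1) for grades 1–4 — free parameters chosen so that the
per-subject maximum background score centres near the published group
median of 1.5.

**Ictal waveforms** are built cycle by cycle so every measured quantity
is an explicit parameter:

* *Frequency*: a hold–ramp–hold profile holds the start frequency over
  the first analysis segment, the mid frequency on a plateau around the
  midpoint, and the end frequency over the final segment; each cycle's
  period is the instantaneous period at its start time.
* *Rhythmicity*: each period is jittered by a uniform multiplicative
  factor whose coefficient of variation is `rhythmicity_jitter`.
  Defaults draw 0.02–0.07 for rhythmic seizures (most neonatal seizures
  are highly rhythmic, consistent with the published rhythmicity-score
  distribution) and 0.05–0.15 for spike trains, whose repetition rate is
  measured by interval counting and tolerates more jitter. The sampling
  error of a 5-s spectral peak grows as `jitter · √(f/T)`, which is what
  bounds the rhythmic default if segment frequencies are to be
  recoverable to ±0.25 Hz at theta/alpha frequencies.
* *Morphology*: rhythmic cycles are sinusoidal (delta 0.5–<4, theta
  4–<8, alpha 8–13 Hz — standard clinical band edges); spike/sharp-wave
  cycles hold one biphasic 50–90 ms transient; spike-and-wave cycles add
  an opposite-polarity slow wave comparable in size to the spike, the
  whole complex normalised so its overall peak-to-trough equals the
  seizure amplitude. Morphology switches from the onset to the peak
  category ahead of the peak analysis window.
* *Amplitude envelope*: `0.6 + 0.4·sin(πt/T)` with short edge tapers —
  maximal at the temporal midpoint, where the clinical measurement is
  defined, with value `peak_amplitude_uV` peak-to-trough on the most
  involved channel.
* *Spatial spread*: a random recruitment order; `channels_onset`
  channels active from onset, later recruits ramping in after the onset
  analysis window and fully involved by the middle third; secondary
  channels are scaled 0.75–0.95 with random polarity and ≤ 80 ms lag.

**Drug effect.** Post-dose seizures are the pre-dose specs transformed:
amplitude × `amplitude_scale`, channel counts reduced by
`channel_delta` (floored at one channel). The packaged
`PHENOBARBITAL_EFFECT` uses 0.435 (the measured 56.5 % drop) and 1.
Records for both periods reuse common random numbers, so with an
identity effect the post record renders identically and the configured
effect is the only systematic pre/post difference.

**Cohort defaults.** Seizure counts per subject follow a truncated
geometric law on [1, 68] (p = 0.15), matching the long right tail of the
observed counts; log-normal amplitudes (median 123 μV, ln-σ 0.95,
clipped to 40–500 μV) and durations (median 103 s, ln-σ 0.7, clipped to
20–400 s) match the published group medians and IQRs; onset morphology
probabilities are (0.45, 0.25, 0.05, 0.10, 0.15) for RDD/RDT/RDA/
spikes/spike-and-wave and morphology changes from onset to peak with
probability 0.45.

## Measurement surrogates

The clinical variables are visual judgements; each gets a quantitative
surrogate with thresholds exposed in `FeatureConfig` and calibrated
against the generator.

* **Peak amplitude** (10 s window centred on the midpoint; one third of
  the duration for seizures under 30 s): for rhythmic discharges,
  `2√2·√(P_band − P_baseline)` with a band around the dominant frequency
  — exact for a sinusoid and robust to background noise; for transient
  discharges, the peak-to-trough of the spike-triggered-average complex
  (averaging suppresses noise riding on the broad slow-wave trough),
  with segments re-centred on the positive spike lobe.
* **Segment frequency**: periodogram argmax (Hann window, zero-padded,
  parabolic refinement) over 0.5–13 Hz, with a transient-rate fallback
  (median inter-spike interval over a window extended into the seizure)
  for spike morphologies. A low-confidence flag is raised when no
  spectral peak stands 20× clear of the in-band median, the level pure
  noise can reach.
* **Transient detection** underlies the morphology split: peaks of the
  envelope-normalised signal above twice the local RMS (a sinusoid's
  crest factor √2 cannot reach this), narrower than 200 ms, at 0.4–3.5/s,
  filtered of sub-threshold crests, and required to repeat regularly and
  to be much narrower than their own repetition period (a "transient"
  occupying > 17 % of its cycle is the crest of a rhythm, not a spike).
  Spike-and-wave vs plain spikes is decided by the spike-triggered
  average: a coupling ratio (wave amplitude over spike amplitude)
  ≥ 0.22.
* **Rhythmicity score**: the coefficient of variation of successive
  discharge intervals estimated from successive-difference statistics
  (RMSSD-style), which cancels slow frequency drift; < 0.15 → 3,
  0.15–0.35 → 2, > 0.35 → 1. Discharge markers are hysteresis crossings
  of the envelope-normalised narrowband signal (rhythmic) or spike peaks
  (transient), both sitting at a fixed phase of their cycle so interval
  statistics track the true cycle periods.
* **Background score**: thresholded channel-median RMS envelope
  (quiet < 15 μV peak-to-peak equivalent, minimum 2 s) on at least
  5 min of seizure-free signal; grades follow the inter-burst interval
  ranges, grade 4 additionally requiring quiet-gap amplitude < 10 μV.
* **Channels involved** (onset window: first 10 s; peak: middle third
  around the midpoint): discharge-band power above `k = 2.5` times the
  channel's baseline power, where the baseline statistic is the *maximum*
  over short pre-onset sub-windows so the bursts of a discontinuous
  background are not mistaken for spread (for stationary grade-1 noise
  this maximum sits 2–2.5× above the mean, so the effective criterion is
  roughly 4–6× mean baseline power). Transient seizures use the
  analogous peak-excursion criterion, since a low-duty spike train
  carries little average power.

**Validity envelope.** On noiseless renders channel counts are exact and
amplitudes within a few percent. With background present, closure holds
for seizures whose amplitude is at least about 3× the background burst
amplitude: amplitude to ±10 %, segment frequencies to ±0.25 Hz, channel
counts to ±1. Post-dose seizures scaled below the background (possible
at the low end of the amplitude distribution) are not reliably
measurable — by these surrogates or by eye — and are excluded from
closure checks, not from analyses.

## Detector

Anti-alias filtering at 12.8 Hz (Chebyshev II, zero-phase), resampling
to 32 Hz, 8 s epochs with 50 % overlap (`floor((T−8)/4)+1` epochs).
Twenty features per channel-epoch: RMS, variance, line length,
zero-crossing rate, Hjorth mobility and complexity, skewness, kurtosis,
AR(5) prediction error; total power, 80 % spectral edge, peak frequency,
delta/theta/alpha band powers, three db4 wavelet sub-band energies;
amplitude-histogram Shannon entropy and spectral entropy. Features are
z-scored; a Gaussian-kernel SVM (C = 1, width cross-validated over a
small grid) is calibrated to probabilities with a sigmoid fitted on
held-out folds; training subsamples at most 2500 epochs per class,
reproducibly. Epochs above the 99.8th percentile of training epoch
energies are masked as artifact — on artifact-free synthetic data a
lower cut (e.g. 97.5 %) would mask the strongest genuine discharges.
Probabilities are smoothed with a 15-epoch (~60 s) moving average; the
channel-wise maximum is thresholded (0.0–1.0 in 0.1 steps, default 0.3);
supra-threshold runs become events carrying onset, duration, modal
max-probability channel and peak probability.

Event scoring: a gold seizure is detected if any event overlaps it by
≥ 1 s (counted once however many events cover it); unmatched events are
false detections. Split detections of one seizure therefore count one
detection and no false positives.

## Statistics

Summary reducers: median for amplitude, duration, channel counts and
frequency variability; maximum for the 3-point rhythmicity and 4-point
background scores; proportion for binary variables and the detection
rate. Group descriptions use the weighted-average percentile at position
`(n+1)p` (`np.quantile(method="weibull")`), the convention that
reproduces the published IQR bounds (46.13, 89.25, 1.38) exactly; at
p = 0.5 it is the ordinary median. The Wilcoxon signed-rank test drops
zero differences, mid-ranks ties, and uses the tie-corrected normal
approximation without continuity correction, two-sided — the SPSS
pathway that yields the published p-values (0.001 for amplitude, 0.018
for channels) from the per-infant tables; exact enumeration over all 2^n
sign assignments is available for n ≤ 12 and is cross-checked against an
independent enumeration oracle and scipy in the tests. Per-subject
change counts treat ties as "not reduced", which reproduces the
published 14/18 and 10/18.

## Cohort-level experiments and problem sizes

* *Amplitude power study*: 50 independent 18-subject cohorts with the
  measured effect (amplitude × 0.435, one channel fewer), up to 4
  seizures per subject on 10-minute records — amplitude medians do not
  depend on record length, so the short records only speed the study.
  Reported: fraction of cohorts with Wilcoxon p < 0.05 and the median
  measured post/pre amplitude ratio.
* *Detection robustness*: the detector is trained on a disjoint
  5-subject synthetic cohort, then applied to both periods of one
  18-subject cohort on 20-minute records per subject per period at
  threshold 0.3. Reported: per-subject detection rates and the pre/post
  change of the medians in percentage points.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the clinical data — graded
backgrounds, amplitude envelopes, frequency slowing, morphology change,
channel recruitment, the drug's amplitude/spread effect — but its
seizures are cleaner and more stereotyped than real neonatal seizures:
no artifacts beyond what the energy mask is designed for, no
electrode-quality drift, no patient movement, coherent discharges across
channels. Automated detection is consequently much easier here (median
detection rates near 100 % versus 77 %/73 % reported on real recordings
at the same threshold), which is why the real-data detection rates and
the raw-EEG feature distributions are *not* reproduction targets; the
meaningful synthetic claims are relative ones — the paired amplitude
comparison reliably rejects under the measured effect size while the
detection rate change stays far below the 15-percentage-point margin,
i.e. the architecture's performance is robust to the drug's effect on
seizure morphology. Wilcoxon p-values, percentile conventions and change
counts are validated exactly on the published per-infant values.

## Known limitations

* The ten-variable surrogates are calibrated to this generator; on real
  EEG their thresholds (involvement `k`, rhythmicity cut-offs, transient
  crest ratio) would need re-calibration against expert annotations.
* The detector's 20-feature set is a documented representative subset of
  the much larger proprietary catalogues of clinical-grade systems, and
  it is trained on synthetic data; its absolute operating points are not
  comparable to validated clinical detectors.
* Spike-and-wave complexes at repetition rates above ~2.5/s approach the
  transient detector's rate ceiling, and onset-window morphology of
  fast spike-wave runs can occasionally read as plain spikes.
* EDF output is 16-bit with a fixed ±2000 μV physical range
  (quantisation ≈ 0.06 μV); signals beyond that range are clipped.
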