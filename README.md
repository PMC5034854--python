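# neoictal

Phenobarbital, the first-line anticonvulsant for neonatal seizures, often
*uncouples* seizures from their clinical signs: electrographic seizure
activity continues on the EEG while the visible manifestations stop. A key
observation behind that phenomenon is that a phenobarbital loading dose
roughly halves the peak-to-trough amplitude of electrographic seizures
(group median drop ≈ 56.5 %) and reduces the number of EEG channels they
recruit, while leaving duration, rhythmicity, discharge frequency and
background grade unchanged — and, importantly for cot-side monitoring,
leaving the performance of SVM-based automated seizure detection intact.

`neoictal` is a research package for exploring exactly that question on
synthetic multichannel neonatal EEG. It is written for neurophysiology and
biomedical-signal researchers who want a fully controllable, reproducible
test bed for seizure-morphology measures and detector robustness. It
provides:

* **`neoictal.simulate`** — an 8-channel neonatal bipolar EEG generator
  (250/256 Hz, 0.5–70 Hz band): graded backgrounds from continuous
  activity to burst suppression (4-point background score with
  inter-burst intervals < 10 s / 10–60 s / > 60 s), and cycle-by-cycle
  ictal waveform synthesis with explicit ground truth for amplitude,
  frequency sweep, rhythmicity jitter, waveform morphology (rhythmic
  delta/theta/alpha, spikes/sharp waves, spike-and-wave) and channel
  recruitment. A configurable drug effect scales post-dose amplitudes and
  strips recruited channels.
* **`neoictal.features`** — quantitative surrogates for the ten-variable
  clinical seizure description: peak amplitude at the seizure midpoint,
  segment frequencies (first 5 s / mid / last 5 s) and their standard
  deviation, a 3-point rhythmicity score from cycle-interval variability,
  a 4-point background grade, morphology classification at onset and peak,
  morphology change, and channels involved at onset and peak.
* **`neoictal.detector`** — an SVM seizure detector in the standard
  clinical architecture: 32 Hz working rate (anti-alias 12.8 Hz), 8 s
  epochs with 50 % overlap, 20 time/frequency/information-theory features
  per channel-epoch, Gaussian-kernel SVM with sigmoid probability
  calibration, moving-average smoothing, adjustable threshold in steps of
  0.1, and event output (onset, duration, channel of highest probability).
* **`neoictal.evaluate`** — event-based scoring (detection rate, false
  detections per hour) with an any-overlap ≥ 1 s matching rule.
* **`neoictal.stats`** — matched seizure counts, per-subject summary
  reducers, the weighted-average `(n+1)p` percentile convention, and a
  Wilcoxon signed-rank test (tie-corrected normal approximation plus
  exact enumeration) reproducing the SPSS pathway.
* **`neoictal.fixtures`** — the published per-infant values of the
  18-neonate cohort (matched seizure counts; median amplitude and channel
  involvement pre/post dose) shipped as plain TSV, from which all group
  statistics are recomputed.

## Worked example

Recompute the published group statistics from the per-infant table:

```bash
$ neoictal reproduce-tables
{
  "n_subjects": 18,
  "amplitude": {
    "pre_median_uV": 123.0,
    "pre_iqr_uV": [
      62.5,
      225.0
    ],
    "post_median_uV": 53.5,
    "post_iqr_uV": [
      46.125,
      89.25
    ],
    "drop_percent": 56.50406504065041,
    "wilcoxon_p": 0.001176563999937216,
    "reduced_in_n_subjects": 14
  },
  "channels_peak": {
    "pre_median": 4.0,
    "pre_iqr": [
      3.0,
      8.0
    ],
    "post_median": 3.0,
    "post_iqr": [
      1.375,
      4.0
    ],
    "wilcoxon_p": 0.018062655671126734,
    "reduced_in_n_subjects": 10
  },
  "matched_seizures_per_period": 262
}
```

Reading: the median per-infant peak seizure amplitude falls from 123 μV
(IQR 62.5–225) before the dose to 53.5 μV (46.13–89.25) after — a 56.5 %
drop, significant at p = 0.001 and present in 14 of 18 infants — while the
median number of channels involved at seizure peak falls from 4 to 3
(p = 0.018, reduced in 10 of 18). 262 matched seizures per period enter
the analysis.

A full synthetic run — simulate a cohort, write EDFs and gold
annotations, measure every seizure, train and apply the detector, and
produce the paired comparison table and plots:

```bash
neoictal run --seed 1 --out myrun        # full pipeline
neoictal simulate --seed 1 --out sim     # just the cohort (EDF + TSV)
neoictal detect --edf sim/s01_pre.edf --model detector.pkl --threshold 0.3
```

Python API:

```python
from neoictal.simulate import generate_cohort, PHENOBARBITAL_EFFECT
from neoictal.pipeline import extract_cohort_features, summarise_cohort
from neoictal.stats import compare_cohort

cohort = generate_cohort(18, PHENOBARBITAL_EFFECT, seed=1)
features = extract_cohort_features(cohort)
table = compare_cohort(summarise_cohort(features))
print(table[["pre_median", "post_median", "p_value"]])
```

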