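"""Orchestration: simulate → annotate → measure → detect → evaluate → compare.

Also provides the two cohort-level experiments used to test whether an
anticonvulsant-induced reduction in seizure amplitude and spread degrades
automated detection:

* :func:`amplitude_power_study` — across many simulated 18-subject
  cohorts with the phenobarbital effect applied, how often does the
  paired amplitude comparison reject the null?
* :func:`detection_robustness_study` — on one paired cohort, how much do
  per-subject seizure detection rates change from pre- to post-dose at a
  fixed probability threshold?
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .core import SeizureAnnotation
from .detector import DetectorModel, detect, probability_trace, train
from .evaluate import EvalResult, evaluate_events
from .features import extract_all, peak_amplitude
from .io import write_detections, write_feature_table
from .simulate import CohortSample, DrugEffect, generate_cohort
from .stats import (SUMMARY_REDUCERS, compare_cohort, match_counts,
                    per_subject_change_counts, summarise,
                    wilcoxon_signed_rank)

__all__ = [
    "extract_cohort_features",
    "summarise_cohort",
    "train_detector",
    "evaluate_cohort_detection",
    "amplitude_power_study",
    "detection_robustness_study",
    "run_pipeline",
]


def _cohort_annotations(sample: CohortSample, subject_id: str, period: str
                        ) -> list[SeizureAnnotation]:
    return [a for a in sample.annotations
            if a.subject_id == subject_id and a.period == period]


def extract_cohort_features(sample: CohortSample, config: RunConfig | None = None
                            ) -> list:
    """All ten measurements for every matched seizure of a rendered cohort."""
    cfg = (config or RunConfig()).features
    out = []
    for sim in sample.sims:
        pre_anns = _cohort_annotations(sample, sim.subject_id, "pre")
        post_anns = _cohort_annotations(sample, sim.subject_id, "post")
        pair = match_counts(pre_anns, post_anns, sim.subject_id)
        for period, anns, all_anns in (("pre", pair.pre, pre_anns),
                                       ("post", pair.post, post_anns)):
            rec = sample.records[(sim.subject_id, period)]
            for ann in anns:
                out.append(extract_all(rec, ann, all_anns, cfg))
    return out


def summarise_cohort(features: list,
                     eval_results: list[EvalResult] | None = None) -> pd.DataFrame:
    """Per-subject per-period summary table ready for :func:`compare_cohort`."""
    frame_rows: dict[tuple[str, str], dict] = {}
    by_subject: dict[tuple[str, str], list] = {}
    for f in features:
        by_subject.setdefault((f.subject_id, f.period), []).append(f)
    for (sid, period), feats in sorted(by_subject.items()):
        row = {"subject_id": sid, "period": period}
        for var in SUMMARY_REDUCERS:
            if var == "detection_rate":
                continue
            vals = [getattr(f, var) for f in feats]
            try:
                row[var] = summarise(vals, var)
            except ValueError:
                row[var] = np.nan
        frame_rows[(sid, period)] = row
    if eval_results:
        for r in eval_results:
            key = (r.subject_id, r.period)
            if key in frame_rows:
                frame_rows[key]["detection_rate"] = r.detection_rate
    return pd.DataFrame(frame_rows.values())


def train_detector(config: RunConfig, seed: int) -> DetectorModel:
    """Train the detector on a dedicated cohort disjoint from the analysis
    cohort (different seed stream, no drug effect)."""
    train_sample = generate_cohort(
        config.n_training_subjects, DrugEffect(), seed=seed + 77003,
        max_count=config.max_seizures_per_subject,
        record_duration_s=min(config.record_duration_s, 600.0),
        amplitude_median=config.amplitude_median_uV,
        amplitude_sigma_ln=config.amplitude_sigma_ln,
        duration_median=config.duration_median_s,
        duration_sigma_ln=config.duration_sigma_ln,
    )
    records, anns = [], []
    for (sid, period), rec in train_sample.records.items():
        records.append(rec)
        anns.append(_cohort_annotations(train_sample, sid, period))
    return train(records, anns, config.detector, seed=seed)


def evaluate_cohort_detection(sample: CohortSample, model: DetectorModel,
                              threshold: float = 0.3,
                              detections_out: dict | None = None
                              ) -> list[EvalResult]:
    """Run the detector over every record and score it against gold."""
    results = []
    for (sid, period), rec in sorted(sample.records.items()):
        trace = probability_trace(rec, model)
        events = detect(trace, threshold)
        if detections_out is not None:
            detections_out[(sid, period)] = events
        gold = _cohort_annotations(sample, sid, period)
        results.append(evaluate_events(gold, events, rec.duration_s / 3600.0,
                                       sid, period))
    return results


# ---------------------------------------------------------------------------
# cohort-level experiments
# ---------------------------------------------------------------------------

def amplitude_power_study(n_seeds: int = 50, base_seed: int = 0,
                          n_subjects: int = 18,
                          effect: DrugEffect | None = None,
                          record_duration_s: float = 600.0,
                          max_count: int = 4,
                          alpha: float = 0.05) -> dict:
    """Replicated paired amplitude comparison on simulated cohorts.

    For each seed an 18-subject cohort is generated with the drug effect
    applied to post-dose seizures, the measured per-seizure peak
    amplitudes are reduced to per-subject medians, and the pre/post
    difference is tested with the Wilcoxon signed-rank test.  Reports the
    fraction of cohorts rejecting at ``alpha`` and the median measured
    post/pre amplitude ratio.
    """
    effect = effect or DrugEffect(amplitude_scale=0.435, channel_delta=1)
    p_values, ratios = [], []
    for k in range(n_seeds):
        sample = generate_cohort(n_subjects, effect, seed=base_seed + 1000 * k,
                                 max_count=max_count,
                                 record_duration_s=record_duration_s)
        pre_med, post_med = [], []
        for sim in sample.sims:
            for period, store in (("pre", pre_med), ("post", post_med)):
                rec = sample.records[(sim.subject_id, period)]
                anns = _cohort_annotations(sample, sim.subject_id, period)
                amps = [peak_amplitude(rec, a) for a in anns]
                store.append(summarise(amps, "peak_amplitude_uV"))
        res = wilcoxon_signed_rank(pre_med, post_med)
        p_values.append(res.p_value)
        ratios.append(float(np.median(np.asarray(post_med) / np.asarray(pre_med))))
    p_values = np.asarray(p_values)
    return {
        "n_seeds": n_seeds,
        "alpha": alpha,
        "p_values": p_values.tolist(),
        "rejection_rate": float(np.mean(p_values < alpha)),
        "median_post_pre_ratio": float(np.median(ratios)),
    }


def detection_robustness_study(seed: int = 0,
                               config: RunConfig | None = None,
                               model: DetectorModel | None = None) -> dict:
    """Pre vs post detection rates on one paired cohort at the configured
    threshold.

    The detector is trained on a disjoint synthetic cohort, then applied
    to both periods of an 18-subject cohort carrying the drug effect.
    Reports per-subject detection rates and the median pre/post change in
    percentage points.
    """
    config = config or RunConfig(seed=seed)
    effect = DrugEffect(amplitude_scale=config.amplitude_scale,
                        channel_delta=config.channel_delta)
    if model is None:
        model = train_detector(config, seed)
    sample = generate_cohort(config.n_subjects, effect, seed=seed,
                             max_count=config.max_seizures_per_subject,
                             record_duration_s=config.record_duration_s,
                             amplitude_median=config.amplitude_median_uV,
                             amplitude_sigma_ln=config.amplitude_sigma_ln,
                             duration_median=config.duration_median_s,
                             duration_sigma_ln=config.duration_sigma_ln)
    results = evaluate_cohort_detection(sample, model, config.threshold)
    rates = {"pre": [], "post": []}
    fd = []
    for r in results:
        rates[r.period].append(r.detection_rate)
        fd.append(r.fd_per_hour)
    pre_med = float(np.median(rates["pre"]))
    post_med = float(np.median(rates["post"]))
    return {
        "threshold": config.threshold,
        "pre_rates": rates["pre"],
        "post_rates": rates["post"],
        "pre_median_rate": pre_med,
        "post_median_rate": post_med,
        "median_change_pp": 100.0 * (pre_med - post_med),
        "fd_per_hour_mean": float(np.mean(fd)),
    }


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _paired_plot(ax, pre, post, title, ylabel):
    for a, b in zip(pre, post):
        ax.plot([0, 1], [a, b], "-o", color="0.6", markersize=3)
    ax.plot([0, 1], [np.median(pre), np.median(post)], "-", color="k", lw=3)
    ax.set_xticks([0, 1], ["pre", "post"])
    ax.set_title(title)
    ax.set_ylabel(ylabel)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str, fn):
    try:
        return fn()
    except Exception as exc:
        raise PipelineStageError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_pipeline(config: RunConfig) -> dict:
    """Full study on one simulated cohort; writes all artefacts to
    ``config.out_dir`` and returns the report dictionary."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    effect = DrugEffect(amplitude_scale=config.amplitude_scale,
                        channel_delta=config.channel_delta)
    sample = _stage("simulate", lambda: generate_cohort(
        config.n_subjects, effect, seed=config.seed,
        max_count=config.max_seizures_per_subject,
        record_duration_s=config.record_duration_s,
        amplitude_median=config.amplitude_median_uV,
        amplitude_sigma_ln=config.amplitude_sigma_ln,
        duration_median=config.duration_median_s,
        duration_sigma_ln=config.duration_sigma_ln,
        out_dir=out / "edf"))

    features = _stage("features", lambda: extract_cohort_features(sample, config))
    write_feature_table(features, out / "seizure_features.tsv")

    model = _stage("train", lambda: train_detector(config, config.seed))
    detections: dict = {}
    eval_results = _stage("detect", lambda: evaluate_cohort_detection(
        sample, model, config.threshold, detections))
    for (sid, period), events in detections.items():
        write_detections(events, out / f"detections_{sid}_{period}.tsv")

    summaries = summarise_cohort(features, eval_results)
    comparison = _stage("compare", lambda: compare_cohort(summaries))
    comparison.to_csv(out / "comparison.tsv", sep="\t")

    wide = summaries.pivot(index="subject_id", columns="period")
    amp_pre = wide[("peak_amplitude_uV", "pre")].to_numpy()
    amp_post = wide[("peak_amplitude_uV", "post")].to_numpy()
    ch_pre = wide[("channels_peak", "pre")].to_numpy()
    ch_post = wide[("channels_peak", "post")].to_numpy()
    det_pre = wide[("detection_rate", "pre")].to_numpy()
    det_post = wide[("detection_rate", "post")].to_numpy()

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(11, 4))
    _paired_plot(axes[0], amp_pre, amp_post,
                 "Median peak seizure amplitude", "μV")
    _paired_plot(axes[1], ch_pre, ch_post,
                 "Median channels at seizure peak", "channels")
    _paired_plot(axes[2], det_pre, det_post,
                 f"Detection rate (threshold {config.threshold})", "proportion")
    fig.tight_layout()
    fig.savefig(out / "paired_changes.png", dpi=120)
    plt.close(fig)

    amp_reduced, n_subj = per_subject_change_counts(amp_pre, amp_post)
    ch_reduced, _ = per_subject_change_counts(ch_pre, ch_post)
    report = {
        "n_subjects": n_subj,
        "amplitude_drop_percent": float(
            100.0 * (np.median(amp_pre) - np.median(amp_post)) / np.median(amp_pre)),
        "amplitude_reduced_in_n_subjects": amp_reduced,
        "channels_reduced_in_n_subjects": ch_reduced,
        "detection_rate_pre_median": float(np.median(det_pre)),
        "detection_rate_post_median": float(np.median(det_post)),
        "comparison": comparison.reset_index().to_dict(orient="records"),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    report = dict(report, runtime_s=time.time() - t0)

    config.to_yaml(out / "config.yaml")
    cfg_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()
    manifest = {
        "package": "neoictal",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": cfg_hash,
        "numpy": np.__version__,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return report
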