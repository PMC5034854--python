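"""Published per-infant values of the 18-neonate phenobarbital cohort.

Two reference tables ship with the package, transcribed from the study
that motivates this analysis:

* ``cohort_seizure_counts.tsv`` — per patient: aetiology, the matched
  number of seizures analysed before and after the phenobarbital loading
  dose, and the doses given.
* ``cohort_subject_summaries.tsv`` — per infant: median peak seizure
  amplitude (μV) and median number of EEG channels involved at seizure
  peak, before and after phenobarbital, plus the electroclinical
  uncoupling status (EC electroclinical, EG electrographic, NVD no video
  data) carried as pass-through metadata.

``reference_report`` recomputes the published group statistics from
these per-infant values using the package's own statistics module.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .stats import per_subject_change_counts, percentile_wa, wilcoxon_signed_rank

__all__ = ["load_seizure_counts", "load_subject_summaries", "reference_report"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("neoictal.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_seizure_counts() -> pd.DataFrame:
    """Per-patient matched seizure counts and phenobarbital doses."""
    df = _read("cohort_seizure_counts.tsv")
    if len(df) != 18:
        raise ValueError(f"expected 18 patients, found {len(df)}")
    if not (df["n_pre"] == df["n_post"]).all():
        raise ValueError("matched counts must be equal pre and post")
    return df


def load_subject_summaries() -> pd.DataFrame:
    """Per-infant median amplitude and channel involvement, both periods."""
    df = _read("cohort_subject_summaries.tsv")
    if len(df) != 18:
        raise ValueError(f"expected 18 infants, found {len(df)}")
    return df


def reference_report() -> dict:
    """Recompute the published group statistics from the per-infant values.

    Returns group medians and IQRs for peak amplitude and channels
    involved at seizure peak, the Wilcoxon p-values, the relative
    amplitude drop, per-subject change counts, and the total number of
    matched seizures per period.
    """
    counts = load_seizure_counts()
    summ = load_subject_summaries()
    amp_pre = summ["amp_pre_uV"].to_numpy(float)
    amp_post = summ["amp_post_uV"].to_numpy(float)
    ch_pre = summ["channels_peak_pre"].to_numpy(float)
    ch_post = summ["channels_peak_post"].to_numpy(float)

    amp_test = wilcoxon_signed_rank(amp_pre, amp_post)
    ch_test = wilcoxon_signed_rank(ch_pre, ch_post)
    amp_reduced, n = per_subject_change_counts(amp_pre, amp_post)
    ch_reduced, _ = per_subject_change_counts(ch_pre, ch_post)
    pre_med = percentile_wa(amp_pre, 0.5)
    post_med = percentile_wa(amp_post, 0.5)
    return {
        "n_subjects": int(n),
        "amplitude": {
            "pre_median_uV": pre_med,
            "pre_iqr_uV": (percentile_wa(amp_pre, 0.25), percentile_wa(amp_pre, 0.75)),
            "post_median_uV": post_med,
            "post_iqr_uV": (percentile_wa(amp_post, 0.25), percentile_wa(amp_post, 0.75)),
            "drop_percent": 100.0 * (pre_med - post_med) / pre_med,
            "wilcoxon_p": amp_test.p_value,
            "reduced_in_n_subjects": amp_reduced,
        },
        "channels_peak": {
            "pre_median": percentile_wa(ch_pre, 0.5),
            "pre_iqr": (percentile_wa(ch_pre, 0.25), percentile_wa(ch_pre, 0.75)),
            "post_median": percentile_wa(ch_post, 0.5),
            "post_iqr": (percentile_wa(ch_post, 0.25), percentile_wa(ch_post, 0.75)),
            "wilcoxon_p": ch_test.p_value,
            "reduced_in_n_subjects": ch_reduced,
        },
        "matched_seizures_per_period": int(counts["n_pre"].sum()),
    }
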