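"""Paired pre/post-dose cohort statistics.

The analysis mirrors the standard clinical workflow for a paired
drug-effect study: seizure counts are matched per subject by truncating
both periods to the smaller count (in temporal order); each measured
variable is reduced to one value per subject per period (median for
quantitative variables, maximum for the ordinal rhythmicity and
background scores, proportion for binary variables); groups are described
by median and interquartile range using the weighted-average
(``(n+1)p``, SPSS/Minitab "HAVERAGE") percentile convention; and the
pre/post difference is tested with the two-sided Wilcoxon signed-rank
test (zero differences dropped, mid-ranks for ties, tie-corrected normal
approximation, with exact enumeration available for small samples).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats

__all__ = [
    "MatchedPair",
    "WilcoxonResult",
    "SUMMARY_REDUCERS",
    "match_counts",
    "summarise",
    "percentile_wa",
    "wilcoxon_signed_rank",
    "compare_cohort",
    "per_subject_change_counts",
]


#: Reducer fixed per variable: how seizures collapse to one value per
#: subject per period.
SUMMARY_REDUCERS: dict[str, str] = {
    "peak_amplitude_uV": "median",
    "duration_s": "median",
    "channels_onset": "median",
    "channels_peak": "median",
    "frequency_variability_hz": "median",
    "rhythmicity_score": "maximum",
    "background_score": "maximum",
    "detection_rate": "proportion",
    "morphology_changed": "proportion",
}


@dataclass(frozen=True)
class MatchedPair:
    """Per-subject seizure lists truncated to the smaller count."""

    subject_id: str
    pre: tuple
    post: tuple

    @property
    def k(self) -> int:
        return len(self.pre)


def match_counts(pre_list: Sequence, post_list: Sequence,
                 subject_id: str = "") -> MatchedPair:
    """Truncate both periods to the first ``min(n_pre, n_post)`` seizures.

    Inputs must be in temporal order; empty lists are rejected because the
    study design requires seizures in both periods.
    """
    if not pre_list or not post_list:
        raise ValueError(
            f"subject {subject_id!r}: seizures required in both periods "
            f"(got {len(pre_list)} pre, {len(post_list)} post)"
        )
    k = min(len(pre_list), len(post_list))
    return MatchedPair(subject_id=subject_id,
                       pre=tuple(pre_list[:k]), post=tuple(post_list[:k]))


def summarise(values: Sequence[float], variable: str) -> float:
    """Reduce one subject-period's per-seizure values for ``variable``."""
    if variable not in SUMMARY_REDUCERS:
        raise ValueError(f"unknown variable {variable!r}; "
                         f"known: {sorted(SUMMARY_REDUCERS)}")
    vals = np.asarray([v for v in values if v is not None], dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"no usable values to summarise for {variable!r}")
    reducer = SUMMARY_REDUCERS[variable]
    if reducer == "median":
        return float(np.median(vals))
    if reducer == "maximum":
        return float(np.max(vals))
    return float(np.mean(vals))  # proportion of a binary variable


def percentile_wa(values: Sequence[float], p: float) -> float:
    """Weighted-average percentile at position ``(n+1)p`` on sorted data.

    Identical to ``np.quantile(..., method="weibull")``; at p = 0.5 it
    coincides with the ordinary median for every input.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("percentile of empty data")
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    return float(np.quantile(vals, p, method="weibull"))


@dataclass(frozen=True)
class WilcoxonResult:
    w_plus: float
    z: float
    p_value: float
    n_nonzero: int
    method: str


def _exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    n = len(ranks)
    masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    dist = masks @ ranks
    p_low = np.mean(dist <= w_plus + 1e-9)
    p_high = np.mean(dist >= w_plus - 1e-9)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_signed_rank(pre: Sequence[float], post: Sequence[float],
                         method: str = "approx") -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    Differences ``pre − post`` equal to zero are dropped; tied absolute
    differences receive mid-ranks; the normal approximation includes the
    tie correction (the SPSS pathway).  ``method="exact"`` enumerates all
    sign assignments (n ≤ 12 only); ``"approx"`` is the default.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or pre.size < 2:
        raise ValueError("paired vectors of equal length >= 2 required")
    d = pre - post
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; test degenerate")
    ranks = spstats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.round(np.abs(d), 12), return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0)
    if sigma == 0:
        raise ValueError("zero variance after tie correction; test degenerate")
    z = (w_plus - mu) / sigma
    if method == "exact":
        if n > 12:
            raise ValueError("exact enumeration supported for n <= 12 only")
        p = _exact_p(ranks, w_plus)
    elif method == "approx":
        p = float(2.0 * spstats.norm.sf(abs(z)))
    else:
        raise ValueError(f"method must be 'approx' or 'exact', got {method!r}")
    return WilcoxonResult(w_plus=w_plus, z=float(z), p_value=p,
                          n_nonzero=n, method=method)


def compare_cohort(summaries: pd.DataFrame,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Group-level pre/post comparison per variable.

    ``summaries`` needs columns ``subject_id``, ``period`` ("pre"/"post")
    and one column per variable (one row per subject per period).  The
    result has one row per variable with group median and IQR for both
    periods, the Wilcoxon statistic and two-sided p, and a significance
    flag at ``alpha``.
    """
    required = {"subject_id", "period"}
    if not required.issubset(summaries.columns):
        raise ValueError(f"summaries must contain columns {sorted(required)}")
    wide = summaries.pivot(index="subject_id", columns="period")
    variables = [c for c in summaries.columns if c not in required]
    rows = []
    for var in variables:
        try:
            pre = wide[(var, "pre")]
            post = wide[(var, "post")]
        except KeyError as exc:
            raise ValueError(f"missing period column for {var!r}") from exc
        both = pd.concat([pre, post], axis=1).dropna()
        if both.isna().any().any() or len(both) < len(wide):
            raise ValueError(
                f"variable {var!r}: subjects present in one period only")
        pre_v, post_v = both.iloc[:, 0].to_numpy(), both.iloc[:, 1].to_numpy()
        try:
            res = wilcoxon_signed_rank(pre_v, post_v)
            w, z, p, n_nz = res.w_plus, res.z, res.p_value, res.n_nonzero
        except ValueError:  # degenerate: identical pre and post
            w, z, p, n_nz = float("nan"), 0.0, 1.0, 0
        rows.append({
            "variable": var,
            "pre_median": percentile_wa(pre_v, 0.5),
            "pre_q1": percentile_wa(pre_v, 0.25),
            "pre_q3": percentile_wa(pre_v, 0.75),
            "post_median": percentile_wa(post_v, 0.5),
            "post_q1": percentile_wa(post_v, 0.25),
            "post_q3": percentile_wa(post_v, 0.75),
            "w_plus": w, "z": z, "p_value": p, "n_nonzero": n_nz,
            "significant": p < alpha,
        })
    return pd.DataFrame(rows).set_index("variable")


def per_subject_change_counts(pre: Sequence[float], post: Sequence[float]
                              ) -> tuple[int, int]:
    """Number of subjects whose summary strictly decreased after the dose.

    Ties (no change) count as not reduced.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired vectors required")
    return int(np.sum(post < pre)), int(pre.size)
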