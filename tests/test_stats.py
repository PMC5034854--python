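"""Paired cohort statistics: count matching, reducers, the (n+1)p
percentile convention, and the Wilcoxon signed-rank test against
independent oracles (brute-force enumeration and scipy)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as spstats

from neoictal.fixtures import (load_seizure_counts, load_subject_summaries,
                               reference_report)
from neoictal.stats import (compare_cohort, match_counts,
                            per_subject_change_counts, percentile_wa,
                            summarise, wilcoxon_signed_rank)


@pytest.fixture(scope="module")
def cohort():
    return load_subject_summaries()


class TestMatchCounts:
    def test_truncates_to_smaller_count(self):
        pre = list(range(5))
        post = list(range(100, 120))
        pair = match_counts(pre, post)
        assert pair.k == 5
        assert pair.post == tuple(range(100, 105))  # first post seizures kept

    def test_equal_counts_unchanged(self):
        pair = match_counts(list("abcdefg"), list("hijklmn"))
        assert pair.k == 7

    def test_empty_period_rejected(self):
        with pytest.raises(ValueError):
            match_counts([], [1, 2])

    def test_published_matched_totals(self):
        counts = load_seizure_counts()
        assert counts["n_pre"].sum() == 262
        assert counts["n_post"].sum() == 262


class TestSummarise:
    def test_even_count_median_averages(self):
        assert summarise([40, 60], "peak_amplitude_uV") == 50

    def test_maximum_reducer(self):
        assert summarise([1, 3, 2], "rhythmicity_score") == 3

    def test_proportion_reducer(self):
        assert summarise([True, False, True, True], "morphology_changed") == 0.75

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError):
            summarise([1.0], "not_a_variable")

    @given(st.lists(st.integers(1, 8), min_size=1, max_size=9))
    @settings(max_examples=60, deadline=None)
    def test_median_matches_brute_force(self, counts):
        # brute-force oracle: sort, midpoint average
        s = sorted(counts)
        n = len(s)
        expected = s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2
        assert summarise(counts, "channels_peak") == expected


class TestPercentile:
    def test_reproduces_printed_iqr_bounds(self, cohort):
        post = cohort["amp_post_uV"].to_numpy(float)
        assert round(percentile_wa(post, 0.25) + 1e-9, 2) == 46.13
        assert percentile_wa(post, 0.75) == pytest.approx(89.25, abs=0.005)
        ch_post = cohort["channels_peak_post"].to_numpy(float)
        assert round(percentile_wa(ch_post, 0.25) + 1e-9, 2) == 1.38

    @given(st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_p_half_is_the_median(self, values):
        assert percentile_wa(values, 0.5) == pytest.approx(
            float(np.median(values)), rel=1e-12, abs=1e-9)

    def test_bad_p_rejected(self):
        with pytest.raises(ValueError):
            percentile_wa([1.0, 2.0], 1.0)


def brute_force_wilcoxon(pre, post):
    """Independent oracle: rank by hand, enumerate every sign assignment."""
    d = np.asarray(pre, float) - np.asarray(post, float)
    d = d[d != 0]
    ranks = spstats.rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    dist = [np.sum(np.array(signs) * ranks)
            for signs in itertools.product([0, 1], repeat=len(d))]
    dist = np.asarray(dist)
    p = 2 * min((dist <= w + 1e-9).mean(), (dist >= w - 1e-9).mean())
    return w, min(1.0, p)


class TestWilcoxon:
    def test_published_amplitude_p(self, cohort):
        res = wilcoxon_signed_rank(cohort["amp_pre_uV"], cohort["amp_post_uV"])
        assert round(res.p_value, 3) == 0.001
        assert res.n_nonzero == 18

    def test_published_channels_p(self, cohort):
        res = wilcoxon_signed_rank(cohort["channels_peak_pre"],
                                   cohort["channels_peak_post"])
        assert res.p_value == pytest.approx(0.018, abs=0.0005)

    def test_matches_scipy_approx_path(self, cohort):
        res = wilcoxon_signed_rank(cohort["amp_pre_uV"], cohort["amp_post_uV"])
        ref = spstats.wilcoxon(cohort["amp_pre_uV"], cohort["amp_post_uV"],
                               zero_method="wilcox", correction=False,
                               mode="approx")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_path_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pre = rng.normal(10, 3, size=8)
        post = pre - rng.normal(0.5, 2, size=8)
        res = wilcoxon_signed_rank(pre, post, method="exact")
        w_ref, p_ref = brute_force_wilcoxon(pre, post)
        assert res.w_plus == pytest.approx(w_ref)
        assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_exact_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(7)
        pre = rng.normal(size=10)
        post = rng.normal(size=10)
        res = wilcoxon_signed_rank(pre, post, method="exact")
        ref = spstats.wilcoxon(pre, post, mode="exact")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_identical_vectors_degenerate(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestCompareCohort:
    @pytest.fixture()
    def summaries(self, cohort):
        rows = []
        for _, r in cohort.iterrows():
            rows.append({"subject_id": r["subject"], "period": "pre",
                         "peak_amplitude_uV": r["amp_pre_uV"],
                         "channels_peak": r["channels_peak_pre"]})
            rows.append({"subject_id": r["subject"], "period": "post",
                         "peak_amplitude_uV": r["amp_post_uV"],
                         "channels_peak": r["channels_peak_post"]})
        return pd.DataFrame(rows)

    def test_group_medians_match_publication(self, summaries):
        table = compare_cohort(summaries)
        amp = table.loc["peak_amplitude_uV"]
        assert amp["pre_median"] == 123.0 and amp["post_median"] == 53.5
        ch = table.loc["channels_peak"]
        assert ch["pre_median"] == 4.0 and ch["post_median"] == 3.0
        assert amp["significant"] and ch["significant"]

    def test_identical_periods_not_significant(self, summaries):
        same = summaries.copy()
        pre_rows = same[same["period"] == "pre"].copy()
        post_rows = pre_rows.copy()
        post_rows["period"] = "post"
        table = compare_cohort(pd.concat([pre_rows, post_rows]))
        assert not table["significant"].any()
        assert (table["p_value"] == 1.0).all()

    def test_subject_mismatch_rejected(self, summaries):
        broken = summaries.iloc[:-1]  # drop one subject's post row
        with pytest.raises(ValueError):
            compare_cohort(broken)


class TestChangeCounts:
    def test_published_change_counts(self, cohort):
        amp = per_subject_change_counts(cohort["amp_pre_uV"], cohort["amp_post_uV"])
        ch = per_subject_change_counts(cohort["channels_peak_pre"],
                                       cohort["channels_peak_post"])
        assert amp == (14, 18)
        assert ch == (10, 18)

    def test_no_change_counts_zero(self):
        assert per_subject_change_counts([1, 2, 3], [1, 2, 3]) == (0, 3)


class TestReferenceReport:
    def test_headline_numbers(self):
        rep = reference_report()
        amp = rep["amplitude"]
        assert amp["pre_median_uV"] == 123.0
        assert amp["post_median_uV"] == 53.5
        assert amp["drop_percent"] == pytest.approx(56.5, abs=0.05)
        assert rep["matched_seizures_per_period"] == 262
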