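import numpy as np
import pytest

from distractorlab import (
    delta_median,
    delta_median_summary,
    delta_median_table,
    exam_profiles,
    generate_exam,
    nfd_count_distribution,
    option_selection_rates,
    selection_rate_histogram,
    stats_by_nfd_count,
    total_scores,
)
from distractorlab.synthdata import ExamGeneratorConfig

from conftest import make_exam


def exam_with_counts():
    """100 candidates; i1 has counts A(correct)=50, B=30, C=19, D=1, E=0."""
    col = ["A"] * 50 + ["B"] * 30 + ["C"] * 19 + ["D"] * 1 + ["E"] * 0
    filler = ["B"] * 100
    return make_exam({"i1": col, "i2": filler}, {"i1": "A", "i2": "B"})


# ---------------------------------------------------------------------------
# selection rates and NF-D classification
# ---------------------------------------------------------------------------

def test_selection_rates_and_strict_thresholds():
    rm, key = exam_with_counts()
    prof = option_selection_rates(rm, key, "i1")
    assert prof.rates == {"B": 30.0, "C": 19.0, "D": 1.0, "E": 0.0}
    # strict inequality: a rate of exactly 1.0 is functional at <1%
    assert prof.nfd_set(1.0) == {"E"}
    assert prof.nfd_set(5.0) == {"D", "E"}
    # nesting across thresholds
    assert prof.nfd_set(1.0) <= prof.nfd_set(5.0)


def test_all_correct_item_has_four_nfds():
    rm, key = make_exam(
        {"i1": ["A"] * 10, "i2": ["B"] * 5 + ["C"] * 5},
        {"i1": "A", "i2": "B"},
    )
    prof = option_selection_rates(rm, key, "i1")
    assert prof.nfd_set(1.0) == {"B", "C", "D", "E"}
    assert prof.nfd_set(0.0) == set()  # rate >= 0 always, strict inequality


def test_rates_sum_with_p_and_omissions_to_100(small_exam):
    responses, key, _ = small_exam
    from distractorlab import item_p_value

    for item, prof in exam_profiles(responses, key).items():
        total = sum(prof.rates.values()) + item_p_value(responses, key, item)
        assert total == pytest.approx(100.0)  # no omissions generated


def test_omissions_stay_in_denominator_not_numerator():
    rm, key = make_exam(
        {"i1": ["A", "B", "OMIT", "OMIT"], "i2": ["B"] * 4},
        {"i1": "A", "i2": "B"},
    )
    prof = option_selection_rates(rm, key, "i1")
    assert prof.n_candidates == 4
    assert prof.rates["B"] == 25.0
    assert "OMIT" not in prof.rates


# ---------------------------------------------------------------------------
# NF-D count distribution
# ---------------------------------------------------------------------------

def test_nfd_distribution_on_designed_exam():
    # every item: correct + 2 chosen distractors + 2 never chosen => 2 NF-Ds
    col = ["A"] * 60 + ["B"] * 25 + ["C"] * 15
    rm, key = make_exam({"i1": col, "i2": col}, {"i1": "A", "i2": "A"})
    dist = nfd_count_distribution(rm, key, threshold=1.0)
    assert dist.loc[2, "n_items"] == 2
    assert dist.loc[2, "pct_items"] == 100.0
    assert dist["pct_items"].sum() == pytest.approx(100.0)


def test_nfd_distribution_threshold_zero_all_functional(small_exam):
    responses, key, _ = small_exam
    dist = nfd_count_distribution(responses, key, threshold=0.0)
    assert dist.loc[0, "n_items"] == responses.n_items


def test_nfd_distribution_matches_per_item_classification(small_exam):
    responses, key, _ = small_exam
    dist = nfd_count_distribution(responses, key, threshold=5.0)
    brute = {k: 0 for k in range(5)}
    for item in responses.item_ids:
        prof = option_selection_rates(responses, key, item)
        brute[sum(r < 5.0 for r in prof.rates.values())] += 1
    assert dist["n_items"].to_dict() == brute
    assert dist["n_items"].sum() == responses.n_items


# ---------------------------------------------------------------------------
# selection-rate histogram
# ---------------------------------------------------------------------------

def test_histogram_all_never_selected():
    rm, key = make_exam(
        {"i1": ["A"] * 10, "i2": ["B"] * 10}, {"i1": "A", "i2": "B"}
    )
    hist = selection_rate_histogram(rm, key)
    assert hist.loc[hist["bin"] == "never selected", "pct_distractors"].item() == 100.0


def test_histogram_hand_binned_counts_and_conservation():
    rm, key = exam_with_counts()
    hist = selection_rate_histogram(rm, key, bin_edges=(0, 1, 10, 100))
    by_bin = dict(zip(hist["bin"], hist["n_distractors"]))
    # i1: B=30%, C=19%, D=1%, E=0; i2: A=C=D=E=0 (all on correct B)
    assert by_bin == {"never selected": 5, "(0, 1]": 1, "(1, 10]": 0, "(10, 100]": 2}
    assert hist["n_distractors"].sum() == 4 * rm.n_items
    assert hist["pct_distractors"].sum() == pytest.approx(100.0)


def test_histogram_rejects_bad_edges(small_exam):
    responses, key, _ = small_exam
    with pytest.raises(ValueError):
        selection_rate_histogram(responses, key, bin_edges=(0, 50))
    with pytest.raises(ValueError):
        selection_rate_histogram(responses, key, bin_edges=(0, 10, 5, 100))


# ---------------------------------------------------------------------------
# stats grouped by NF-D count
# ---------------------------------------------------------------------------

def test_stats_by_nfd_count_single_group():
    col = ["A"] * 60 + ["B"] * 25 + ["C"] * 15
    rm, key = make_exam({"i1": col, "i2": col}, {"i1": "A", "i2": "A"})
    grouped = stats_by_nfd_count(rm, key, threshold=1.0)
    assert list(grouped.index) == [2]
    assert grouped.loc[2, "mean_p"] == pytest.approx(60.0)
    assert grouped.loc[2, "n_items"] == 2


def test_stats_by_nfd_count_partitions_items(default_exam):
    responses, key, _ = default_exam
    grouped = stats_by_nfd_count(responses, key, threshold=1.0)
    assert grouped["n_items"].sum() == responses.n_items


def test_mean_p_increases_with_designed_nfd_count():
    """Easier items carry more NF-Ds, so mean P rises with NF-D count."""
    cfg = ExamGeneratorConfig(n_items=300)
    responses, key, _ = generate_exam(cfg, seed=5)
    grouped = stats_by_nfd_count(responses, key, threshold=1.0)
    sub = grouped[grouped["n_items"] >= 5]
    p = sub["mean_p"]
    assert (p.diff().dropna() > 0).all()
    # discrimination falls as items get easier
    assert sub["mean_r"].iloc[-1] < sub["mean_r"].iloc[0]


# ---------------------------------------------------------------------------
# delta-medians
# ---------------------------------------------------------------------------

def build_delta_exam():
    """Five candidates with totals 0,1,3,4,5; the two weakest pick B on item t."""
    cols = {"t": ["B", "B", "A", "A", "A"]}
    # filler f is answered correctly by candidates ranked above f
    for f in range(5):
        cols[f"f{f}"] = ["E" if j > f else "D" for j in range(5)]
    key = {"t": "A", **{f"f{f}": "E" for f in range(5)}}
    return make_exam(cols, key)


def test_delta_median_hand_case():
    rm, key = build_delta_exam()
    totals = total_scores(rm, key)
    assert sorted(totals) == [0, 1, 3, 4, 5]  # group median 3
    rec = delta_median(rm, key, "t", "B")
    assert rec.n_selectors == 2
    # selectors score 0 and 1: median 0.5 (midpoint of two), delta -2.5
    assert rec.delta_median == pytest.approx(0.5 - 3.0)


def test_delta_median_all_selectors_is_zero():
    rm, key = make_exam(
        {"i1": ["B"] * 4, "i2": ["A", "A", "B", "B"]}, {"i1": "A", "i2": "A"}
    )
    assert delta_median(rm, key, "i1", "B").delta_median == 0.0


def test_delta_median_none_without_selectors():
    rm, key = make_exam(
        {"i1": ["A"] * 4, "i2": ["A", "A", "B", "B"]}, {"i1": "A", "i2": "A"}
    )
    assert delta_median(rm, key, "i1", "E") is None


def test_delta_median_table_matches_brute_force(small_exam):
    import statistics

    responses, key, _ = small_exam
    table = delta_median_table(responses, key)
    totals = total_scores(responses, key)
    overall = statistics.median(totals)
    for row in table.sample(25, random_state=0).itertuples():
        sel = [
            totals[c]
            for c in responses.candidate_ids
            if responses.choice(c, row.item_id) == row.option
        ]
        assert row.delta_median == pytest.approx(statistics.median(sel) - overall)
        assert row.n_selectors == len(sel)


def test_delta_median_summary_brackets_records(small_exam):
    responses, key, _ = small_exam
    table = delta_median_table(responses, key)
    summary = delta_median_summary(responses, key, threshold=1.0)
    assert summary["min_delta"].min() == table["delta_median"].min()
    assert summary["max_delta"].max() == table["delta_median"].max()
    for cls in summary.index:
        assert (
            summary.loc[cls, "min_delta"]
            <= summary.loc[cls, "median_delta"]
            <= summary.loc[cls, "max_delta"]
        )


def test_nfd_selectors_weaker_than_fd_selectors(default_exam):
    """NF-Ds attract lower-scoring candidates than F-Ds do."""
    responses, key, _ = default_exam
    summary = delta_median_summary(responses, key, threshold=1.0)
    assert summary.loc["NF-D", "median_delta"] < summary.loc["F-D", "median_delta"]
    assert summary.loc["NF-D", "median_delta"] < 0
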