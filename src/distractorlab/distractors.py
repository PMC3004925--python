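"""Distractor selection-rate analysis.

A distractor is *non-functional* (NF-D) at threshold ``t`` percent when it
is selected by strictly fewer than ``t``% of all candidates; a distractor
at or above the threshold is *functional* (F-D).  The conventional
thresholds are 1% and 5%.  The denominator is always the full candidate
group, and omitted answers never count as a selection.

Besides classification this module provides the NF-D count distribution
over items, selection-rate histograms, grouping of difficulty and
discrimination by NF-D count, and the delta-median attractiveness measure:
the median total score of the candidates selecting a distractor minus the
median total score of all candidates (negative values mean the distractor
draws low-performing candidates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ctt
from .io import AnswerKey, ResponseMatrix

#: Conventional NF-D thresholds, in percent of candidates.
DEFAULT_THRESHOLDS = (1.0, 5.0)

#: Default selection-rate histogram bin edges (percent): 1-point steps up
#: to 10%, then wider bins.  Figure-style binning is configurable.
DEFAULT_BIN_EDGES = (0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 20, 30, 50, 100)


@dataclass
class DistractorProfile:
    """Selection counts and rates of one item's distractors."""

    item_id: str
    n_candidates: int
    counts: dict[str, int]  # distractor label -> selection count
    rates: dict[str, float]  # distractor label -> percent of candidates

    def nfd_set(self, threshold: float) -> set[str]:
        """Distractors selected by strictly less than ``threshold``%."""
        return {d for d, r in self.rates.items() if r < threshold}

    def n_nfd(self, threshold: float) -> int:
        return len(self.nfd_set(threshold))


def option_selection_rates(
    responses: ResponseMatrix, key: AnswerKey, item: str
) -> DistractorProfile:
    """Count and rate of every distractor of ``item``.

    Rates are percentages of all candidates (omissions stay in the
    denominator but are never a selection).
    """
    col = responses.table[item]
    n = responses.n_candidates
    counts = {d: int((col == d).sum()) for d in key.distractors(item)}
    rates = {d: 100.0 * c / n for d, c in counts.items()}
    return DistractorProfile(item_id=item, n_candidates=n, counts=counts, rates=rates)


def exam_profiles(
    responses: ResponseMatrix, key: AnswerKey
) -> dict[str, DistractorProfile]:
    return {
        item: option_selection_rates(responses, key, item)
        for item in responses.item_ids
    }


def nfd_count_distribution(
    responses: ResponseMatrix, key: AnswerKey, threshold: float
) -> pd.DataFrame:
    """Partition items by their number of NF-Ds at ``threshold``.

    Returns a frame indexed by ``n_nfd`` (0..4 for five-option items) with
    the item count and the percentage of items in each group; the
    percentages sum to 100.
    """
    profiles = exam_profiles(responses, key)
    max_d = max(len(key.distractors(i)) for i in responses.item_ids)
    counts = {k: 0 for k in range(max_d + 1)}
    for prof in profiles.values():
        counts[prof.n_nfd(threshold)] += 1
    n_items = len(profiles)
    return pd.DataFrame(
        {
            "n_nfd": list(counts),
            "n_items": list(counts.values()),
            "pct_items": [100.0 * c / n_items for c in counts.values()],
        }
    ).set_index("n_nfd")


def selection_rate_histogram(
    responses: ResponseMatrix,
    key: AnswerKey,
    bin_edges=DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Histogram of distractor selection rates.

    Never-selected distractors (rate exactly 0) are reported in a separate
    leading ``never selected`` row; positive rates fall into half-open bins
    ``(lo, hi]`` built from ``bin_edges``, which must be strictly increasing
    and cover [0, 100].  Every distractor lands in exactly one row.
    """
    edges = list(bin_edges)
    if sorted(edges) != edges or len(set(edges)) != len(edges):
        raise ValueError("bin edges must be strictly increasing")
    if edges[0] != 0 or edges[-1] < 100:
        raise ValueError("bin edges must cover [0, 100]")
    rates = [
        r
        for prof in exam_profiles(responses, key).values()
        for r in prof.rates.values()
    ]
    rates = np.asarray(rates)
    total = rates.size
    n_zero = int((rates == 0).sum())
    labels = ["never selected"]
    counts = [n_zero]
    pos = rates[rates > 0]
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"({lo:g}, {hi:g}]")
        counts.append(int(((pos > lo) & (pos <= hi)).sum()))
    return pd.DataFrame(
        {
            "bin": labels,
            "n_distractors": counts,
            "pct_distractors": [100.0 * c / total for c in counts],
        }
    )


def stats_by_nfd_count(
    responses: ResponseMatrix, key: AnswerKey, threshold: float
) -> pd.DataFrame:
    """Mean P-value and Fisher-pooled discrimination by NF-D count.

    Groups the exam's items by their number of NF-Ds at ``threshold`` and
    reports each group's mean difficulty and pooled discrimination; groups
    partition the items.
    """
    profiles = exam_profiles(responses, key)
    rows = []
    by_count: dict[int, list[str]] = {}
    for item, prof in profiles.items():
        by_count.setdefault(prof.n_nfd(threshold), []).append(item)
    for n_nfd in sorted(by_count):
        items = by_count[n_nfd]
        ps = [ctt.item_p_value(responses, key, i) for i in items]
        rs = [ctt.item_discrimination(responses, key, i) for i in items]
        rows.append(
            {
                "n_nfd": n_nfd,
                "n_items": len(items),
                "mean_p": float(np.mean(ps)),
                "mean_r": ctt.fisher_mean_r(rs),
            }
        )
    return pd.DataFrame(rows).set_index("n_nfd")


# ---------------------------------------------------------------------------
# Delta-median attractiveness
# ---------------------------------------------------------------------------

@dataclass
class DeltaMedianRecord:
    """Departure of a distractor's selectors from the group median.

    ``delta_median`` is in raw number-correct points: median total score of
    the candidates selecting the option minus the median total score of all
    candidates.  Only defined when at least one candidate selected the
    option.
    """

    item_id: str
    option: str
    delta_median: float
    n_selectors: int


def delta_median(
    responses: ResponseMatrix, key: AnswerKey, item: str, option: str
) -> DeltaMedianRecord | None:
    """Delta-median of one distractor; ``None`` when nobody selected it."""
    totals = ctt.total_scores(responses, key)
    selectors = totals[responses.table[item] == option]
    if selectors.empty:
        return None
    return DeltaMedianRecord(
        item_id=item,
        option=option,
        delta_median=float(selectors.median() - totals.median()),
        n_selectors=int(selectors.size),
    )


def delta_median_table(responses: ResponseMatrix, key: AnswerKey) -> pd.DataFrame:
    """Delta-median records of every selected distractor, with rates."""
    totals = ctt.total_scores(responses, key)
    group_median = totals.median()
    rows = []
    for item in responses.item_ids:
        prof = option_selection_rates(responses, key, item)
        col = responses.table[item]
        for d in key.distractors(item):
            if prof.counts[d] == 0:
                continue
            sel = totals[col == d]
            rows.append(
                {
                    "item_id": item,
                    "option": d,
                    "delta_median": float(sel.median() - group_median),
                    "n_selectors": prof.counts[d],
                    "rate": prof.rates[d],
                }
            )
    return pd.DataFrame(rows, columns=["item_id", "option", "delta_median",
                                       "n_selectors", "rate"])


def delta_median_summary(
    responses: ResponseMatrix, key: AnswerKey, threshold: float
) -> pd.DataFrame:
    """Median and range of delta-medians for F-Ds vs NF-Ds.

    Pools per-distractor records across items, classifies each selected
    distractor at ``threshold`` and summarises each class by the median,
    minimum and maximum of its delta-medians.
    """
    table = delta_median_table(responses, key)
    table = table.assign(
        functional_class=np.where(table["rate"] < threshold, "NF-D", "F-D")
    )
    rows = []
    for cls in ("F-D", "NF-D"):
        sub = table[table["functional_class"] == cls]["delta_median"]
        if sub.empty:
            continue
        rows.append(
            {
                "class": cls,
                "n": int(sub.size),
                "median_delta": float(sub.median()),
                "min_delta": float(sub.min()),
                "max_delta": float(sub.max()),
            }
        )
    return pd.DataFrame(rows).set_index("class")
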