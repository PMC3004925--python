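"""Analysis of expert least-plausibility ratings.

Experts mark, per item, the option most obviously wrong (rank 1) and the
next most obviously wrong (rank 2); two rank-1 marks denote a tie.  A *hit*
is a rank-1 mark landing on a distractor that really is non-functional by
selection rate; when an expert tied two options, one of the two is picked
at random before testing, with a seeded generator so the analysis is
reproducible.

The *panel* view aggregates the individual ratings: options are scored by
weighted votes (rank 1 = 2 points, rank 2 = 1 point) and the two
highest-scoring options become the panel's first and second removal
recommendation.  The top-voted option operationalises the mode of the
experts' least-plausible choices; the weighted score extends it to a second
option so the panel can drive two-removal elimination models.  The
alternative of taking the mode of the rank-2 marks alone for the second
removal is available via ``second_from_rank2_mode``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ctt
from .distractors import exam_profiles
from .elimination import EliminationPlan
from .io import AnswerKey, ExpertRatings, ResponseMatrix


@dataclass
class HitRecord:
    """Whether one expert's least-plausible mark hit an NF-D."""

    expert_id: str
    item_id: str
    hit: bool
    tie_resolved: bool


@dataclass
class PanelRating:
    """Panel-level removal recommendation for one item."""

    item_id: str
    first_removal: str
    second_removal: str
    vote_counts: dict[str, tuple[int, int]]  # option -> (rank-1, rank-2) votes
    tie_broken: bool


def expert_hit(
    marks: dict[str, int],
    nfd_set: set[str],
    rng: np.random.Generator,
    expert_id: str = "",
    item_id: str = "",
) -> HitRecord:
    """Test one expert's rating of one item against the NF-D ground truth.

    The hit criterion applies to the expert's rank-1 mark; with two rank-1
    marks (a tie) one of them is first picked uniformly at random from
    ``rng``.
    """
    rank1 = sorted(o for o, r in marks.items() if r == 1)
    if not rank1:
        raise ValueError(f"no rank-1 mark for expert {expert_id!r}, item {item_id!r}")
    tie = len(rank1) == 2
    pick = rank1[int(rng.integers(2))] if tie else rank1[0]
    return HitRecord(
        expert_id=expert_id, item_id=item_id, hit=pick in nfd_set, tie_resolved=tie
    )


def hit_records(
    ratings: ExpertRatings,
    responses: ResponseMatrix,
    key: AnswerKey,
    threshold: float,
    seed: int,
) -> list[HitRecord]:
    """Hit records for every (expert, item) pair on items with >= 1 NF-D.

    Tie resolution draws from a generator seeded per (expert, item) from
    ``seed`` and the pair's position in sorted order, so records do not
    depend on iteration order.
    """
    profiles = exam_profiles(responses, key)
    eligible = {
        item for item, prof in profiles.items() if prof.n_nfd(threshold) >= 1
    }
    records = []
    items = sorted(set(ratings.item_ids) & eligible)
    item_index = {item: i for i, item in enumerate(items)}
    experts = ratings.expert_ids
    expert_index = {e: i for i, e in enumerate(experts)}
    frame = ratings.frame[ratings.frame["item_id"].isin(eligible)]
    for (expert, item), grp in frame.groupby(["expert_id", "item_id"]):
        rng = np.random.default_rng(
            [seed, item_index[item], expert_index[expert]]
        )
        marks = dict(zip(grp["option"], grp["rank"]))
        records.append(
            expert_hit(
                marks,
                profiles[item].nfd_set(threshold),
                rng,
                expert_id=expert,
                item_id=item,
            )
        )
    return records


def hit_statistics(
    ratings: ExpertRatings,
    responses: ResponseMatrix,
    key: AnswerKey,
    threshold: float,
    seed: int,
) -> dict:
    """Per-item hit proportions and their association with NF-D count.

    Returns the per-item hit proportion (over the experts who rated the
    item), its mean and range across items, and the Pearson correlation
    between per-item hit proportion and the item's NF-D count.  The
    correlation is undefined (NaN) when either quantity is constant.
    """
    records = hit_records(ratings, responses, key, threshold, seed)
    if not records:
        raise ValueError("no items with at least one NF-D were rated")
    df = pd.DataFrame([(r.item_id, r.hit) for r in records],
                      columns=["item_id", "hit"])
    per_item = df.groupby("item_id")["hit"].mean()
    profiles = exam_profiles(responses, key)
    nfd_counts = pd.Series(
        {item: profiles[item].n_nfd(threshold) for item in per_item.index}
    )
    if per_item.std(ddof=0) == 0 or nfd_counts.std(ddof=0) == 0:
        r = ctt.UNDEFINED
    else:
        r = float(np.corrcoef(per_item.to_numpy(), nfd_counts.to_numpy())[0, 1])
    return {
        "per_item": per_item,
        "mean": float(per_item.mean()),
        "min": float(per_item.min()),
        "max": float(per_item.max()),
        "pearson_r_vs_nfd_count": r,
        "n_items": int(per_item.size),
    }


def panel_mode(
    ratings: ExpertRatings,
    item: str,
    key: AnswerKey | None = None,
    second_from_rank2_mode: bool = False,
) -> PanelRating:
    """Aggregate one item's ratings into a panel recommendation.

    Options are scored 2 points per rank-1 vote and 1 point per rank-2
    vote; the two highest scores give the first and second removal.  With
    ``second_from_rank2_mode`` the second removal is instead the most
    frequent rank-2 mark (excluding the first removal).  All ties break by
    option-label order and are flagged.
    """
    sel = ratings.frame[ratings.frame["item_id"] == item]
    if sel.empty:
        raise ValueError(f"no ratings for item {item!r}")
    votes: dict[str, list[int]] = {}
    for opt, rank in zip(sel["option"], sel["rank"]):
        votes.setdefault(opt, [0, 0])[rank - 1] += 1
    if key is not None:
        candidates = [o for o in key.options[item] if o != key.correct[item]]
        for o in candidates:
            votes.setdefault(o, [0, 0])
    score = {o: 2 * v[0] + v[1] for o, v in votes.items()}
    order = sorted(score, key=lambda o: (-score[o], o))
    first = order[0]
    if second_from_rank2_mode:
        r2 = {o: v[1] for o, v in votes.items() if o != first}
        second = sorted(r2, key=lambda o: (-r2[o], o))[0]
        second_score_tie = sorted(r2.values(), reverse=True)[:2]
        tie2 = len(r2) > 1 and second_score_tie[0] == second_score_tie[1]
    else:
        second = order[1]
        tie2 = len(order) > 2 and score[order[1]] == score[order[2]]
    tie_broken = score[order[0]] == score[order[1]] or tie2
    return PanelRating(
        item_id=item,
        first_removal=first,
        second_removal=second,
        vote_counts={o: (v[0], v[1]) for o, v in votes.items()},
        tie_broken=tie_broken,
    )


def panel_ratings(
    ratings: ExpertRatings,
    key: AnswerKey | None = None,
    second_from_rank2_mode: bool = False,
) -> dict[str, PanelRating]:
    return {
        item: panel_mode(ratings, item, key, second_from_rank2_mode)
        for item in ratings.item_ids
    }


def panel_hit_rate(
    panel: dict[str, PanelRating],
    responses: ResponseMatrix,
    key: AnswerKey,
    threshold: float,
) -> dict:
    """Fraction of eligible items where the panel's first removal is an NF-D.

    Eligible items are those with at least one NF-D at ``threshold``.
    Returns the hit count, the number of eligible items, and the percentage.
    """
    profiles = exam_profiles(responses, key)
    eligible = [
        item
        for item in panel
        if item in profiles and profiles[item].n_nfd(threshold) >= 1
    ]
    if not eligible:
        raise ValueError("no rated items with at least one NF-D")
    hits = sum(
        panel[item].first_removal in profiles[item].nfd_set(threshold)
        for item in eligible
    )
    return {
        "hits": int(hits),
        "n_items": len(eligible),
        "pct": 100.0 * hits / len(eligible),
    }


def panel_plan(
    panel: dict[str, PanelRating], key: AnswerKey | None = None
) -> EliminationPlan:
    """Elimination plan from panel recommendations (first, then second)."""
    plan = {
        item: [rating.first_removal, rating.second_removal]
        for item, rating in panel.items()
    }
    if key is not None:
        from .elimination import validate_plan

        validate_plan(plan, key)
    return plan
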