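"""Simulated reduction of five-option items to four or three options.

The core simulation: the least and second-least chosen distractors of each
item are identified from the original response matrix, removed one at a
time, and the candidates who chose them are reallocated under two extreme
assumptions about their behaviour:

* RANDOM — the candidate picks uniformly at random among the options that
  remain after the removal (4 options after the first removal, 3 after the
  second), modelling a candidate who had chosen the removed distractor by
  chance;
* CORRECT — the candidate switches to the keyed answer, modelling a
  candidate who had oscillated between the removed distractor and the
  correct option.

Models are labelled by the number of distractors that remain:
A = 3 distractors / random, B = 3 distractors / correct answer,
C = 2 distractors / random, D = 2 distractors / correct answer.

Removing a distractor that nobody chose alters no responses, so such
removals are exact no-ops on every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ctt
from .distractors import DistractorProfile, exam_profiles, option_selection_rates
from .io import AnswerKey, ResponseMatrix

RANDOM = "random"
CORRECT = "correct"


@dataclass(frozen=True)
class EliminationModel:
    """How many distractors are removed and where their choosers go."""

    label: str
    n_removed: int  # 1 or 2
    reallocation: str  # RANDOM or CORRECT

    @property
    def description(self) -> str:
        kind = "random" if self.reallocation == RANDOM else "right answer"
        return f"{self.label}) {4 - self.n_removed} distractors, {kind}"


#: The four canonical models. Labels count the distractors that REMAIN:
#: A/B keep 3 (one removal), C/D keep 2 (two removals).
MODELS: dict[str, EliminationModel] = {
    "A": EliminationModel("A", 1, RANDOM),
    "B": EliminationModel("B", 1, CORRECT),
    "C": EliminationModel("C", 2, RANDOM),
    "D": EliminationModel("D", 2, CORRECT),
}

#: item_id -> ordered distractor labels to remove (removal priority order).
EliminationPlan = dict[str, list[str]]


def rank_distractors(profile: DistractorProfile) -> list[str]:
    """Distractor labels in ascending selection count.

    Ties are broken deterministically by option-label order, so the first
    element is always a minimally chosen distractor.
    """
    return sorted(profile.counts, key=lambda d: (profile.counts[d], d))


def statistics_plan(
    responses: ResponseMatrix,
    key: AnswerKey,
    n_remove: int = 2,
    nfd_only: bool = False,
    threshold: float = 1.0,
) -> EliminationPlan:
    """Removal plan from selection statistics of the original matrix.

    Per item the ``n_remove`` least chosen distractors, in ascending order
    of selection count.  With ``nfd_only`` the plan is restricted to
    distractors classified NF-D at ``threshold`` (so items may contribute
    fewer than ``n_remove`` removals, or none).
    """
    plan: EliminationPlan = {}
    for item, prof in exam_profiles(responses, key).items():
        ranked = rank_distractors(prof)
        if nfd_only:
            nfd = prof.nfd_set(threshold)
            ranked = [d for d in ranked if d in nfd]
        plan[item] = ranked[:n_remove]
    return plan


def validate_plan(plan: EliminationPlan, key: AnswerKey) -> None:
    for item, removals in plan.items():
        if len(set(removals)) != len(removals):
            raise ValueError(f"plan for item {item!r} repeats a removal")
        for opt in removals:
            if opt == key.correct[item]:
                raise ValueError(
                    f"plan for item {item!r} removes the keyed answer {opt!r}"
                )
            if opt not in key.options[item]:
                raise ValueError(
                    f"plan for item {item!r} removes unknown option {opt!r}"
                )


def eliminate(
    responses: ResponseMatrix,
    key: AnswerKey,
    plan: EliminationPlan,
    model: EliminationModel,
    seed: int | None = None,
    random_over_five: bool = False,
) -> ResponseMatrix:
    """Apply removals and reallocate affected candidates.

    Takes the first ``model.n_removed`` entries of each item's plan and
    applies them sequentially: the least-chosen distractor is removed and
    its choosers reallocated first, then the second least (both identified
    from the original matrix).  Under RANDOM reallocation a candidate moved
    onto a distractor that is removed in the next step is reallocated
    again.  Cells of unaffected candidates are bit-identical to the input.

    ``seed`` is required for RANDOM reallocation and ignored otherwise.
    ``random_over_five`` reproduces, for comparison, a literal uniform draw
    over all five option codes -- the draw may then land on a removed
    distractor -- instead of the default draw over the remaining options.
    """
    validate_plan(plan, key)
    if model.reallocation == RANDOM:
        if seed is None:
            raise ValueError("RANDOM reallocation requires a seed")
        rng = np.random.default_rng(seed)
    table = responses.table.copy()
    for item in responses.item_ids:
        removals = plan.get(item, [])[: model.n_removed]
        col = table[item].to_numpy(copy=True)
        for step, removed in enumerate(removals):
            mask = col == removed
            n_hit = int(mask.sum())
            if n_hit == 0:
                continue  # never-chosen distractor: exact no-op
            if model.reallocation == CORRECT:
                col[mask] = key.correct[item]
            else:
                if random_over_five:
                    remaining = list(key.options[item])
                else:
                    remaining = [
                        o for o in key.options[item]
                        if o not in removals[: step + 1]
                    ]
                col[mask] = rng.choice(remaining, size=n_hit)
        table[item] = col
    return ResponseMatrix(table, options=responses.options)


def run_models(
    responses: ResponseMatrix,
    key: AnswerKey,
    models=("A", "B", "C", "D"),
    plan: EliminationPlan | None = None,
    seed: int | None = None,
    target_items: int = 100,
) -> pd.DataFrame:
    """Exam statistics of the original exam and of each elimination model.

    One row per model plus a leading ``4 distractors`` row for the original
    exam; columns are the mean item P-value, the Fisher-pooled mean
    discrimination, Cronbach's alpha and its Spearman-Brown projection to
    ``target_items`` items.  ``plan`` defaults to the statistics-based
    least/second-least plan; a panel-derived plan produces the expert
    variant of the same table.
    """
    if plan is None:
        plan = statistics_plan(responses, key, n_remove=2)
    rng = np.random.default_rng(seed) if seed is not None else None

    def row(label: str, resp: ResponseMatrix) -> dict:
        stats = ctt.exam_stats(resp, key)
        std = (
            ctt.spearman_brown(stats.alpha, stats.n_items, target_items)
            if ctt.is_defined(stats.alpha) and stats.alpha >= 0
            else ctt.UNDEFINED
        )
        return {
            "model": label,
            "pct_correct": stats.mean_p,
            "discrimination": stats.mean_r,
            "reliability": stats.alpha,
            "std_reliability_100": std,
        }

    rows = [row("4 distractors", responses)]
    for name in models:
        model = MODELS[name] if isinstance(name, str) else name
        sub_seed = int(rng.integers(2**31)) if rng is not None else None
        modified = eliminate(responses, key, plan, model, seed=sub_seed)
        rows.append(row(model.description, modified))
    return pd.DataFrame(rows)
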