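"""Classical test theory statistics for one-best-answer MCQ exams.

Implements the item- and exam-level statistics the distractor analyses are
built on: item difficulty (P-value, the percentage of correct answers),
item discrimination (point-biserial correlation of item correctness with
the rest score), Cronbach's alpha, Fisher-Z pooled mean discrimination, and
Spearman-Brown projection of reliability to a standard 100-item test
length.

Statistics that do not exist for a given input (for example the
discrimination of an item everyone answered correctly) are returned as
:data:`UNDEFINED`, which is NaN; they are values, not errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OMIT, AnswerKey, ResponseMatrix

#: Marker for statistics that are undefined on the given input (NaN).
UNDEFINED = float("nan")


def is_defined(x: float) -> bool:
    return not math.isnan(x)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_matrix(responses: ResponseMatrix, key: AnswerKey) -> pd.DataFrame:
    """0/1 correctness matrix (candidate x item); omissions score 0."""
    correct = pd.Series({i: key.correct[i] for i in responses.item_ids})
    return (responses.table == correct).astype(int)


def total_scores(responses: ResponseMatrix, key: AnswerKey) -> pd.Series:
    """Number-correct total score per candidate (one point per item)."""
    return score_matrix(responses, key).sum(axis=1)


def item_p_value(responses: ResponseMatrix, key: AnswerKey, item: str) -> float:
    """Percentage of candidates answering ``item`` correctly, in [0, 100]."""
    col = responses.table[item]
    return 100.0 * (col == key.correct[item]).mean()


def item_discrimination(
    responses: ResponseMatrix,
    key: AnswerKey,
    item: str,
    corrected: bool = True,
) -> float:
    """Point-biserial discrimination of one item.

    Pearson correlation between the item's 0/1 correctness vector and the
    rest score (total score minus the item's own point).  ``corrected=False``
    correlates against the uncorrected total score instead.  Returns
    :data:`UNDEFINED` when either vector is constant.
    """
    scores = score_matrix(responses, key)
    x = scores[item].to_numpy(dtype=float)
    y = scores.sum(axis=1).to_numpy(dtype=float)
    if corrected:
        y = y - x
    if x.std() == 0.0 or y.std() == 0.0:
        return UNDEFINED
    return float(np.corrcoef(x, y)[0, 1])


def cronbach_alpha(responses: ResponseMatrix, key: AnswerKey) -> float:
    """Cronbach's alpha of the 0/1 item scores.

    alpha = k/(k-1) * (1 - sum of item variances / total-score variance),
    with population (n-denominator) variances; the choice of denominator
    cancels in the ratio but is fixed for reproducible intermediates.
    Returns :data:`UNDEFINED` when the total score has zero variance.
    """
    scores = score_matrix(responses, key).to_numpy(dtype=float)
    k = scores.shape[1]
    item_vars = scores.var(axis=0, ddof=0)
    total_var = scores.sum(axis=1).var(ddof=0)
    if total_var == 0.0:
        return UNDEFINED
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


# ---------------------------------------------------------------------------
# Pooling and standardization
# ---------------------------------------------------------------------------

def fisher_mean_r(rs) -> float:
    """Average correlations through the Fisher Z transform.

    Undefined (NaN) entries and entries with ``|r| = 1`` (where atanh
    diverges) are dropped before pooling; an empty effective list yields
    :data:`UNDEFINED`.  The result is ``tanh(mean(atanh(r)))``.
    """
    eff = [r for r in rs if is_defined(r) and abs(r) < 1.0]
    if not eff:
        return UNDEFINED
    return float(np.tanh(np.mean(np.arctanh(eff))))


def spearman_brown(
    reliability: float, n_items: int, target_items: int = 100
) -> float:
    """Project a reliability to a different test length.

    Spearman-Brown prophecy: rho' = k*rho / (1 + (k-1)*rho) with
    k = target_items / n_items.  Reliability 1 is a fixed point; negative
    reliabilities are rejected.
    """
    if reliability < 0.0:
        raise ValueError(f"reliability must be non-negative, got {reliability}")
    if reliability >= 1.0:
        return 1.0
    k = target_items / n_items
    return k * reliability / (1.0 + (k - 1.0) * reliability)


# ---------------------------------------------------------------------------
# Aggregated per-item and per-exam views
# ---------------------------------------------------------------------------

@dataclass
class ItemStats:
    """Difficulty, discrimination and option selection rates of one item.

    ``option_rates`` maps every option label (and :data:`OMIT`) to the
    percentage of all candidates choosing it; the rates sum to 100 and the
    rate of the keyed option equals ``p_value``.
    """

    item_id: str
    p_value: float
    discrimination_r: float
    option_rates: dict[str, float]


def item_stats(
    responses: ResponseMatrix, key: AnswerKey, item: str, corrected: bool = True
) -> ItemStats:
    col = responses.table[item]
    n = responses.n_candidates
    rates = {
        opt: 100.0 * (col == opt).sum() / n for opt in key.options[item]
    }
    rates[OMIT] = 100.0 * (col == OMIT).sum() / n
    return ItemStats(
        item_id=item,
        p_value=item_p_value(responses, key, item),
        discrimination_r=item_discrimination(responses, key, item, corrected),
        option_rates=rates,
    )


@dataclass
class ExamStats:
    """Exam-level summary: mean difficulty, pooled discrimination, alpha."""

    mean_p: float
    mean_r: float
    alpha: float
    std_reliability_100: float
    n_items: int
    n_candidates: int


def exam_stats(
    responses: ResponseMatrix, key: AnswerKey, corrected: bool = True
) -> ExamStats:
    """Mean P, Fisher-Z mean discrimination, alpha and its 100-item projection."""
    items = responses.item_ids
    ps = [item_p_value(responses, key, i) for i in items]
    rs = [item_discrimination(responses, key, i, corrected) for i in items]
    alpha = cronbach_alpha(responses, key)
    std = (
        spearman_brown(alpha, len(items), 100)
        if is_defined(alpha) and alpha >= 0
        else UNDEFINED
    )
    return ExamStats(
        mean_p=float(np.mean(ps)),
        mean_r=fisher_mean_r(rs),
        alpha=alpha,
        std_reliability_100=std,
        n_items=len(items),
        n_candidates=responses.n_candidates,
    )
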