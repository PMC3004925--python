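"""Synthetic exams and expert ratings with realistic distractor structure.

Candidate choice follows a nominal-response (softmax) model: candidate
``c`` with ability ``theta_c ~ N(0, 1)`` chooses option ``k`` of an item
with probability proportional to ``exp(alpha_k * theta_c + beta_k)``.  The
correct option carries a positive ability slope and an intercept that sets
item difficulty; distractors carry non-positive slopes (so low-ability
candidates prefer them) and intercepts ``beta`` that set their selection
rates.  Distractors designed to be non-functional get strongly negative
``beta`` (rarely selected) and more negative slopes (their few selectors
are weak candidates), which produces the delta-median contrast between
functional and non-functional distractors.

Defaults emulate a large one-best-answer licensing examination: 620
candidates, 55 five-option items, about 30% of distractors selected by
fewer than 1% of candidates, roughly one item in ten with a never-selected
distractor, and mean item difficulty around 76% correct.  The per-item
count of designed NF-Ds follows the empirical distribution observed in
such exams (about 30% of items with none, 3-4% with four), and easier items
carry more NF-Ds.

Synthetic expert ratings mark the truly least plausible distractor (lowest
``beta``) with a configurable accuracy, with items split into two blocks
rated by disjoint expert groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DEFAULT_OPTIONS, OMIT, AnswerKey, ExpertRatings, ResponseMatrix

#: Distribution of the number of designed NF-Ds per item (0..4), matching
#: the shares observed in large five-option licensing exams at the <1%
#: threshold; its mean of ~1.26 NF-Ds/item puts ~31.5% of distractors
#: below the 1% selection rate.
NFD_COUNT_PROBS = (0.303, 0.319, 0.231, 0.113, 0.034)


@dataclass
class ExamGeneratorConfig:
    """Parameters of the synthetic exam generator.

    Ability is standard normal.  ``slope_range`` bounds the correct
    option's ability slope (uniform draw); ``difficulty_mean/sd`` set the
    correct option's intercept, shifted by ``difficulty_per_nfd`` for each
    designed NF-D so that easier items have more NF-Ds.  Functional and
    non-functional distractors draw (slope, intercept) from separate normal
    distributions; slopes are clipped to be non-positive.
    """

    n_candidates: int = 620
    n_items: int = 55
    n_options: int = 5
    slope_range: tuple[float, float] = (0.25, 0.55)
    difficulty_mean: float = 0.75
    difficulty_sd: float = 0.45
    difficulty_per_nfd: float = 0.35
    fd_slope_mean: float = -0.3
    fd_slope_sd: float = 0.1
    fd_beta_mean: float = -1.6
    fd_beta_sd: float = 0.6
    nfd_slope_mean: float = -0.8
    nfd_slope_sd: float = 0.2
    nfd_beta_mean: float = -5.3
    nfd_beta_sd: float = 0.4
    nfd_count_probs: tuple[float, ...] = NFD_COUNT_PROBS
    omit_rate: float = 0.0


@dataclass
class RatingGeneratorConfig:
    """Parameters of the synthetic expert-rating generator.

    ``accuracy`` is the probability that an expert's rank-1 mark is the
    truly least plausible distractor (lowest ``beta``); the rank-2 mark is
    drawn the same way from the remaining distractors.  With probability
    ``tie_prob`` the two marks are reported as an equal-implausibility tie
    (two rank-1 marks).  Items are split into two blocks, each rated by its
    own group of ``n_experts_per_block`` experts.
    """

    n_experts_per_block: int = 18
    accuracy: float = 0.8
    tie_prob: float = 0.1


def choice_probabilities(
    theta: np.ndarray, slopes: np.ndarray, intercepts: np.ndarray
) -> np.ndarray:
    """Softmax choice probabilities (candidates x options); rows sum to 1."""
    util = theta[:, None] * slopes[None, :] + intercepts[None, :]
    util -= util.max(axis=1, keepdims=True)
    p = np.exp(util)
    p /= p.sum(axis=1, keepdims=True)
    return p


def generate_exam(
    config: ExamGeneratorConfig | None = None, seed: int = 0
) -> tuple[ResponseMatrix, AnswerKey, pd.DataFrame]:
    """Draw a synthetic exam.

    Returns the response matrix, the answer key, and a ground-truth frame
    with one row per (item, option): the option's role (``correct``,
    ``fd`` or ``nfd``), its slope and intercept in the choice model, and
    per item the ability used.  Identical seeds yield identical output.
    """
    cfg = config or ExamGeneratorConfig()
    if cfg.n_options != len(DEFAULT_OPTIONS):
        raise ValueError("only five-option items are supported")
    rng = np.random.default_rng(seed)
    probs = np.asarray(cfg.nfd_count_probs, dtype=float)
    probs = probs / probs.sum()

    theta = rng.normal(0.0, 1.0, cfg.n_candidates)
    candidate_ids = [f"c{i + 1:04d}" for i in range(cfg.n_candidates)]
    item_ids = [f"i{j + 1:03d}" for j in range(cfg.n_items)]

    columns: dict[str, np.ndarray] = {}
    correct: dict[str, str] = {}
    truth_rows = []
    for item in item_ids:
        n_nfd = int(rng.choice(len(probs), p=probs))
        correct_pos = int(rng.integers(cfg.n_options))
        distractor_pos = [k for k in range(cfg.n_options) if k != correct_pos]
        nfd_pos = set(
            rng.choice(distractor_pos, size=n_nfd, replace=False).tolist()
        )
        slopes = np.empty(cfg.n_options)
        intercepts = np.empty(cfg.n_options)
        slopes[correct_pos] = rng.uniform(*cfg.slope_range)
        intercepts[correct_pos] = (
            rng.normal(cfg.difficulty_mean, cfg.difficulty_sd)
            + cfg.difficulty_per_nfd * n_nfd
        )
        for k in distractor_pos:
            if k in nfd_pos:
                slopes[k] = min(0.0, rng.normal(cfg.nfd_slope_mean, cfg.nfd_slope_sd))
                intercepts[k] = rng.normal(cfg.nfd_beta_mean, cfg.nfd_beta_sd)
            else:
                slopes[k] = min(0.0, rng.normal(cfg.fd_slope_mean, cfg.fd_slope_sd))
                intercepts[k] = rng.normal(cfg.fd_beta_mean, cfg.fd_beta_sd)
        p = choice_probabilities(theta, slopes, intercepts)
        draws = rng.random(cfg.n_candidates)
        chosen = (draws[:, None] > p.cumsum(axis=1)).sum(axis=1)
        labels = np.array(DEFAULT_OPTIONS)[chosen]
        if cfg.omit_rate > 0:
            omit = rng.random(cfg.n_candidates) < cfg.omit_rate
            labels = np.where(omit, OMIT, labels)
        columns[item] = labels
        correct[item] = DEFAULT_OPTIONS[correct_pos]
        for k in range(cfg.n_options):
            role = "correct" if k == correct_pos else (
                "nfd" if k in nfd_pos else "fd"
            )
            truth_rows.append(
                {
                    "item_id": item,
                    "option": DEFAULT_OPTIONS[k],
                    "role": role,
                    "slope": slopes[k],
                    "beta": intercepts[k],
                }
            )

    table = pd.DataFrame(columns, index=candidate_ids)
    responses = ResponseMatrix(table)
    key = AnswerKey(correct=correct)
    truth = pd.DataFrame(truth_rows)
    return responses, key, truth


def least_plausible(truth: pd.DataFrame) -> dict[str, list[str]]:
    """Per item, distractor labels ordered by true plausibility (ascending beta)."""
    order: dict[str, list[str]] = {}
    for item, grp in truth.groupby("item_id", sort=False):
        d = grp[grp["role"] != "correct"].sort_values(["beta", "option"])
        order[item] = list(d["option"])
    return order


def generate_ratings(
    truth: pd.DataFrame,
    config: RatingGeneratorConfig | None = None,
    seed: int = 0,
) -> ExpertRatings:
    """Draw synthetic expert least-plausibility ratings from ground truth.

    Items are split alternately into blocks A and B, each rated by its own
    experts.  Per expert and item: the rank-1 mark is the true least
    plausible distractor with probability ``accuracy`` (else uniform over
    the other three); the rank-2 mark repeats the scheme on the remaining
    three; with probability ``tie_prob`` the two marks become a rank-1 tie.
    """
    cfg = config or RatingGeneratorConfig()
    rng = np.random.default_rng(seed)
    plaus = least_plausible(truth)
    items = list(plaus)
    blocks = {item: ("A" if j % 2 == 0 else "B") for j, item in enumerate(items)}
    rows = []
    for block in ("A", "B"):
        block_items = [i for i in items if blocks[i] == block]
        for e in range(cfg.n_experts_per_block):
            expert = f"{block}{e + 1:02d}"
            for item in block_items:
                order = plaus[item]  # ascending true plausibility
                if rng.random() < cfg.accuracy:
                    first = order[0]
                else:
                    first = order[1 + int(rng.integers(3))]
                rest = [d for d in order if d != first]
                if rng.random() < cfg.accuracy:
                    second = rest[0]
                else:
                    second = rest[1 + int(rng.integers(2))]
                tie = rng.random() < cfg.tie_prob
                rows.append(
                    {"expert_id": expert, "item_id": item, "option": first,
                     "rank": 1, "block": block}
                )
                rows.append(
                    {"expert_id": expert, "item_id": item, "option": second,
                     "rank": 1 if tie else 2, "block": block}
                )
    return ExpertRatings(pd.DataFrame(rows))
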