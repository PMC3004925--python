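# Methods

## Scope and data model

`distractorlab` analyses five-option one-best-answer MCQ exams given as a
candidate × item matrix of chosen option labels plus an answer key. All
analyses are classical test theory: item difficulty P (percent correct),
item discrimination r (point-biserial), Cronbach's alpha, and derived
distractor-level measures. Omitted answers carry the reserved label
`OMIT`: they score as incorrect and are never counted as a distractor
selection, but the candidate stays in every denominator (selection rates
are fractions of the full candidate group). How real examinees' omissions
should be treated is a convention of this package, not an empirical fact;
with the default generator no omissions occur.

## Conventions and numerical choices

* **NF-D thresholds are strict.** A distractor is non-functional at
  threshold *t* iff its selection rate is `< t` percent; a rate of exactly
  1.0% is functional at the 1% threshold. NF-D sets are therefore nested
  across thresholds.
* **Discrimination** is the item-rest (corrected) point-biserial by
  default: the item's 0/1 correctness correlated with the total score minus
  that item's point. The uncorrected item-total variant is available via
  `corrected=False`. Items with zero variance in either vector have
  undefined discrimination (NaN), which is a value, not an error.
* **Fisher-Z pooling.** Mean discriminations are `tanh(mean(atanh(r)))`.
  Undefined entries and entries with |r| = 1 (where atanh diverges) are
  dropped before pooling; an empty effective list pools to NaN.
* **Cronbach's alpha** uses population (n-denominator) variances for all
  intermediates; the choice cancels in alpha itself but is fixed so
  intermediate outputs are reproducible.
* **Spearman-Brown** standardization to 100 items uses
  ρ′ = kρ/(1+(k−1)ρ), k = 100/n. Reliability 1 is a fixed point; negative
  reliabilities are rejected (the projection is not meaningful there).
* **Medians** of even-sized sets are the midpoint of the two central
  values. Delta-medians are in raw number-correct points (1 point per
  item); a distractor nobody selected has no delta-median record.
* **Tie-breaking** is deterministic by option-label order wherever a total
  order is needed (equally rare distractors in removal ranking, equal vote
  scores in panel aggregation) and flagged where it matters
  (`PanelRating.tie_broken`). The one deliberately random tie-break —
  an expert marking two options as equally implausible — draws from a
  generator seeded per (expert, item), so results are reproducible but
  unbiased.

## Option-reduction simulation

Removals are identified from the *original* matrix: per item, the least
and second-least selected distractors (ties by label order). They are then
applied sequentially — first removal, reallocate, second removal,
reallocate — so under random reallocation a candidate can be moved twice.
Reallocation is either:

* `RANDOM`: uniform over the options remaining after the removal (4 after
  the first, 3 after the second). A comparison flag `random_over_five`
  reproduces a literal uniform draw over all five option codes instead,
  in which case the draw may land back on a removed distractor.
* `CORRECT`: every affected candidate switches to the keyed answer.

Removing a never-selected distractor changes no responses, so such
removals are exact no-ops on every statistic. An optional plan variant
restricts removals to distractors classified NF-D, giving items a variable
number of removals; its impact is bounded between the original exam and
the full least/second-least removal.

These two reallocation rules are deliberate extremes: real candidates mix
knowledge-driven and guessing behaviour, so observed consequences of an
actual option reduction should fall between the RANDOM and CORRECT rows.

## Expert panel aggregation

The panel's first removal is the option with the highest weighted vote
score (rank-1 mark = 2 points, rank-2 mark = 1 point), which coincides
with the mode of the least-plausible marks in the unanimous and
clear-majority cases. The weighting exists to pick a *second* removal from
the same scores, which a plain mode of rank-1 marks does not define;
`second_from_rank2_mode=True` instead takes the mode of the rank-2 marks
alone. A panel *hit* on an item with at least one NF-D is a first removal
that lands in the NF-D set.

## Synthetic data generator

Candidate `c` has ability θ_c ~ N(0,1) and chooses option `k` of an item
with probability ∝ exp(α_k·θ_c + β_k) — a nominal-response model chosen
because it controls selection rates and ability gradients continuously
with few parameters. Per item:

* the correct option has slope α ~ U(0.25, 0.55) and intercept
  ~ N(0.75, 0.45²) plus 0.35 per designed NF-D (easier items carry more
  NF-Ds, reproducing the observed difficulty gradient across NF-D counts);
* the number of designed NF-Ds per item is drawn from
  (30.3, 31.9, 23.1, 11.3, 3.4)% for 0–4, the distribution reported for
  large five-option medical licensing exams, putting ~31.5% of distractors
  below a 1% selection rate in expectation;
* functional distractors have slope ~ N(−0.3, 0.1²) (clipped ≤ 0) and
  intercept ~ N(−1.6, 0.6²); designed NF-Ds have slope ~ N(−0.8, 0.2²) and
  intercept ~ N(−5.3, 0.4²). The more negative NF-D slopes make their few
  selectors low-ability candidates, which produces the delta-median
  contrast between functional and non-functional distractors.

At the default 620 candidates × 55 items this calibration yields mean P
around 76–80, alpha around 0.75–0.80, mean item-rest r around 0.2, about
30% of distractors selected by <1% of candidates, and designed NF-Ds
classified NF-D at the 1% threshold in ≈99% of cases (≥95% in every
replicate examined). Roughly 10% of distractors are never selected —
somewhat more than the ~7% seen in real exam pools; pushing it lower would
raise NF-D selection counts enough to hurt the near-perfect recovery
above, and recovery was prioritised. Exam-level statistics match a real
licensing exam's order of magnitude rather than any particular exam.

Synthetic expert ratings mark the truly least plausible distractor (lowest
β) with probability `accuracy` (default 0.8), else a uniformly random
other distractor, and analogously for the rank-2 mark on the remainder;
with probability `tie_prob` (default 0.1) the two marks become an
equal-implausibility tie. Items are split alternately into two blocks,
each rated by its own group of 18 experts. Setting `accuracy = 0.25`
makes the rank-1 mark uniform over the four distractors, the analytic
chance level at which an item with k NF-Ds is hit with probability k/4.

### What passing tests on synthetic data do and do not show

The generator reproduces the *structure* the analyses assume — rare
distractors, ability-dependent option choice, difficulty/discrimination
gradients over NF-D counts — but real exams add features it lacks:
item-type mixtures, content clustering, testwiseness cues, omission
behaviour, and non-normal ability distributions. Passing the recovery and
ordering tests shows the pipeline measures what it claims under a known
truth, not that any particular real exam has these parameter values.

## Problem sizes used in the validation suite

Oracle-equivalence checks run on 100 random 5–15 × 3–6 matrices against
brute-force formula evaluation; elimination invariants on a 100 × 20
synthetic exam with the random-reallocation expectation averaged over
1000 seeded replicates; parameter recovery and the qualitative model
ordering on 20 replicates of the default 620 × 55 configuration. These
sizes give Monte-Carlo error well inside the asserted bands.

## Known limitations

* No IRT modelling: the simulation recomputes classical statistics only;
  equating of pass-fail thresholds after option reduction is out of scope.
* No distractor-level discrimination indices (selector samples are small
  and skewed, so such indices would be unstable).
* No inter-rater reliability coefficients for the expert survey.
* The panel's second removal has no canonical definition; the weighted
  vote used here is one defensible choice, and an alternative is provided.
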