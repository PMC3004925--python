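# distractorlab

Distractor analytics for five-option one-best-answer multiple-choice
examinations, aimed at psychometricians and assessment units who maintain
large MCQ item banks (for example medical licensing exams).

Many high-stakes exams still present 1 correct answer plus 4 distractors,
although a sizeable share of those distractors is *non-functional* — so
implausible that almost nobody picks them. `distractorlab` quantifies this
and simulates what would happen to the exam's psychometric quality if the
rarely chosen distractors were dropped:

* **NF-D detection** — a distractor is non-functional at threshold *t*
  when strictly fewer than *t*% of all candidates select it (conventional
  thresholds: 1% and 5%; omissions count in the denominator, never as a
  selection).
* **Attractiveness** — the *delta-median* of a distractor is the median
  total score of its selectors minus the median total score of all
  candidates; strongly negative values mean the distractor still does its
  job of attracting weak candidates.
* **Option-reduction simulation** — the least and second-least chosen
  distractors are removed and their choosers reallocated under two extreme
  behaviour models: uniformly at random over the remaining options, or
  straight to the correct answer. The four models are labelled by the
  distractors that remain: A = 3/random, B = 3/correct, C = 2/random,
  D = 2/correct. Difficulty (mean P-value), discrimination (Fisher-Z pooled
  item-rest point-biserial r̄), reliability (Cronbach's α) and the
  Spearman-Brown projection of α to a 100-item test,
  ρ′ = kρ / (1 + (k−1)ρ) with k = 100/n, are recomputed per model.
* **Expert survey analysis** — experts mark the least (rank 1) and second
  least (rank 2) plausible option per item; a *hit* is a rank-1 mark on a
  truly non-functional distractor. Individual hit rates, their Pearson
  correlation with the item's NF-D count, and a majority ("panel")
  aggregation that can drive the elimination models are all computed.
* **Synthetic data** — a nominal-response (softmax) generator produces
  exams with a realistic NF-D structure (and matching expert ratings), so
  the whole pipeline can be exercised and validated without confidential
  exam data.

## Worked example

```python
import distractorlab as dl

responses, key, truth = dl.generate_exam(seed=1)   # 620 candidates, 55 items
stats = dl.exam_stats(responses, key)
print(f"mean P = {stats.mean_p:.2f}, mean r = {stats.mean_r:.2f}, "
      f"alpha = {stats.alpha:.2f}, alpha(100 items) = {stats.std_reliability_100:.2f}")

print(dl.nfd_count_distribution(responses, key, threshold=1.0).round(1))
print(dl.delta_median_summary(responses, key, threshold=1.0).round(1))
print(dl.run_models(responses, key, seed=2).round(2).to_string(index=False))
```

prints

```
mean P = 77.37, mean r = 0.23, alpha = 0.79, alpha(100 items) = 0.88
       n_items  pct_items
n_nfd
0           17       30.9
1           22       40.0
2           13       23.6
3            2        3.6
4            1        1.8
         n  median_delta  min_delta  max_delta
class
F-D    162          -3.5      -11.0        0.5
NF-D    37          -7.0      -21.0        4.5
                         model  pct_correct  discrimination  reliability  std_reliability_100
                 4 distractors        77.37            0.23         0.79                 0.88
      A) 3 distractors, random        77.68            0.22         0.79                 0.87
B) 3 distractors, right answer        78.70            0.22         0.78                 0.87
      C) 2 distractors, random        78.89            0.21         0.78                 0.86
D) 2 distractors, right answer        82.13            0.19         0.73                 0.83
```

Reading the output: about a third of the items have four functional
distractors at the <1% threshold; non-functional distractors attract
clearly weaker candidates (median delta −7.0 vs −3.5 points for functional
ones); and dropping one or even two rarely chosen distractors barely moves
difficulty or reliability except under model D, where every affected
candidate switches to the correct answer.

The same pipeline is available from the shell:

```bash
distractorlab simulate --seed 1 -o responses.csv -k key.csv --truth truth.csv --ratings ratings.csv
distractorlab analyze responses.csv key.csv --threshold 1
distractorlab eliminate responses.csv key.csv --seed 2 -o table.csv
distractorlab experts ratings.csv responses.csv key.csv --seed 3 --emit-plan plan.csv
```

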