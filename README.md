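# hofstee

Hofstee compromise cut-score calculation for pass/fail examinations — a
tested library and command-line tool for assessment teams in medical (and
any other) education who set standards with judge panels.

## The method

Criterion-referenced standard setting fixes an absolute pass mark;
norm-referenced setting fixes the failure rate. The Hofstee method is the
classic compromise between the two. Each judge supplies four bounds:

- `c_min`, `c_max` — the lowest/highest score they would accept as the
  cut-off (percent score);
- `f_min`, `f_max` — the lowest/highest percentage of students they would
  accept failing.

The panel's bounds are aggregated per parameter (mean by default, median
optionally). On the chart of cumulative percentage of students against
score, line **AB** runs from A = (`c_min`, `f_max`) to
B = (`c_max`, `f_min`); the cut score is where AB crosses the cohort's
cumulative curve

```
y(v) = 100 · #{scores ≤ v} / n
```

(one vertex per distinct score, straight segments between). Rather than
reading the crossing off a drawing, this package finds it algebraically:
it scans the curve's segments in ascending score order and solves each
against AB; since AB descends while the curve ascends, at most one
crossing exists. If AB never meets the curve, the tool fails loudly with a
directional diagnostic (which judge bound to revisit) instead of silently
substituting a corner.

Alongside the cut score the tool reports panel statistics (mean/SD/median
per parameter), the largest data gaps near the cut (wide empty score
intervals make a cut easier to defend), a JSON result document, and the
familiar full/detailed charts.

## Worked example

Five judges rated a 181-student class (scores 43–97):

| judge | c_min | c_max | f_min | f_max |
|---|---|---|---|---|
| 1 | 50 | 60 | 1 | 4 |
| 2 | 44 | 56 | 3 | 8 |
| 3 | 41 | 52 | 4 | 8 |
| 4 | 45 | 54 | 5 | 8 |
| 5 | 45 | 53 | 2 | 7 |

```
hofstee --scores class.csv \
  --judge 50,60,1,4 --judge 44,56,3,8 --judge 41,52,4,8 \
  --judge 45,54,5,8 --judge 45,53,2,7 \
  --chart both --out results/
```

prints

```
students: 181 (scores 43-97)
parameters (mean): c_min=45 c_max=55 f_min=3 f_max=7
Hofstee cut-off: 53.80 (expected fail 3.48%)
gap: 51-53.5 (width 2.5)
gap: 45-47 (width 2)
gap: 47-49 (width 2)
```

Line by line: the panel means give AB from (45, 7) to (55, 3); that line
crosses the cumulative curve at score 53.80, where 3.48% of the class sits
at or below — inside every judge's bounds, so 53.80 is the compromise pass
mark. The gap lines say no student scored strictly between 51 and 53.5,
so the cut sits in empty territory and no student is a rounding error away
from the boundary. `results/` receives the JSON document
(`hofstee_result.json`, full precision) and the two charts.

Pre-aggregated parameters can be entered directly — `--params 35,45,6,18`
— and `hofstee synth --n 1000 --seed 42 --out fixture.csv` writes a
reproducible uniform-random score fixture for trying the tool out.

As a library:

```python
from hofstee import (JudgePanel, aggregate_panel, read_scores,
                     build_cumulative_curve, compute_cutoff)

panel = JudgePanel.from_quadruples([(50,60,1,4), (44,56,3,8), (41,52,4,8),
                                    (45,54,5,8), (45,53,2,7)])
params = aggregate_panel(panel, "mean")
curve = build_cumulative_curve(read_scores("class.csv"))
result = compute_cutoff(curve, params)
print(result.display_cutoff)   # 53.8
```

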