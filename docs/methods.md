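# Methods

## The Hofstee compromise

Standard setting for a pass/fail examination can be criterion-referenced
(judges fix an absolute cut score) or norm-referenced (a fixed fraction of
the cohort fails). The Hofstee method interpolates between the two. Each
judge answers four questions:

| parameter | meaning | axis |
|---|---|---|
| `c_min` | lowest acceptable cut score | score, % (0–100) |
| `c_max` | highest acceptable cut score | score, % (0–100) |
| `f_min` | lowest acceptable failure rate | % of students (0–100) |
| `f_max` | highest acceptable failure rate | % of students (0–100) |

The panel's estimates are aggregated per parameter (arithmetic mean by
default; median available). On a chart of cumulative percentage of
students against score, the line **AB** is drawn from A = (`c_min`,
`f_max`) to B = (`c_max`, `f_min`). The cut score is where AB crosses the
cohort's cumulative curve: if many students would fail at `c_max`, the
crossing slides toward lower scores; if few would fail at `c_min`, it
slides up.

## Cumulative-curve convention

The curve has one vertex per distinct observed score `v`, at

```
y(v) = 100 · #{scores ≤ v} / n ,
```

with consecutive vertices joined by straight segments. This "at or below"
rank convention is load-bearing: for a 181-student cohort whose 6th and
7th ascending scores are 53.5 and 54.5 it puts vertices at
(53.5, 3.3149…) and (54.5, 3.8674…) — i.e. (53.5, 3.31)/(54.5, 3.87) at
the 2-dp display precision a practitioner reads off the chart — and the
resulting cut-off matches hand-verified worked examples to the printed
precision. Midpoint percentile conventions such as `100·(k−0.5)/n` are
deliberately not offered because they would move every vertex and hence
the cut score.

No synthetic (0, 0) origin vertex is prepended; the curve starts at the
minimum observed score. A crossing below the minimum score therefore
cannot occur and is reported as a no-intersection diagnostic instead.

## The algebraic cut-off scan

The cumulative curve has no closed-form equation, but each of its segments
does. The scan walks the segments in ascending score order and solves each
segment's supporting line against AB with the standard parametric
2-D segment intersection (cross-product form). A candidate is accepted
when it lies within the segment's x-range *and* on AB as a closed segment
— an intersection beyond A or B is not a compromise between the judges'
bounds. Because AB is non-increasing (`f_max ≥ f_min`) and the curve is
strictly increasing across vertices, the difference curve−AB is strictly
monotone wherever AB has negative slope, so at most one crossing exists;
the first accepted candidate is the answer. When the crossing lands
exactly on a shared vertex, both adjacent segments produce the identical
point and the scan's "first segment wins" rule is immaterial.

Numerical choices:

- Membership tests use an absolute tolerance of `1e-9` so a
  vertex-coincident crossing is not lost to floating-point rounding.
- Collinear overlap (possible only with a horizontal AB, `f_min = f_max`)
  returns the smallest-x point of the overlap: the lowest passing standard
  consistent with the judgement.
- Vertical AB (`c_min = c_max`) needs no special case in the scan; the
  parametric form yields the cut at `c_min` with the curve's value there,
  provided it falls inside `[f_min, f_max]`.
- A fully degenerate AB (both pairs equal) is rejected as input.
- Display rounding is two decimal places, half away from zero, applied
  only at the presentation layer; all arithmetic and the JSON output keep
  full double precision.

When no crossing exists the package fails loudly with a directional
diagnostic — the curve sits entirely above AB (more students would fail
than `f_max` allows; revisit `f_max`/`c_min`) or entirely below (fewer
than `f_min`; revisit `f_min`/`c_max`). A cohort whose scores fall wholly
outside `[c_min, c_max]` is classified the same way (all above the window
⇒ 0% failing ⇒ "below", and vice versa). An optional corner fallback
(`--fallback corner`) substitutes the AB endpoint nearest the curve in
y-distance, a convention some practitioners use; it is off by default
because a silent substitute is not a compromise the judges agreed to.

## Judge aggregation

- Mean: `statistics.fmean` per parameter. Median: `statistics.median`,
  with an even-sized panel taking the mean of the two middle values (the
  dominant convention; the method itself is silent).
- Spread is reported as the sample standard deviation (n−1 denominator),
  treating the panel as a sample from a population of possible judges; a
  single-judge panel reports 0.
- Both aggregates preserve `c_min ≤ c_max` and `f_min ≤ f_max` whenever
  every judge satisfies them, so aggregation cannot produce an invalid
  line; estimates are validated per judge *and* the aggregate is
  re-validated, and the error message names which level failed.
- The library accepts any panel size ≥ 1; the CLI warns above 10 judges
  (a practical panel-size convention, not a constraint of the method).

## Score ingestion and the synthetic generator

Scores are percentages in `[0, 100]`; out-of-range values are an error
rather than a clipped warning because both chart axes are percentage axes
and silent clipping would corrupt the cut-off. Input is comma-delimited,
point-decimal CSV; only the first column is read; exactly one leading
non-numeric row is tolerated as a header (gradebook exports usually carry
one); duplicates are retained since they shape the curve; sorting is
automatic.

`generate_synthetic_scores(n, low, high, seed)` draws n integers uniformly
with replacement from `[low, high]` — the spreadsheet-RANDBETWEEN-style
fixture, defaulting to 1000 draws from 1–100. A flat cohort is a useful
stress case (near-linear curve, crossings possible over a wide window),
but it lacks the features of real cohorts: unimodality, left skew, tied
half-point clusters. Passing tests on it therefore demonstrate the
geometry and the plumbing, not distributional realism; the worked-example
cohorts in the test suite are constructed to contain the exact published
curve segments instead.

## Data gaps

A cut placed inside a wide empty score interval is easier to defend
(nobody sits at the boundary). `find_gaps` reports the `top_k` (default 3)
widest intervals between adjacent distinct scores whose endpoints both lie
in a window — default `[c_min, c_max]`, the region the detailed chart
covers, since "vicinity of the cut-off" is otherwise unspecified. Ties
break by lower score ascending. The report is advisory; the cut-off is
never moved automatically.

## Charts and CLI

The full chart spans the data; the detailed chart spans
`[c_min − m, c_max + m]` with margin `m` = 10% of `c_max − c_min` (our
choice of "close to the range of the parameters"; floor of one score
point when the span is zero). Rendering is a pure sink and never feeds
back into the numbers. The CLI maps error classes to distinct exit codes
(3 input, 4 validation, 5 no-intersection) and writes a deterministic,
sorted-key JSON result document; re-running on identical inputs yields
byte-identical JSON. Judge parameters can also come from a JSON config
file (`{"judges": [[c_min,c_max,f_min,f_max], …], "params": […],
"method": "mean"}`); flags override the config, and a direct `--params`
quadruple overrides judges.

## Problem sizes used in the tests

Worked examples use cohorts of 100 and 181 students; the oracle
comparison in the acceptance suite runs 500 random cohort/parameter
configurations (20–300 students each) against a dense-grid (step 1e-4)
sign-change oracle refined by bisection, agreeing within 1e-6 on the
cut score. The generator convergence check uses 10,000 draws.

## Known limitations

- No alternative compromise methods (Beuk, Cohen) and no closed-form
  frequency formulation; the segment scan is the implemented method.
- No confidence intervals on the cut score and no inter-rater statistics
  beyond per-parameter SD.
- No Excel ingestion, rescaling, or multi-cohort batching.
- Ties in the cohort at the cut score itself are not flagged beyond the
  gap report.
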