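# Methods

`statrigor` implements a meta-research audit of statistical rigor in
clinical publications: articles are hand-coded into categorical checklist
responses, scored on a five-domain weighted checklist, classified by error
severity, and the resulting classification is tested for association with
article characteristics. The package also ships a calibrated synthetic
corpus generator so that every stage is exercisable and testable without
access to the underlying hand-coded article data, which are not public.

## The scoring model

Each appraised article receives five domain scores:

| Domain | What it measures | Values | Weight |
|---|---|---|---|
| 1 | test selection matched to design/variables | 0, 1 | 0.35 |
| 2 | sample-size calculation reported | 0, 1 | 0.15 |
| 3 | assumption testing (independence, normality, homogeneity) | 0, 0.5, 1 | 0.35 |
| 4 | examiner calibration reported and appropriate | 0, 1 | 0.05 |
| 5 | interpretation/reporting quality | 0, 0.5, 1 | 0.10 |

Domain 3 scores 0 when independence of observations is violated, 1 when
independence is maintained and every assumption the primary test requires
was tested and satisfied (vacuously so for non-parametric tests, which
require only independence), and 0.5 otherwise (unclear independence, or
required normality/homogeneity checks missing).

Domain 5 is a five-item raw sum in [0, 5]: p-values reported (1),
confidence intervals (1 reported-and-interpreted / 0.5 reported-only / 0
absent), non-significant results discussed (1 fully / 0.5 briefly),
limitations discussed (1), assumption violations acknowledged (1). Raw ≥ 3
maps to 1, raw in [2, 3) to 0.5, raw < 2 to 0.

The composite is the weighted sum `0.35·d1 + 0.15·d2 + 0.35·d3 + 0.05·d4 +
0.10·d5` and the classification rules are:

* **major error** — d1 = 0, or d3 = 0, or composite < 0.60;
* **no major error** — composite ≥ 0.80, or d1 = d3 = 1 with composite ≥ 0.70;
* **minor error** — the residual (a 0.5 critical-domain score or a
  composite in [0.60, 0.80) not meeting the no-major criteria).

Rule precedence is major → no-major → minor. The only point on the
36-point reachable score grid where the precedence matters is
(d1 = 1, d3 = 0.5, composite = 0.825): the composite-≥-0.80 clause and the
"critical domain at 0.5 → minor" reading conflict, and we resolve it in
favor of the explicit composite threshold, i.e. no major error. All
threshold comparisons carry a 1e-9 tolerance because the composite is a
floating-point sum. With the default weights a zero in either critical
domain caps the composite at 0.65, so such articles are always major — the
classification is monotone in every single domain score (verified by
enumeration in the test suite).

## Sampling frame and precision

`stratified_sample` models a 20% feasibility sample: within each
journal-by-year stratum, entries get fresh uniform random keys from a
seeded generator, are sorted ascending, and the top
`max(1, round_half_up(fraction · n_stratum))` are taken. The floor of one
guarantees every journal-year remains represented; per-stratum counts are
a function of stratum sizes alone. `margin_of_error` is the standard
`z·sqrt(p(1−p)/n)` with `z = 1.96` and no finite-population correction. At
maximum variability (p = 0.5) and n = 119 this evaluates to 0.0898; the
formula reaches 0.082 only near n = 143.

## Inference layer

* **Goodness of fit** and **independence** use Pearson chi-square with no
  continuity correction (scipy's implementations behind the package
  surface). Zero margins are rejected with the offending level named.
* **Monte Carlo exact p-values** are computed when more than 20% of
  expected cell counts fall below 5 (strict inequality). The null scheme
  fixes row margins and redraws each row as a multinomial over the pooled
  column proportions; the Pearson statistic is recomputed on every
  simulated table from that table's own margins, which preserves the
  (r−1)(c−1)-df null distribution. An empty simulated column contributes
  zero (the degenerate-table convention). The estimator is add-one,
  `(1 + #{T ≥ T_obs}) / (R + 1)`, so p is never zero. For 2×2 tables with
  small margins the discrete conditional null departs visibly from the
  chi-square approximation; the Monte Carlo p then tracks exact
  enumeration, not the asymptotic value — this is by design.
* **Cramér's V** is `sqrt(χ² / (n·(min(r,c)−1)))`. Its 95% CI is a
  percentile bootstrap: resample records with replacement n-from-n,
  recompute V, take the 2.5/97.5 percentiles (default 1000 replicates).
  Replicates that collapse an axis below two observed levels are redrawn
  by default; `collapse="zero"` scores them as V = 0 instead.
* **Effect-size labels** follow Cohen's thresholds with left-closed bins:
  negligible < 0.1 ≤ small < 0.3 ≤ medium < 0.5 ≤ large.
* **Cohen's kappa** is the unweighted chance-corrected agreement; when
  both raters are constant with identical marginals (chance agreement 1)
  the statistic is undefined and returned as NaN.

Association rows cross each factor (journal, year, statistician
involvement, continent, or a domain score) with the three-level outcome;
the significance flag always follows the reported p-value (Monte Carlo
when triggered, asymptotic otherwise).

## The synthetic corpus generator

The generator's defaults encode the audited corpus' published category
frequencies out of n = 119 — e.g. journals 25/37/57, statistician
involvement 19/119, appropriate test-variable match 105/119, independence
violated/maintained/unclear 30/78/11, confidence intervals 99/11/9 — plus
the two structural facts the audit reports:

* every statistician-involved article selected appropriate tests
  (`p_match_given_statistician = 1`, so the (statistician, inappropriate)
  cell is empty by construction; articles without statistician involvement
  match with probability 86/100, reproducing the overall 105/119);
* the outcome classification is **derived** by scoring each generated
  record, never sampled, so the strong Domain-1/Domain-3 ↔ outcome
  associations arise structurally. On a 5000-article corpus the
  Domain-3/outcome Cramér's V exceeds 0.5 ("large").

Fields are otherwise sampled independently given the structural
constraints (normality/homogeneity statuses are drawn conditionally on
whether the primary test is parametric, 57/119 by default; calibration
quality conditionally on calibration being mentioned, 33 appropriate of
48). The published joint distribution is not available, so the generator
makes no attempt to match joint cell counts beyond the stated couplings —
in particular, the generated outcome proportions at n = 119 fluctuate
around ~35–40% major rather than landing on the audited 44.5/21.0/34.5
split, because that split reflects joint structure the marginals do not
pin down. The overall assumption-testing status is likewise derived from
the Domain-3 rule rather than sampled, which reproduces 30 "not met"
rather than the published 31 — the published item-level and overall counts
are not exactly reconcilable under any deterministic rule, and internal
consistency wins. p-values-reported defaults to probability 1, matching
the report that all audited studies gave p-values (the published frequency
column for that row is internally inconsistent with n = 119 and is not
reproduced).

All draws flow through one seeded `numpy` generator: corpora are
bit-reproducible, and two pipeline runs with the same seed emit
byte-identical CSVs.

## Reporting conventions

Percentages are rounded half-up to one decimal, computed as
`100·count/N` with N the variable's applicable denominator (calibration
quality is tabulated over the subset that mentions calibration). The
major-error decomposition partitions major-error articles strictly into
test-selection-only, assumption-handling-only, and both; majors arising
from a composite below 0.60 with neither critical domain at zero go to an
explicit residual bucket rather than being silently misassigned. Reports
are plain CSV/JSON data tables; no figure rendering.

## Problem sizes and numerical choices

The test suite validates the Monte Carlo machinery at 10⁵ replicates
against the asymptotic p (well-filled 3×3 table) and against exact
enumeration over all 2×2 tables with row margins (6, 6); type-I error is
checked over 2000 null 3×3 tables at n = 119; generator marginal recovery
is checked at n = 5000 within 3 binomial standard deviations. Default
pipeline settings are 10⁴ Monte Carlo replicates and 10³ bootstrap
replicates per association row. The whole suite runs in a few seconds on
one CPU.

## Limitations

* The generator emulates marginals and stated couplings only; real
  hand-coded corpora carry joint dependencies (e.g. journal-specific
  reporting cultures) that it does not model, so passing tests demonstrate
  pipeline correctness, not that the generator mimics real audit data in
  distribution.
* Published association effect sizes and the inter-rater kappa depend on
  article-level data that were never released; the package pins those
  statistics at the formula level (hand-computable cross-tables, exact
  enumeration) rather than attempting to reproduce their published values.
* Scoring consumes human-coded categories; the package performs no reading
  or judgment of manuscripts.
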