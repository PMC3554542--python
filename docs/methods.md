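# Methods

## Model

`adaptrand` allocates sequentially arriving participants to `k ≥ 2`
treatment groups with target ratio `r_1 : … : r_k`, recomputing the
allocation probabilities for every participant from the imbalance already
accumulated at three levels: the whole trial, the participant's level of
each stratification variable, and the participant's stratum. A stratum is
one cell of the full cross-classification of all declared variables
(e.g. female × center Z); variables must be discrete — continuous
covariates such as age are banded before they enter the specification.

For a two-group comparison with odds `odds = r_A / r_B`, the imbalance at
a level with counts `(n_A, n_B)` is

```
d = (odds · n_B − n_A) / odds
```

and the total imbalance is the weighted signed-squared sum over the
relevant levels

```
a = Σ_level  w_level · sign(x) · x² / odds ,   x = odds · n_B − n_A ,
```

fed through the odds-offset logistic

```
p(A) = odds · e^a / (1 + odds · e^a) .
```

The per-level term equals `w · sign(d) · odds · d²`. A literal squaring
of `d` itself (`w · sign(d) · d²`) is available as
`term_form="plain"`; the two coincide whenever the odds are 1, i.e. for
every equal-allocation trial. The odds-scaled form is the package
default because it is the form whose arithmetic the method's published
worked example follows; the plain form is kept for sensitivity analyses.

**Sign convention.** Positive `a` means group A is underrepresented and
raises `p(A)`. The uniform draw is compared against cumulative
boundaries that are half-open and lower-inclusive: `u < p(A)` assigns A.

**More than two groups.** The probability of each group `g` is computed
one-vs-rest: its odds against all remaining groups pooled are
`odds_g = r_g / (R − r_g)` with `R = Σ r_i`, the pooled counts of the
other groups play the role of `n_B`, and steps 2–4 proceed unchanged.
The `k` one-vs-rest probabilities are then renormalized to sum to 1. At
`k = 2` the two one-vs-rest probabilities are already exactly
complementary (an algebraic identity, property-tested), so the
construction reduces to the base method; at zero imbalance every group
receives exactly `r_g / R`. The published description asserts the
four-step scheme covers any number of groups without writing the
`k`-group formula, so this construction is the package's design choice;
its three-group production configuration is therefore checked only
structurally, not against printed probabilities.

## Weights

Weights are non-negative reals fixed for the whole trial (the method is
covariate-adaptive, never outcome-adaptive). Conventionally the stratum
weight is largest, variable weights intermediate and the overall weight
smallest, because the stratum counts are smallest and imbalance there is
both likelier and more damaging. Two limits anchor the scale:

* all weights 0 — simple randomization, `p_g = r_g / R` exactly, every
  time (tested as exact equality);
* all weights 10 on an unstratified 1:1 trial — effectively permuted
  blocks of two: once the counts differ by one, the overrepresented
  group's probability is below 10⁻⁴, so consecutive non-overlapping
  pairs virtually always contain one of each group. With stratification
  variables present, weights of 10 still leave a few percent of
  replicates off the exact final split, because stratum-level and
  overall-level corrections can pull in opposite directions.

The bundled fixtures record the weight sets used in practice: the four
simulation scenarios (strong 1/2/2/5, medium 0.1/0.2/0.2/0.5, weak
0.01/0.02/0.02/0.05, zero) and the three production set-ups (FolATED
1:1 with four variables; EPIC 2:1; SWAD 2:2:1 with three groups).

## Numerical choices

* Odds are exact rationals (`fractions.Fraction`), and every difference
  and term is evaluated from the integer `x = p·n_B − q·n_A` (odds
  `p/q`), so a balanced level yields exactly zero — no floating-point
  dust decides a sign, which matters because the strong-weight scenarios
  produce integer imbalance totals whose probability values populate a
  strictly discrete set (four histogram intervals are structurally
  unreachable, and the tests assert exact zeros there).
* The logit exponent is clamped at ±700 before exponentiation; beyond
  that the probability saturates at 0/1 in double precision anyway.
* Probabilities must sum to 1 within 1e−12; the last cumulative boundary
  is pinned to exactly 1.0.
* Comparisons against published two-decimal values round to the printed
  precision.

## State, log and replay

The engine's running state (counts at every touched level key) is a
cache: the durable record is the CSV allocation log, one row per
participant with the stratification levels, the full-precision
probabilities, the uniform draw and the assignment. `replay` rebuilds
the state by re-running the engine over the log, re-deriving each
assignment from the recorded draw and failing loudly on any divergence —
a tampered group or probability column is detected, not trusted.
Participant ids are unique; re-randomization is refused at both the
library and CLI layers. Timestamps are recorded in UTC ISO-8601 and
excluded from replay equality. The functional
`allocate_participant` never mutates its input state; the `Randomizer`
session object and the simulator use an in-place fast path whose
equivalence to the functional path is tested record-by-record.

## The simulator

`simulate_trial` draws each participant's levels independently across
variables from a `CovariateModel` (uniform over levels by default — the
neutral choice when the covariate mix of the future trial is unknown)
and allocates them sequentially; `simulate_batch` runs replicates on
substreams spawned from one master seed, so any replicate is
reproducible in isolation. `summarize` produces the standard
pre-recruitment diagnostics: final-split counts, per-level end-of-trial
differences (first group minus second), the per-replicate maximum
same-group run length, a histogram of every computed boundary on the
intervals `[0, 0.05], (0.05, 0.15], …, (0.95, 1]`, and the split at an
interim checkpoint. Conservation invariants (each histogram's total
against replicates × cells) are asserted on every run.

What the i.i.d. covariate model does not emulate: real recruitment
streams are neither independent nor stationary — centers open late,
cohorts arrive in blocks (the three-group production trial recruited in
six sequential cohorts), and covariate mixes drift. Passing simulation
checks therefore demonstrate the engine's balancing behavior under a
neutral participant stream, not a forecast for any particular trial.
The standard study size used throughout the diagnostics and the
acceptance run — 1,000 replicates of 50 participants, with 1,000
replicates of 549 for the equal-allocation production fixture — matches
the published simulation study it is compared against; sampling error at
that size is what the ±3 binomial-SE test tolerances encode.

## Open design points resolved

* The published Step-3 prose ("square the differences") conflicts with
  its own worked totals, which follow the odds-scaled form; the package
  implements the arithmetic-consistent form by default (see above).
* The published probability for the ×10-strengthened example (0.0000167)
  is inconsistent with the published Step-4 formula, which gives
  2e⁻¹¹/(1+2e⁻¹¹) ≈ 3.34×10⁻⁵; the printed value equals the formula
  with the odds factor omitted from the numerator. The package
  implements the formula and treats the printed number as a misprint.
* The 2:1 production fixture weights its center variable without stating
  the number of centers; the fixture takes the center count as a
  parameter (default 4, a typical multi-center scale) and its published
  probabilities are treated as soft checks only.

## Limitations

* No outcome-adaptive (response-driven) reweighting; weights are fixed
  at design time.
* Continuous stratification variables must be pre-discretized.
* The web-service deployment layer (authentication, email intake,
  blinding workflow beyond the `--blind` token) is out of scope; the CLI
  plus log is the operational surface.
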