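# adaptrand

Covariate-adaptive (dynamic) randomization for sequential clinical trials:
an allocation engine, an auditable randomization log with a command-line
interface, and a seeded simulator for choosing imbalance weights before
recruitment starts.

## The problem

Trials that recruit participants one at a time need an allocation method
that is unpredictable (so assessors cannot anticipate the next assignment)
yet keeps the treatment arms balanced — not only overall, but within each
stratification variable (center, gender, ...) and within every stratum
(each cell of the full cross-classification). Simple randomization is
maximally unpredictable but can drift badly out of balance, especially in
small trials and small strata; deterministic schemes are balanced but
guessable. `adaptrand` implements a minimization-style compromise that
controls imbalance at all three levels simultaneously through a single
weighted function, for two or more groups and arbitrary allocation ratios.

## The algorithm

For each arriving participant, with target ratio *A*:*B*:

1. **Odds.** Compute the allocation odds `odds = r_A / r_B` (a 2:1 ratio
   gives odds 2).
2. **Differences.** At every relevant level — overall, the participant's
   level of each stratification variable, and the participant's stratum —
   compute `d = (odds · n_B − n_A) / odds` from the counts already
   allocated. Positive `d` means A is underrepresented there.
3. **Total imbalance.** Form the weighted signed-squared sum
   `a = Σ w · sign(odds·n_B − n_A) · (odds·n_B − n_A)² / odds`, one term
   per level, with non-negative weights chosen per trial (largest for the
   stratum, smallest for the overall level, as stratum counts are the
   smallest and most fragile).
4. **Probability.** Assign to A with probability
   `p(A) = odds · e^a / (1 + odds · e^a)`, and draw a uniform number
   against the resulting boundary.

With all weights 0 this is exactly simple randomization at the ratio
proportions; with very large weights it mimics permuted blocks of size
two. For *k* > 2 groups each group's probability is computed one-vs-rest
(`odds_g = r_g / (R − r_g)`, all other groups pooled) and the *k* results
renormalized; at *k* = 2 this reduces exactly to the base method.

## Worked example

A 2:1 two-group trial stratified by gender (M/F) and center (X/Y/Z), with
weights 0.1 overall, 0.2 per variable, 0.5 stratum. Twelve participants
are already allocated (8:4 overall, but stratum F×Z stands at 2:0 and
center Z at 3:1). The 13th arrival is female, from center Z:

```python
from adaptrand import ParticipantProfile, group_probabilities, total_imbalance
from adaptrand.fixtures import example_spec, example_table_state

spec = example_spec()
state = example_table_state(spec)
p13 = ParticipantProfile({"gender": "F", "center": "Z"})

print(total_imbalance(p13, state, spec).total)
print(group_probabilities(p13, state, spec).probabilities)
```

prints

```
-1.1
(0.39966699554519197, 0.6003330044548081)
```

The negative total imbalance (−1.1) says A is overrepresented at the
levels relevant to this participant, so her probability of assignment to
A drops from the neutral 2/3 to 0.40 — the boundary has shifted toward B
to repair the stratum and center imbalances. Scaling all weights by 10
gives total −11 and p(A) ≈ 3×10⁻⁵ (near-deterministic correction);
scaling by 1/10 gives −0.11 and p(A) = 0.64 (barely different from
simple randomization).

## Command line

```sh
adaptrand init --out trial.yaml            # template configuration
adaptrand randomize --config trial.yaml --log log.csv \
    --id P001 --var gender=F --var center=Z
adaptrand report --config trial.yaml --log log.csv
adaptrand simulate --config trial.yaml --n 50 --replicates 1000 \
    --seed 7 --checkpoint 12 --out sim/
```

`randomize` appends to a CSV log holding, per participant, the
probabilities in force, the uniform draw and the assignment; the running
state is always rebuilt by replaying the log through the engine, which
re-derives and verifies every recorded assignment. A participant id can
only ever be randomized once. `--blind` prints a confirmation token
instead of the group. `simulate` writes the diagnostic tables (final
splits, within-level imbalances, run lengths, boundary histogram, interim
splits) used to choose weights before recruitment.

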