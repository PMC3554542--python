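"""Seeded synthetic-trial engine and pre-recruitment diagnostics.

Before a trial starts, the weights of the allocation algorithm are chosen
by simulating the whole randomization many times: a stream of synthetic
participants is drawn from a covariate model, allocated sequentially by the
engine, and the replicated trials are summarized by

* the distribution of final overall splits,
* the end-of-trial allocation difference within each stratification
  variable's levels,
* the longest run of consecutive same-group allocations per replicate
  (a predictability diagnostic),
* a histogram of every allocation probability computed along the way
  (boundaries pinned near 0 or 1 mean the next assignment is guessable),
* the overall split at an interim checkpoint.

Replicates are seeded from one master seed via spawned substreams, so any
single replicate can be reproduced in isolation.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from itertools import groupby
from typing import Mapping, Sequence

import numpy as np

from .core import (
    AllocationRecord,
    AllocationState,
    ParticipantProfile,
    TrialSpec,
    ValidationError,
    _EXP_CLAMP,
)

__all__ = [
    "CovariateModel",
    "TrialResult",
    "SimulationSummary",
    "generate_profile",
    "simulate_trial",
    "simulate_batch",
    "max_run_length",
    "summarize",
    "BOUNDARY_EDGES",
    "BOUNDARY_LABELS",
]

#: Bin edges for the boundary histogram: [0, 0.05] closed, then
#: (0.05, 0.15], (0.15, 0.25], ... (0.95, 1] half-open on the left.
BOUNDARY_EDGES = (0.0, 0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85, 0.95, 1.0)
BOUNDARY_LABELS = ("[0, 0.05]",) + tuple(
    f"({BOUNDARY_EDGES[i]:g}, {BOUNDARY_EDGES[i + 1]:g}]" for i in range(1, 11)
)


def boundary_bin(p: float) -> int:
    """Index of the histogram interval containing probability ``p``."""
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"probability {p} outside [0, 1]")
    return max(bisect_left(BOUNDARY_EDGES, p) - 1, 0)


@dataclass(frozen=True)
class CovariateModel:
    """Per-variable level probabilities for synthetic participants.

    Levels are sampled independently across variables.  The default
    (:meth:`uniform`) puts equal mass on every level, the simplest neutral
    assumption when the covariate mix of the future trial is unknown.
    """

    probabilities: Mapping[str, tuple[float, ...]]

    def __post_init__(self):
        object.__setattr__(
            self, "probabilities", {k: tuple(v) for k, v in self.probabilities.items()}
        )
        for name, probs in self.probabilities.items():
            if any(p < 0 for p in probs):
                raise ValidationError(f"negative probability for variable {name!r}")
            if abs(math.fsum(probs) - 1.0) > 1e-12:
                raise ValidationError(f"probabilities for {name!r} must sum to 1")

    @classmethod
    def uniform(cls, spec: TrialSpec) -> "CovariateModel":
        return cls({v.name: (1.0 / len(v.levels),) * len(v.levels) for v in spec.variables})

    def validate_for(self, spec: TrialSpec) -> None:
        for v in spec.variables:
            probs = self.probabilities.get(v.name)
            if probs is None:
                raise ValidationError(f"no probabilities for variable {v.name!r}")
            if len(probs) != len(v.levels):
                raise ValidationError(
                    f"variable {v.name!r} has {len(v.levels)} levels but "
                    f"{len(probs)} probabilities"
                )


def generate_profile(
    model: CovariateModel, rng: np.random.Generator, spec: TrialSpec
) -> ParticipantProfile:
    """Draw one synthetic participant from the covariate model."""
    values = {}
    for v in spec.variables:
        probs = model.probabilities[v.name]
        values[v.name] = v.levels[rng.choice(len(probs), p=probs)]
    return ParticipantProfile(values)


@dataclass
class TrialResult:
    """One simulated trial: final state, boundary trace and assignments."""

    spec: TrialSpec
    final_state: AllocationState
    boundaries: list[float]  # p(first group) at each allocation
    assignments: list[int]

    @property
    def final_split(self) -> tuple[int, ...]:
        return self.final_state.overall

    def split_after(self, checkpoint: int) -> tuple[int, ...]:
        """Overall counts after the first ``checkpoint`` allocations."""
        if not (0 < checkpoint <= len(self.assignments)):
            raise ValidationError(
                f"checkpoint {checkpoint} outside 1..{len(self.assignments)}"
            )
        counts = [0] * self.spec.n_groups
        for g in self.assignments[:checkpoint]:
            counts[g] += 1
        return tuple(counts)


def simulate_trial(
    spec: TrialSpec,
    n: int,
    model: CovariateModel | None = None,
    rng: np.random.Generator | int | None = None,
    *,
    profiles: Sequence[ParticipantProfile] | None = None,
    keep_records: bool = False,
) -> TrialResult:
    """Sequentially allocate ``n`` synthetic participants.

    Participants are drawn from ``model`` (uniform by default) unless an
    explicit ``profiles`` stream is given (then ``n`` may be omitted as
    ``len(profiles)``).  The loop is a lean re-statement of the engine's
    four steps; equivalence with :class:`adaptrand.core.Randomizer` on a
    shared draw stream is enforced by the test suite.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    # materialize the covariate stream first, then the assignment draws,
    # so the draw stream is identical however profiles were produced
    if profiles is None:
        model = model or CovariateModel.uniform(spec)
        model.validate_for(spec)
        level_idx = {
            v.name: rng.choice(
                len(v.levels), size=n, p=model.probabilities[v.name]
            )
            for v in spec.variables
        }
        profiles = [
            ParticipantProfile(
                {v.name: v.levels[level_idx[v.name][i]] for v in spec.variables}
            )
            for i in range(n)
        ]
    else:
        profiles = list(profiles)
        if len(profiles) != n:
            raise ValidationError("need exactly n profiles")
        for p in profiles:
            p.validate(spec)
    us = rng.random(n)

    k = spec.n_groups
    R = spec.ratio_total
    w = spec.weights
    weights = [w.overall] + [w.per_variable[v.name] for v in spec.variables] + [w.stratum]
    # one-vs-rest odds per group, as exact integer pairs
    odds = [Fraction(r, R - r) for r in spec.ratio]
    pq = [(o.numerator, o.denominator, float(o), 1.0 / (o.numerator * o.denominator)) for o in odds]

    counts: dict[tuple, list[int]] = {}
    state = AllocationState(spec)
    state._counts = counts
    boundaries: list[float] = []
    assignments: list[int] = []
    exp = math.exp

    for i in range(n):
        profile = profiles[i]
        keys = profile.level_keys(spec)
        probs = []
        for g in range(1 if k == 2 else k):
            pnum, qden, odds_f, inv_pq = pq[g]
            a = 0.0
            for key, weight in zip(keys, weights):
                c = counts.get(key)
                if c is not None and weight:
                    n_a = c[g]
                    x = pnum * (sum(c) - n_a) - qden * n_a
                    if x:
                        a += weight * (x * x) * inv_pq * (1.0 if x > 0 else -1.0)
            t = odds_f * exp(min(max(a, -_EXP_CLAMP), _EXP_CLAMP))
            probs.append(t / (1.0 + t))
        if k == 2:
            p_first = probs[0]
            g = 0 if us[i] < p_first else 1
            prob_tuple = (p_first, 1.0 - p_first)
        else:
            s = math.fsum(probs)
            prob_tuple = tuple(x / s for x in probs)
            p_first = prob_tuple[0]
            cum = 0.0
            g = k - 1
            for j in range(k):
                cum += prob_tuple[j]
                if us[i] < cum:
                    g = j
                    break
        for key in keys:
            c = counts.get(key)
            if c is None:
                c = counts[key] = [0] * k
            c[g] += 1
        boundaries.append(p_first)
        assignments.append(g)
        if keep_records:
            state.sequence.append(
                AllocationRecord(
                    sequence=i + 1,
                    participant_id=f"S{i + 1:04d}",
                    profile=profile,
                    probabilities=prob_tuple,
                    u=float(us[i]),
                    group=g,
                )
            )

    return TrialResult(spec, state, boundaries, assignments)


def simulate_batch(
    spec: TrialSpec,
    n: int,
    replicates: int,
    model: CovariateModel | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> list[TrialResult]:
    """Run ``replicates`` independent trials from spawned substreams."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [
        simulate_trial(spec, n, model, np.random.default_rng(child))
        for child in ss.spawn(replicates)
    ]


def max_run_length(assignments: Sequence[int]) -> int:
    """Length of the longest block of consecutive same-group allocations."""
    if len(assignments) == 0:
        raise ValidationError("assignment sequence is empty")
    return max(len(list(block)) for _, block in groupby(assignments))


@dataclass
class SimulationSummary:
    """Distributional diagnostics over a batch of simulated trials."""

    spec: TrialSpec
    n_replicates: int
    n_participants: int
    final_splits: Counter  # final overall count tuple -> replicates
    level_differences: dict[str, Counter]  # variable -> (first-second diff -> obs)
    run_lengths: Counter  # max same-group run length -> replicates
    boundary_histogram: Counter  # interval index -> boundary count
    checkpoint: int | None = None
    interim_splits: Counter | None = None  # split at checkpoint -> replicates

    def validate(self) -> None:
        reps, n = self.n_replicates, self.n_participants
        if sum(self.final_splits.values()) != reps:
            raise ValidationError("final-split counts must sum to the replicates")
        for v in self.spec.variables:
            total = sum(self.level_differences[v.name].values())
            if total != reps * len(v.levels):
                raise ValidationError(
                    f"level-difference histogram for {v.name!r} must have "
                    f"replicates x levels entries"
                )
        if sum(self.run_lengths.values()) != reps:
            raise ValidationError("run-length counts must sum to the replicates")
        if sum(self.boundary_histogram.values()) != reps * n:
            raise ValidationError(
                "boundary histogram must have replicates x participants entries"
            )
        if self.interim_splits is not None and sum(self.interim_splits.values()) != reps:
            raise ValidationError("interim-split counts must sum to the replicates")

    def boundary_counts(self) -> list[int]:
        """Boundary histogram as a list aligned with BOUNDARY_LABELS."""
        return [self.boundary_histogram.get(i, 0) for i in range(len(BOUNDARY_LABELS))]


def summarize(
    results: Sequence[TrialResult],
    spec: TrialSpec | None = None,
    checkpoint: int | None = None,
) -> SimulationSummary:
    """Aggregate a batch of replicates into the standard diagnostics.

    The within-level difference is (count in first group) - (count in
    second group) at trial end, one observation per replicate per level.
    """
    if not results:
        raise ValidationError("no results to summarize")
    spec = spec or results[0].spec
    n = len(results[0].assignments)
    for r in results:
        if r.spec is not spec and r.spec != spec:
            raise ValidationError("all replicates must share one spec")
        if len(r.assignments) != n:
            raise ValidationError("all replicates must share one trial size")
    if checkpoint is not None and not (0 < checkpoint <= n):
        raise ValidationError(f"checkpoint {checkpoint} outside 1..{n}")

    final_splits: Counter = Counter()
    level_diffs: dict[str, Counter] = {v.name: Counter() for v in spec.variables}
    run_lengths: Counter = Counter()
    boundary_hist: Counter = Counter()
    interim: Counter | None = Counter() if checkpoint is not None else None

    for r in results:
        final_splits[r.final_split] += 1
        run_lengths[max_run_length(r.assignments)] += 1
        for p in r.boundaries:
            boundary_hist[boundary_bin(p)] += 1
        for v in spec.variables:
            for lv in v.levels:
                c = r.final_state.counts(("level", v.name, lv))
                level_diffs[v.name][c[0] - c[1]] += 1
        if interim is not None:
            interim[r.split_after(checkpoint)] += 1

    summary = SimulationSummary(
        spec=spec,
        n_replicates=len(results),
        n_participants=n,
        final_splits=final_splits,
        level_differences=level_diffs,
        run_lengths=run_lengths,
        boundary_histogram=boundary_hist,
        checkpoint=checkpoint,
        interim_splits=interim,
    )
    summary.validate()
    return summary
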