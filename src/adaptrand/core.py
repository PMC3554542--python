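"""Sequential covariate-adaptive allocation engine.

The boundary between treatment groups is recomputed for every arriving
participant in four steps:

1. the allocation odds ``r_A / r_B`` from the target ratio ``A:B``;
2. a difference ``d = (odds * n_B - n_A) / odds`` at each relevant level
   (overall, the participant's level of each stratification variable, and
   the participant's stratum — the full cross-classification cell);
3. a weighted signed-squared sum of those differences, the total imbalance
   ``a``;
4. the allocation probability ``p(A) = odds * exp(a) / (1 + odds * exp(a))``.

Positive ``a`` means group A is underrepresented and raises ``p(A)``.  With
all weights zero the probabilities are the fixed ratio proportions (simple
randomization); with very large weights the method behaves like permuted
blocks of size two.

For more than two groups each group's probability is computed one-vs-rest
(its odds against all other groups pooled, ``odds_g = r_g / (R - r_g)``)
and the results renormalized; at two groups this reduces exactly to the
base two-group method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "OVERALL",
    "StratVariable",
    "WeightScheme",
    "TrialSpec",
    "ParticipantProfile",
    "AllocationState",
    "ImbalanceBreakdown",
    "ProbabilityBoundaries",
    "AllocationRecord",
    "Randomizer",
    "allocation_odds",
    "level_difference",
    "imbalance_term",
    "total_imbalance",
    "probability_from_imbalance",
    "group_probabilities",
    "draw_assignment",
    "allocate_participant",
]

#: Level key for the whole-trial (overall) count.
OVERALL = ("overall",)

#: Clamp for the exponent in the logit; beyond this the probability
#: saturates at 0 or 1 in double precision anyway.
_EXP_CLAMP = 700.0

_TOL = 1e-12


class SpecificationError(ValueError):
    """Invalid trial specification (groups, ratio, variables or weights)."""


class ValidationError(ValueError):
    """Invalid participant profile, state or draw for a given trial spec."""


def _sign(x) -> int:
    return (x > 0) - (x < 0)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StratVariable:
    """A discrete stratification variable: a name and its ordered levels."""

    name: str
    levels: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(self.levels))
        if len(self.levels) < 2:
            raise SpecificationError(
                f"variable {self.name!r} needs at least 2 levels, "
                f"got {len(self.levels)}"
            )
        if len(set(self.levels)) != len(self.levels):
            raise SpecificationError(f"variable {self.name!r} has duplicate levels")


@dataclass(frozen=True)
class WeightScheme:
    """Non-negative imbalance weights for each level of control.

    ``overall`` scales the whole-trial imbalance, ``per_variable`` the
    imbalance within each stratification variable (one entry per declared
    variable), and ``stratum`` the imbalance within the participant's
    cross-classification cell.  Larger weights correct imbalance harder at
    the cost of predictability.
    """

    overall: float
    per_variable: Mapping[str, float]
    stratum: float

    def __post_init__(self):
        object.__setattr__(self, "per_variable", dict(self.per_variable))
        for label, w in [("overall", self.overall), ("stratum", self.stratum)] + [
            (f"variable {v!r}", w) for v, w in self.per_variable.items()
        ]:
            if not (w >= 0):
                raise SpecificationError(f"weight for {label} must be >= 0, got {w}")

    def validate_for(self, variables: Sequence[StratVariable]) -> None:
        declared = {v.name for v in variables}
        missing = declared - set(self.per_variable)
        if missing:
            raise SpecificationError(f"missing weight for variable(s): {sorted(missing)}")
        extra = set(self.per_variable) - declared
        if extra:
            raise SpecificationError(f"weight given for undeclared variable(s): {sorted(extra)}")


@dataclass(frozen=True)
class TrialSpec:
    """Immutable definition of a trial's randomization set-up.

    Parameters
    ----------
    group_names
        Ordered treatment-group labels, ``k >= 2``.
    ratio
        Target allocation ratio, one positive integer per group
        (``2:1`` is ``(2, 1)``).
    variables
        The stratification variables, each with >= 2 discrete levels.
    weights
        The :class:`WeightScheme` controlling imbalance correction.
    """

    group_names: tuple[str, ...]
    ratio: tuple[int, ...]
    variables: tuple[StratVariable, ...] = ()
    weights: WeightScheme | None = None

    def __post_init__(self):
        object.__setattr__(self, "group_names", tuple(self.group_names))
        object.__setattr__(self, "ratio", tuple(int(r) for r in self.ratio))
        object.__setattr__(self, "variables", tuple(self.variables))
        if len(self.group_names) < 2:
            raise SpecificationError("need at least 2 treatment groups")
        if len(set(self.group_names)) != len(self.group_names):
            raise SpecificationError("group names must be unique")
        if len(self.ratio) != len(self.group_names):
            raise SpecificationError("ratio must have one entry per group")
        if any(r < 1 for r in self.ratio):
            raise SpecificationError("every ratio entry must be a positive integer")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SpecificationError("variable names must be unique")
        if self.weights is None:
            object.__setattr__(
                self,
                "weights",
                WeightScheme(0.0, {v.name: 0.0 for v in self.variables}, 0.0),
            )
        self.weights.validate_for(self.variables)

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    @property
    def ratio_total(self) -> int:
        return sum(self.ratio)

    def variable(self, name: str) -> StratVariable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)


@dataclass(frozen=True)
class ParticipantProfile:
    """One participant's levels of the trial's stratification variables."""

    values: Mapping[str, str]
    participant_id: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "values", dict(self.values))

    def validate(self, spec: TrialSpec) -> None:
        declared = {v.name for v in spec.variables}
        if set(self.values) != declared:
            raise ValidationError(
                f"profile must give exactly one value per declared variable; "
                f"got {sorted(self.values)}, declared {sorted(declared)}"
            )
        for v in spec.variables:
            if self.values[v.name] not in v.levels:
                raise ValidationError(
                    f"{self.values[v.name]!r} is not a level of variable {v.name!r}"
                )

    def stratum_key(self, spec: TrialSpec) -> tuple:
        return ("stratum",) + tuple(self.values[v.name] for v in spec.variables)

    def level_keys(self, spec: TrialSpec) -> list[tuple]:
        """The relevant level keys, in weight order: overall, each
        variable's level, then the stratum."""
        keys = [OVERALL]
        keys += [("level", v.name, self.values[v.name]) for v in spec.variables]
        keys.append(self.stratum_key(spec))
        return keys


@dataclass(frozen=True)
class AllocationRecord:
    """Audit record of a single allocation: what was known and drawn."""

    sequence: int
    participant_id: str
    profile: ParticipantProfile
    probabilities: tuple[float, ...]
    u: float
    group: int
    timestamp: str | None = None


class AllocationState:
    """Running allocation counts at every relevant level, plus the log.

    Counts are kept for the overall level, every (variable, level) pair
    and every occupied stratum; the full allocation sequence is retained
    so the counts are always reconstructible by replay.
    """

    def __init__(self, spec: TrialSpec):
        self.spec = spec
        self._counts: dict[tuple, list[int]] = {}
        self.sequence: list[AllocationRecord] = []

    def counts(self, key: tuple) -> Sequence[int]:
        """Per-group counts at a level key (zeros if never touched)."""
        c = self._counts.get(key)
        return tuple(c) if c is not None else (0,) * self.spec.n_groups

    @property
    def overall(self) -> tuple[int, ...]:
        return tuple(self.counts(OVERALL))

    @property
    def n_allocated(self) -> int:
        return len(self.sequence)

    def copy(self) -> "AllocationState":
        new = AllocationState(self.spec)
        new._counts = {k: list(v) for k, v in self._counts.items()}
        new.sequence = list(self.sequence)
        return new

    def apply(self, record: AllocationRecord) -> None:
        """Apply one allocation in place (engine-internal fast path)."""
        record.profile.validate(self.spec)
        k = self.spec.n_groups
        for key in record.profile.level_keys(self.spec):
            c = self._counts.get(key)
            if c is None:
                c = self._counts[key] = [0] * k
            c[record.group] += 1
        self.sequence.append(record)

    def assignments(self) -> list[int]:
        return [r.group for r in self.sequence]

    def validate_consistency(self) -> None:
        """Cross-tabulation consistency: each variable's level counts sum
        to the overall counts, and stratum counts sum to level counts."""
        spec = self.spec
        overall = self.counts(OVERALL)
        for v in spec.variables:
            for g in range(spec.n_groups):
                s = sum(self.counts(("level", v.name, lv))[g] for lv in v.levels)
                if s != overall[g]:
                    raise ValidationError(
                        f"counts of variable {v.name!r} do not sum to the "
                        f"overall count for group {spec.group_names[g]!r}"
                    )
        # stratum counts roll up to each variable-level count
        for vi, v in enumerate(spec.variables):
            roll: dict[tuple, list[int]] = {}
            for key, c in self._counts.items():
                if key[0] == "stratum":
                    lvl_key = ("level", v.name, key[1 + vi])
                    acc = roll.setdefault(lvl_key, [0] * spec.n_groups)
                    for g in range(spec.n_groups):
                        acc[g] += c[g]
            for lvl_key, acc in roll.items():
                if tuple(acc) != tuple(self.counts(lvl_key)):
                    raise ValidationError(f"stratum counts do not sum to {lvl_key}")


@dataclass(frozen=True)
class ImbalanceBreakdown:
    """Per-level imbalance terms and their total (the logit argument)."""

    terms: tuple[tuple[tuple, float, float], ...]  # (level key, d, weighted term)
    total: float

    def __post_init__(self):
        if abs(sum(t for _, _, t in self.terms) - self.total) > _TOL:
            raise ValidationError("breakdown total does not match its terms")


@dataclass(frozen=True)
class ProbabilityBoundaries:
    """Per-group allocation probabilities and the cumulative partition of
    [0, 1) against which the uniform draw is compared."""

    probabilities: tuple[float, ...]
    cumulative: tuple[float, ...]

    def __post_init__(self):
        p = self.probabilities
        if any(not (0.0 <= x <= 1.0) for x in p):
            raise ValidationError("probabilities must lie in [0, 1]")
        if abs(sum(p) - 1.0) > _TOL:
            raise ValidationError("probabilities must sum to 1")
        c = self.cumulative
        if any(c[i] > c[i + 1] + _TOL for i in range(len(c) - 1)) or abs(c[-1] - 1.0) > _TOL:
            raise ValidationError("cumulative boundaries must be non-decreasing and end at 1")


# ---------------------------------------------------------------------------
# The four steps
# ---------------------------------------------------------------------------


def allocation_odds(ratio_a: int, ratio_b: int) -> Fraction:
    """Step 1: the allocation odds ``ratio_a / ratio_b``, exactly.

    A 2:1 ratio in favor of A gives odds 2; 1:1 gives odds 1.
    """
    if ratio_a < 1 or ratio_b < 1:
        raise SpecificationError("ratio entries must be positive")
    return Fraction(int(ratio_a), int(ratio_b))


def level_difference(n_a: int, n_b: int, odds) -> float:
    """Step 2: ``d = (odds * n_b - n_a) / odds`` at one level.

    Positive when group A is underrepresented relative to the target odds.
    """
    if n_a < 0 or n_b < 0:
        raise ValidationError("counts must be non-negative")
    odds = Fraction(odds)
    # (p*n_b - q*n_a)/q / (p/q) = (p*n_b - q*n_a)/p  -- exact in integers
    return (odds.numerator * n_b - odds.denominator * n_a) / odds.numerator


def imbalance_term(
    weight: float, n_a: int, n_b: int, odds, *, term_form: str = "odds-scaled"
) -> float:
    """Step 3 (one level): the weighted signed squared difference.

    The default ``"odds-scaled"`` form is
    ``w * sign(x) * x**2 / odds`` with ``x = odds*n_b - n_a``, which equals
    ``w * sign(d) * odds * d**2`` — the form the worked arithmetic of the
    method uses.  ``term_form="plain"`` gives ``w * sign(d) * d**2``
    (squaring the Step-2 difference literally); the two coincide at odds 1.
    """
    if n_a < 0 or n_b < 0:
        raise ValidationError("counts must be non-negative")
    if weight < 0:
        raise SpecificationError("weight must be >= 0")
    odds = Fraction(odds)
    p, q = odds.numerator, odds.denominator
    x = p * n_b - q * n_a  # q * (odds*n_b - n_a), exact
    if term_form == "odds-scaled":
        return weight * _sign(x) * (x * x) / (q * p)
    if term_form == "plain":
        return weight * _sign(x) * (x * x) / (p * p)
    raise ValueError(f"unknown term_form {term_form!r}")


def total_imbalance(
    profile: ParticipantProfile,
    state: AllocationState,
    spec: TrialSpec,
    group_pair: tuple[int, int] = (0, 1),
    *,
    term_form: str = "odds-scaled",
) -> ImbalanceBreakdown:
    """Step 3: sum the per-level terms into the total imbalance ``a``.

    One term for the overall level, one per stratification variable at the
    participant's level of it, and one for the participant's stratum;
    counts are read for the ``group_pair`` (A-index, B-index).
    """
    profile.validate(spec)
    ga, gb = group_pair
    odds = allocation_odds(spec.ratio[ga], spec.ratio[gb])
    w = spec.weights
    weights = [w.overall] + [w.per_variable[v.name] for v in spec.variables] + [w.stratum]
    terms = []
    for key, weight in zip(profile.level_keys(spec), weights):
        c = state.counts(key)
        n_a, n_b = c[ga], c[gb]
        d = level_difference(n_a, n_b, odds)
        terms.append((key, d, imbalance_term(weight, n_a, n_b, odds, term_form=term_form)))
    return ImbalanceBreakdown(tuple(terms), math.fsum(t for _, _, t in terms))


def probability_from_imbalance(odds, a: float) -> float:
    """Step 4: ``p(A) = odds * exp(a) / (1 + odds * exp(a))``.

    Strictly increasing in ``a``; equals ``odds / (1 + odds)`` at ``a = 0``.
    The exponent is clamped at +/-700 so the probability saturates at 0/1
    instead of overflowing.
    """
    if not math.isfinite(a):
        raise ValidationError("imbalance must be finite")
    odds = float(odds)
    t = odds * math.exp(min(max(a, -_EXP_CLAMP), _EXP_CLAMP))
    return t / (1.0 + t)


def _one_vs_rest_probability(
    profile: ParticipantProfile,
    state: AllocationState,
    spec: TrialSpec,
    g: int,
    weights: Sequence[float],
    term_form: str,
) -> float:
    """p for group g against all other groups pooled, via Steps 1-4."""
    r_g = spec.ratio[g]
    rest = spec.ratio_total - r_g
    odds = Fraction(r_g, rest)
    p, q = odds.numerator, odds.denominator
    total = 0.0
    for key, weight in zip(profile.level_keys(spec), weights):
        c = state.counts(key)
        n_a = c[g]
        n_b = sum(c) - n_a
        x = p * n_b - q * n_a
        if x and weight:
            if term_form == "odds-scaled":
                total += weight * _sign(x) * (x * x) / (q * p)
            else:
                total += weight * _sign(x) * (x * x) / (p * p)
    return probability_from_imbalance(odds, total)


def group_probabilities(
    profile: ParticipantProfile,
    state: AllocationState,
    spec: TrialSpec,
    *,
    term_form: str = "odds-scaled",
) -> ProbabilityBoundaries:
    """Probability boundaries for the next participant.

    Two groups use the base four-step method directly, returning
    ``(p, 1 - p)``.  With ``k > 2`` groups each probability is computed
    one-vs-rest (``odds_g = r_g / (R - r_g)``, the rest pooled as "B") and
    the k results renormalized to sum to 1; at ``k = 2`` the construction
    is algebraically identical to the base method.
    """
    profile.validate(spec)
    w = spec.weights
    weights = [w.overall] + [w.per_variable[v.name] for v in spec.variables] + [w.stratum]
    if spec.n_groups == 2:
        p = _one_vs_rest_probability(profile, state, spec, 0, weights, term_form)
        probs = (p, 1.0 - p)
    else:
        raw = [
            _one_vs_rest_probability(profile, state, spec, g, weights, term_form)
            for g in range(spec.n_groups)
        ]
        s = math.fsum(raw)
        probs = tuple(x / s for x in raw)
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    return ProbabilityBoundaries(probs, tuple(float(x) for x in cum))


def draw_assignment(boundaries: ProbabilityBoundaries, u: float) -> int:
    """Locate the uniform draw among the cumulative boundaries.

    Intervals are half-open and lower-inclusive: with boundaries
    ``(2/3, 1/3)``, a draw below 2/3 assigns the first group.
    """
    if not (0.0 <= u < 1.0):
        raise ValidationError(f"uniform draw must be in [0, 1), got {u}")
    for g, b in enumerate(boundaries.cumulative):
        if u < b:
            return g
    return len(boundaries.cumulative) - 1  # u == 1 - eps landing on last edge


def allocate_participant(
    profile: ParticipantProfile,
    state: AllocationState,
    spec: TrialSpec,
    rng: np.random.Generator | None = None,
    *,
    u: float | None = None,
    participant_id: str | None = None,
    term_form: str = "odds-scaled",
) -> tuple[AllocationRecord, AllocationState]:
    """Allocate one participant; returns the record and the updated state.

    The input state is not mutated: a copy with the new counts and record
    is returned.  Supply either ``rng`` (a seeded generator) or an explicit
    uniform draw ``u``.
    """
    if u is None:
        if rng is None:
            raise ValidationError("provide an rng or an explicit uniform draw")
        u = float(rng.random())
    boundaries = group_probabilities(profile, state, spec, term_form=term_form)
    g = draw_assignment(boundaries, u)
    pid = participant_id or profile.participant_id or f"P{state.n_allocated + 1:04d}"
    record = AllocationRecord(
        sequence=state.n_allocated + 1,
        participant_id=pid,
        profile=profile,
        probabilities=boundaries.probabilities,
        u=u,
        group=g,
    )
    new_state = state.copy()
    new_state.apply(record)
    return record, new_state


class Randomizer:
    """A live randomization session: spec + running state + seeded RNG.

    Mutates its own state in place (the functional
    :func:`allocate_participant` wraps the same steps with a pure-update
    contract).  Every uniform draw is retained in the record so the whole
    session can be replayed for audit.
    """

    def __init__(
        self,
        spec: TrialSpec,
        rng: np.random.Generator | int | None = None,
        *,
        term_form: str = "odds-scaled",
    ):
        self.spec = spec
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.rng = rng
        self.term_form = term_form
        self.state = AllocationState(spec)

    def probabilities(self, profile: ParticipantProfile) -> ProbabilityBoundaries:
        return group_probabilities(profile, self.state, self.spec, term_form=self.term_form)

    def allocate(
        self,
        profile: ParticipantProfile,
        *,
        participant_id: str | None = None,
        u: float | None = None,
    ) -> AllocationRecord:
        if u is None:
            u = float(self.rng.random())
        boundaries = self.probabilities(profile)
        g = draw_assignment(boundaries, u)
        pid = participant_id or profile.participant_id or f"P{self.state.n_allocated + 1:04d}"
        record = AllocationRecord(
            sequence=self.state.n_allocated + 1,
            participant_id=pid,
            profile=profile,
            probabilities=boundaries.probabilities,
            u=u,
            group=g,
        )
        self.state.apply(record)
        return record
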