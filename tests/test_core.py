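"""Unit tests for the four-step boundary calculation and allocation."""

import math
from fractions import Fraction

import numpy as np
import pytest

from adaptrand.core import (
    AllocationState,
    ParticipantProfile,
    ProbabilityBoundaries,
    Randomizer,
    SpecificationError,
    StratVariable,
    TrialSpec,
    ValidationError,
    WeightScheme,
    allocate_participant,
    allocation_odds,
    draw_assignment,
    group_probabilities,
    imbalance_term,
    level_difference,
    probability_from_imbalance,
    total_imbalance,
)
from adaptrand.fixtures import example_spec


@pytest.mark.parametrize(
    "ra,rb,expected",
    [(2, 1, Fraction(2)), (1, 1, Fraction(1)), (3, 3, Fraction(1)), (3, 2, Fraction(3, 2))],
)
def test_allocation_odds(ra, rb, expected):
    assert allocation_odds(ra, rb) == expected


@pytest.mark.parametrize("ra,rb", [(0, 1), (1, 0), (-2, 1)])
def test_allocation_odds_rejects_non_positive(ra, rb):
    with pytest.raises(SpecificationError):
        allocation_odds(ra, rb)


@pytest.mark.parametrize(
    "n_a,n_b,odds,expected",
    [
        # the worked 2:1 example: balanced overall, center Z, stratum (F, Z)
        (8, 4, 2, 0.0),
        (3, 1, 2, -0.5),
        (2, 0, 2, -1.0),
        (0, 0, 2, 0.0),
        (4, 2, 2, 0.0),
    ],
)
def test_level_difference(n_a, n_b, odds, expected):
    assert level_difference(n_a, n_b, odds) == expected


def test_level_difference_is_exact_at_awkward_counts():
    # (odds*n_b - n_a)/odds evaluated in integer arithmetic: no float dust
    assert level_difference(14, 7, 2) == 0.0
    assert level_difference(3, 1, Fraction(3, 1)) == 0.0


@pytest.mark.parametrize(
    "w,n_a,n_b,odds,expected",
    [
        (0.2, 3, 1, 2, -0.1),  # center term of the worked sum
        (0.5, 2, 0, 2, -1.0),  # stratum term of the worked sum
        (0.7, 5, 5, 1, 0.0),
        (3.0, 0, 0, 1, 0.0),
    ],
)
def test_imbalance_term(w, n_a, n_b, odds, expected):
    assert imbalance_term(w, n_a, n_b, odds) == pytest.approx(expected, abs=1e-12)


def test_imbalance_term_sign_matches_difference():
    for n_a, n_b in [(0, 3), (3, 0), (1, 1), (5, 2), (2, 5)]:
        d = level_difference(n_a, n_b, 2)
        t = imbalance_term(1.0, n_a, n_b, 2)
        assert math.copysign(1, t) == math.copysign(1, d) or (t == 0 and d == 0)


def test_imbalance_term_plain_form():
    # the literal square-the-difference variant: w*sign(d)*d^2
    assert imbalance_term(0.2, 3, 1, 2, term_form="plain") == pytest.approx(
        0.2 * (-1) * 0.5**2, abs=1e-12
    )
    # forms coincide at odds 1
    assert imbalance_term(0.3, 4, 1, 1, term_form="plain") == imbalance_term(0.3, 4, 1, 1)


class TestTotalImbalance:
    """The Step-3 sum for the 13th participant of the worked example."""

    def test_medium_weights(self, spec_21, table_state, profile_fz):
        b = total_imbalance(profile_fz, table_state, spec_21)
        assert b.total == pytest.approx(-1.1, abs=1e-12)
        # overall and gender balanced, center Z and stratum (F, Z) favor A
        terms = {key: t for key, _, t in b.terms}
        assert terms[("overall",)] == 0.0
        assert terms[("level", "gender", "F")] == 0.0
        assert terms[("level", "center", "Z")] == pytest.approx(-0.1, abs=1e-12)
        assert terms[("stratum", "F", "Z")] == pytest.approx(-1.0, abs=1e-12)

    def test_strengthened_weights(self, table_state, profile_fz):
        b = total_imbalance(profile_fz, table_state, example_spec(10.0))
        assert b.total == pytest.approx(-11.0, abs=1e-12)

    def test_weakened_weights(self, table_state, profile_fz):
        b = total_imbalance(profile_fz, table_state, example_spec(0.1))
        assert b.total == pytest.approx(-0.11, abs=1e-12)

    def test_empty_state_is_balanced(self, spec_21, profile_fz):
        b = total_imbalance(profile_fz, AllocationState(spec_21), spec_21)
        assert b.total == 0.0

    def test_rejects_undeclared_level(self, spec_21, table_state):
        bad = ParticipantProfile({"gender": "F", "center": "Q"})
        with pytest.raises(ValidationError):
            total_imbalance(bad, table_state, spec_21)


@pytest.mark.parametrize(
    "odds,a,expected,places",
    [
        (2, 0.0, 2 / 3, 12),
        (2, -1.1, 0.40, 2),
        (2, -0.11, 0.64, 2),
        (1, 0.0, 0.5, 12),
    ],
)
def test_probability_from_imbalance(odds, a, expected, places):
    assert round(probability_from_imbalance(odds, a), places) == round(expected, places)


def test_probability_extreme_imbalance():
    # closed form at a = -11: 2 e^-11 / (1 + 2 e^-11)
    expected = 2 * math.exp(-11) / (1 + 2 * math.exp(-11))
    assert probability_from_imbalance(2, -11) == pytest.approx(expected, rel=1e-12)
    assert probability_from_imbalance(2, -11) == pytest.approx(3.34e-5, rel=5e-3)


def test_probability_saturates_instead_of_overflowing():
    assert probability_from_imbalance(2, 1e6) == 1.0
    assert probability_from_imbalance(2, -1e6) == pytest.approx(0.0, abs=1e-300)
    with pytest.raises(ValidationError):
        probability_from_imbalance(2, float("nan"))


def test_probability_monotone_in_imbalance():
    values = [probability_from_imbalance(2, a) for a in np.linspace(-5, 5, 41)]
    assert all(b > a for a, b in zip(values, values[1:]))


class TestGroupProbabilities:
    def test_worked_example(self, spec_21, table_state, profile_fz):
        b = group_probabilities(profile_fz, table_state, spec_21)
        assert round(b.probabilities[0], 2) == 0.40
        assert round(b.probabilities[1], 2) == 0.60

    def test_first_participant_gets_ratio_proportions(self, spec_21, profile_fz):
        b = group_probabilities(profile_fz, AllocationState(spec_21), spec_21)
        assert b.probabilities[0] == pytest.approx(2 / 3, abs=1e-15)

    def test_three_groups_zero_imbalance(self):
        spec = TrialSpec(
            ("MBCT", "CPE", "TAU"),
            (2, 2, 1),
            (StratVariable("center", ("O", "B")),),
            WeightScheme(0.05, {"center": 0.1}, 0.25),
        )
        b = group_probabilities(
            ParticipantProfile({"center": "O"}), AllocationState(spec), spec
        )
        assert b.probabilities == pytest.approx((0.4, 0.4, 0.2), abs=1e-12)
        assert b.cumulative[-1] == 1.0


@pytest.mark.parametrize(
    "probs,u,expected",
    [
        ((2 / 3, 1 / 3), 0.30, 0),
        ((2 / 3, 1 / 3), 0.90, 1),
        ((2 / 3, 1 / 3), 0.0, 0),
        ((0.4, 0.4, 0.2), 0.79, 1),  # cumulative points 0.4, 0.8, 1.0
        ((0.4, 0.4, 0.2), 0.80, 2),  # lower-inclusive half-open intervals
    ],
)
def test_draw_assignment(probs, u, expected):
    cum = tuple(np.cumsum(probs))
    b = ProbabilityBoundaries(tuple(probs), cum[:-1] + (1.0,))
    assert draw_assignment(b, u) == expected


def test_draw_assignment_rejects_out_of_range():
    b = ProbabilityBoundaries((0.5, 0.5), (0.5, 1.0))
    for u in (-0.1, 1.0, 1.5):
        with pytest.raises(ValidationError):
            draw_assignment(b, u)


class TestAllocateParticipant:
    def test_first_allocation(self, spec_21, profile_fz):
        rec, state = allocate_participant(
            profile_fz, AllocationState(spec_21), spec_21, u=0.5
        )
        assert rec.group == 0  # 0.5 < 2/3
        assert state.overall == (1, 0)
        assert state.counts(("stratum", "F", "Z")) == (1, 0)

    def test_worked_example_boundary(self, spec_21, table_state, profile_fz):
        rec, _ = allocate_participant(profile_fz, table_state, spec_21, u=0.55)
        assert rec.group == 1  # boundary at 0.40, so 0.55 lands in B

    def test_does_not_mutate_input_state(self, spec_21, table_state, profile_fz):
        before = table_state.overall
        allocate_participant(profile_fz, table_state, spec_21, u=0.1)
        assert table_state.overall == before
        assert table_state.n_allocated == 12

    def test_seeded_sequences_are_reproducible(self, spec_21, profile_fz):
        def run():
            r = Randomizer(spec_21, rng=42)
            return [r.allocate(profile_fz).group for _ in range(25)]

        assert run() == run()

    def test_randomizer_matches_functional_path(self, spec_21, profile_fz):
        r = Randomizer(spec_21, rng=7)
        state = AllocationState(spec_21)
        rng = np.random.default_rng(7)
        for _ in range(15):
            u = float(rng.random())
            rec_f, state = allocate_participant(profile_fz, state, spec_21, u=u)
            rec_m = r.allocate(profile_fz)
            assert rec_m.group == rec_f.group
            assert rec_m.probabilities == rec_f.probabilities
        assert r.state.overall == state.overall


class TestSpecValidation:
    def test_rejects_single_group(self):
        with pytest.raises(SpecificationError):
            TrialSpec(("A",), (1,))

    def test_rejects_zero_ratio(self):
        with pytest.raises(SpecificationError):
            TrialSpec(("A", "B"), (1, 0))

    def test_rejects_duplicate_levels(self):
        with pytest.raises(SpecificationError):
            StratVariable("center", ("X", "X"))

    def test_rejects_missing_variable_weight(self):
        with pytest.raises(SpecificationError):
            TrialSpec(
                ("A", "B"),
                (1, 1),
                (StratVariable("center", ("X", "Y")),),
                WeightScheme(0.1, {}, 0.5),
            )

    def test_rejects_negative_weight(self):
        with pytest.raises(SpecificationError):
            WeightScheme(-0.1, {}, 0.5)

    def test_state_consistency_check(self, spec_21, table_state):
        table_state.validate_consistency()
        broken = table_state.copy()
        broken._counts[("overall",)][0] += 1
        with pytest.raises(ValidationError):
            broken.validate_consistency()
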