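"""Ready-made trial specifications used throughout the docs and tests.

Includes the didactic 2:1 two-variable example trial, the four
weight-strength scenarios of the simulation study (strong, medium, weak,
simple randomization), and the three published trial set-ups the method
ran in production: FolATED (two groups 1:1, four stratification
variables), EPIC (2:1 unequal allocation) and SWAD (three groups 2:2:1).
"""

from __future__ import annotations

from .core import (
    AllocationRecord,
    AllocationState,
    ParticipantProfile,
    StratVariable,
    TrialSpec,
    WeightScheme,
)

__all__ = [
    "example_spec",
    "example_table_state",
    "scenario_weights",
    "scenario_spec",
    "folated_spec",
    "epic_spec",
    "swad_spec",
    "state_from_assignments",
]

_CENTER = StratVariable("center", ("X", "Y", "Z"))
_GENDER = StratVariable("gender", ("M", "F"))

#: Weight sets of the four simulation scenarios, strongest to none.
SCENARIO_WEIGHTS = {
    1: (1.0, 2.0, 2.0, 5.0),  # strong control
    2: (0.1, 0.2, 0.2, 0.5),  # medium
    3: (0.01, 0.02, 0.02, 0.05),  # weak
    4: (0.0, 0.0, 0.0, 0.0),  # simple randomization
}


def scenario_weights(scenario: int) -> WeightScheme:
    overall, center, gender, stratum = SCENARIO_WEIGHTS[scenario]
    return WeightScheme(overall, {"center": center, "gender": gender}, stratum)


def scenario_spec(scenario: int) -> TrialSpec:
    """Two-group 1:1 trial with center (X/Y/Z) and gender (M/F) under one
    of the four simulation weight scenarios."""
    return TrialSpec(("A", "B"), (1, 1), (_CENTER, _GENDER), scenario_weights(scenario))


def example_spec(weight_scale: float = 1.0) -> TrialSpec:
    """The didactic two-group 2:1 trial: gender and center variables with
    medium weights (overall 0.1, variables 0.2, stratum 0.5), optionally
    scaled by ``weight_scale`` (x10 strengthened, /10 weakened)."""
    s = weight_scale
    return TrialSpec(
        ("A", "B"),
        (2, 1),
        (_GENDER, _CENTER),
        WeightScheme(0.1 * s, {"gender": 0.2 * s, "center": 0.2 * s}, 0.5 * s),
    )


def state_from_assignments(
    spec: TrialSpec, rows: list[tuple[dict, int]]
) -> AllocationState:
    """Build a state by applying (profile values, group index) pairs.

    Probabilities and draws are not part of the count bookkeeping, so the
    synthetic records carry placeholder values; use the allocation log for
    auditable history.
    """
    state = AllocationState(spec)
    k = spec.n_groups
    for i, (values, group) in enumerate(rows, start=1):
        state.apply(
            AllocationRecord(
                sequence=i,
                participant_id=f"F{i:04d}",
                profile=ParticipantProfile(values),
                probabilities=(1.0 / k,) * k,
                u=0.0,
                group=group,
            )
        )
    state.validate_consistency()
    return state


def example_table_state(spec: TrialSpec | None = None) -> AllocationState:
    """The 12-participant allocation table of the didactic example:
    overall 8:4, with e.g. stratum (F, center Z) at 2:0."""
    spec = spec or example_spec()
    cells = [
        ("M", "X", 1, 0),
        ("F", "X", 1, 1),
        ("M", "Y", 2, 1),
        ("F", "Y", 1, 1),
        ("M", "Z", 1, 1),
        ("F", "Z", 2, 0),
    ]
    rows = []
    for gender, center, n_a, n_b in cells:
        rows += [({"gender": gender, "center": center}, 0)] * n_a
        rows += [({"gender": gender, "center": center}, 1)] * n_b
    return state_from_assignments(spec, rows)


def folated_spec() -> TrialSpec:
    """FolATED: folate augmentation of antidepressants, two groups 1:1,
    549 intended participants; stratified by center, gender, patient type
    (new/continuing x counseling, merged to four levels) and
    antidepressant type."""
    return TrialSpec(
        ("folate", "placebo"),
        (1, 1),
        (
            StratVariable("center", ("Bangor", "Swansea", "Wrexham")),
            StratVariable("gender", ("M", "F")),
            StratVariable(
                "patient_type",
                (
                    "new/counseling",
                    "new/no-counseling",
                    "continuing/counseling",
                    "continuing/no-counseling",
                ),
            ),
            StratVariable("antidepressant", ("SSRI", "other")),
        ),
        WeightScheme(
            0.02,
            {"center": 0.04, "gender": 0.04, "patient_type": 0.02, "antidepressant": 0.02},
            0.05,
        ),
    )


def epic_spec(n_centers: int = 4) -> TrialSpec:
    """EPIC: diabetes information-pack trial, 2:1 allocation, 252 intended
    participants; stratified by age band, gender, time since diagnosis and
    center.  The number of recruiting centers is a free parameter of the
    fixture (the published set-up weights center at 0.1 without stating
    the count)."""
    return TrialSpec(
        ("intervention", "control"),
        (2, 1),
        (
            StratVariable("age", ("6-10", "11-15", "16-18")),
            StratVariable("gender", ("M", "F")),
            StratVariable("diagnosis", ("<2y", ">=2y")),
            StratVariable("center", tuple(f"C{i + 1}" for i in range(n_centers))),
        ),
        WeightScheme(
            0.05,
            {"age": 0.05, "gender": 0.05, "diagnosis": 0.05, "center": 0.1},
            0.2,
        ),
    )


def swad_spec() -> TrialSpec:
    """SWAD: staying well after depression, three groups (MBCT, CPE, TAU)
    in ratio 2:2:1, 375 intended participants; stratified by center,
    recruitment cohort, suicidality history and antidepressant use."""
    return TrialSpec(
        ("MBCT", "CPE", "TAU"),
        (2, 2, 1),
        (
            StratVariable("center", ("Oxford", "Bangor")),
            StratVariable("cohort", tuple(f"cohort{i + 1}" for i in range(6))),
            StratVariable("suicidality", ("none", "ideation", "attempt")),
            StratVariable("ad_use", ("yes", "no")),
        ),
        WeightScheme(
            0.05,
            {"center": 0.1, "cohort": 0.1, "suicidality": 0.05, "ad_use": 0.05},
            0.25,
        ),
    )
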