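"""Append-only CSV allocation log with exact replay.

The log is the durable record of a randomization session: one row per
allocation holding the participant's stratification levels, the
probabilities in force, the uniform draw and the assigned group.  The
in-memory counts of an :class:`AllocationState` are merely a cache — the
state is always reconstructible by replaying the log through the engine,
and :func:`replay` re-derives every assignment from the recorded draw and
verifies it against the recorded group, so a tampered or corrupted log is
detected rather than trusted.
"""

from __future__ import annotations

import csv
import io
from datetime import datetime, timezone
from pathlib import Path

from .core import (
    AllocationRecord,
    AllocationState,
    ParticipantProfile,
    TrialSpec,
    ValidationError,
    draw_assignment,
    group_probabilities,
)

__all__ = ["AllocationLog", "replay"]

_FIXED_LEAD = ["sequence", "participant_id"]
_FIXED_TAIL = ["u", "assigned", "timestamp"]


class LogError(ValidationError):
    """Malformed or inconsistent allocation log."""


class AllocationLog:
    """A CSV allocation log bound to a trial spec.

    Header: ``sequence, participant_id, <one column per stratification
    variable>, p_<group> per group, u, assigned, timestamp``.  Appends are
    flushed row-by-row; probabilities and draws are serialized at full
    precision (``repr`` of the float) so replay is bit-exact.
    """

    def __init__(self, path: str | Path, spec: TrialSpec):
        self.path = Path(path)
        self.spec = spec
        self.columns = (
            _FIXED_LEAD
            + [v.name for v in spec.variables]
            + [f"p_{g}" for g in spec.group_names]
            + _FIXED_TAIL
        )
        if not self.path.exists() or self.path.stat().st_size == 0:
            with open(self.path, "w", newline="") as fh:
                csv.writer(fh).writerow(self.columns)

    def _read_rows(self) -> list[dict]:
        with open(self.path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames != self.columns:
                raise LogError(
                    f"log header {reader.fieldnames} does not match the trial "
                    f"specification (expected {self.columns})"
                )
            return list(reader)

    def participant_ids(self) -> set[str]:
        return {row["participant_id"] for row in self._read_rows()}

    def append(self, record: AllocationRecord, *, timestamp: str | None = None) -> None:
        """Append one allocation; rejects re-randomization of a known id."""
        if record.participant_id in self.participant_ids():
            raise LogError(
                f"participant {record.participant_id!r} is already in the log; "
                "no participant can be randomized twice"
            )
        ts = timestamp or datetime.now(timezone.utc).isoformat(timespec="seconds")
        row = (
            [record.sequence, record.participant_id]
            + [record.profile.values[v.name] for v in self.spec.variables]
            + [repr(p) for p in record.probabilities]
            + [repr(record.u), self.spec.group_names[record.group], ts]
        )
        with open(self.path, "a", newline="") as fh:
            csv.writer(fh).writerow(row)

    def records(self) -> list[AllocationRecord]:
        """Parse the log rows back into allocation records."""
        out = []
        seen: set[str] = set()
        for i, row in enumerate(self._read_rows(), start=2):  # row 1 is header
            try:
                profile = ParticipantProfile(
                    {v.name: row[v.name] for v in self.spec.variables},
                    participant_id=row["participant_id"],
                )
                rec = AllocationRecord(
                    sequence=int(row["sequence"]),
                    participant_id=row["participant_id"],
                    profile=profile,
                    probabilities=tuple(
                        float(row[f"p_{g}"]) for g in self.spec.group_names
                    ),
                    u=float(row["u"]),
                    group=self.spec.group_names.index(row["assigned"]),
                    timestamp=row["timestamp"] or None,
                )
            except (KeyError, TypeError, AttributeError) as exc:
                raise LogError(f"malformed log row {i}: {exc}") from exc
            except ValueError as exc:
                raise LogError(f"malformed log row {i}: {exc}") from exc
            if rec.participant_id in seen:
                raise LogError(
                    f"log row {i}: participant {rec.participant_id!r} appears twice"
                )
            seen.add(rec.participant_id)
            out.append(rec)
        return out


def replay(log: AllocationLog, spec: TrialSpec | None = None) -> AllocationState:
    """Rebuild the allocation state by re-running the engine over the log.

    Each row's probabilities and assignment are recomputed from the trial
    spec, the state so far and the recorded uniform draw, and must match
    the recorded values exactly; any divergence raises :class:`LogError`.
    """
    spec = spec or log.spec
    state = AllocationState(spec)
    for rec in log.records():
        boundaries = group_probabilities(rec.profile, state, spec)
        if boundaries.probabilities != rec.probabilities:
            raise LogError(
                f"row {rec.sequence}: recorded probabilities "
                f"{rec.probabilities} do not match recomputed "
                f"{boundaries.probabilities}"
            )
        g = draw_assignment(boundaries, rec.u)
        if g != rec.group:
            raise LogError(
                f"row {rec.sequence}: recorded assignment "
                f"{spec.group_names[rec.group]!r} does not match recomputed "
                f"{spec.group_names[g]!r}"
            )
        state.apply(rec)
    state.validate_consistency()
    return state
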