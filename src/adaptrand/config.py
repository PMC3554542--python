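"""Trial configuration documents (YAML) <-> :class:`TrialSpec`.

One canonical dialect::

    groups: [A, B]
    ratio: [2, 1]
    variables:
      - name: center
        levels: [X, Y, Z]
      - name: gender
        levels: [M, F]
    weights:
      overall: 0.1
      center: 0.2
      gender: 0.2
      stratum: 0.5
    seed: 20130117        # optional

Unknown keys anywhere in the document are rejected, so a misspelled weight
name is a hard error rather than a silently unweighted variable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .core import SpecificationError, StratVariable, TrialSpec, WeightScheme

__all__ = ["load_spec", "save_spec", "loads_spec", "dumps_spec"]

_TOP_KEYS = {"groups", "ratio", "variables", "weights", "seed"}
_VAR_KEYS = {"name", "levels"}


def _reject_unknown(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise SpecificationError(f"unknown key(s) {sorted(unknown)} in {where}")


def loads_spec(text: str) -> tuple[TrialSpec, int | None]:
    """Parse a configuration document; returns (spec, optional seed)."""
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise SpecificationError("configuration must be a mapping")
    _reject_unknown(doc, _TOP_KEYS, "configuration")
    for key in ("groups", "ratio", "weights"):
        if key not in doc:
            raise SpecificationError(f"configuration is missing {key!r}")

    variables = []
    for i, v in enumerate(doc.get("variables") or []):
        if not isinstance(v, dict):
            raise SpecificationError(f"variable #{i + 1} must be a mapping")
        _reject_unknown(v, _VAR_KEYS, f"variable #{i + 1}")
        variables.append(StratVariable(str(v["name"]), tuple(str(x) for x in v["levels"])))

    wdoc = doc["weights"]
    if not isinstance(wdoc, dict):
        raise SpecificationError("weights must be a mapping")
    _reject_unknown(wdoc, {"overall", "stratum"} | {v.name for v in variables}, "weights")
    for key in ("overall", "stratum"):
        if key not in wdoc:
            raise SpecificationError(f"weights is missing {key!r}")
    missing = [v.name for v in variables if v.name not in wdoc]
    if missing:
        raise SpecificationError(f"weights is missing variable(s): {missing}")
    weights = WeightScheme(
        overall=float(wdoc["overall"]),
        per_variable={v.name: float(wdoc[v.name]) for v in variables},
        stratum=float(wdoc["stratum"]),
    )

    spec = TrialSpec(
        group_names=tuple(str(g) for g in doc["groups"]),
        ratio=tuple(int(r) for r in doc["ratio"]),
        variables=tuple(variables),
        weights=weights,
    )
    seed = doc.get("seed")
    return spec, (int(seed) if seed is not None else None)


def load_spec(path: str | Path) -> tuple[TrialSpec, int | None]:
    """Read and validate a trial configuration file."""
    return loads_spec(Path(path).read_text())


def dumps_spec(spec: TrialSpec, seed: int | None = None) -> str:
    """Serialize a spec to the canonical document form (round-trips)."""
    doc: dict[str, Any] = {
        "groups": list(spec.group_names),
        "ratio": list(spec.ratio),
        "variables": [{"name": v.name, "levels": list(v.levels)} for v in spec.variables],
        "weights": {
            "overall": spec.weights.overall,
            **{v.name: spec.weights.per_variable[v.name] for v in spec.variables},
            "stratum": spec.weights.stratum,
        },
    }
    if seed is not None:
        doc["seed"] = int(seed)
    return yaml.safe_dump(doc, sort_keys=False)


def save_spec(spec: TrialSpec, path: str | Path, seed: int | None = None) -> None:
    Path(path).write_text(dumps_spec(spec, seed))
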