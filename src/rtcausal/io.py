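"""Population spec files, canonical JSON, and tabular output.

Population specs are JSON or YAML with either the direct parameterization::

    n_total: 1000
    mass:          [{e: 1, d: 6, s: 4, p: 1.0}]
    c_given_type:  [{e: 1, d: 6, s: 4, p_c: 0.3}]

or the conditional parameterization (converted exactly via Bayes' rule)::

    n_total: 1000
    p_c: 0.5
    mass_given_c:      [{e: 1, d: 1, s: 1, p: 1.0}]
    mass_given_not_c:  [{e: 4, d: 16, s: 1, p: 1.0}]

Validation is strict — unknown keys are rejected and every violation is
reported, not just the first.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any

import yaml

from .population import PopulationSpec, PopulationError


class SchemaError(ValueError):
    """A population file violates the schema; lists every violation."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid population file:\n  " + "\n  ".join(violations))


_DIRECT_KEYS = {"n_total", "mass", "c_given_type"}
_CONDITIONAL_KEYS = {"n_total", "p_c", "mass_given_c", "mass_given_not_c"}
_RANGES = {"e": (1, 4), "d": (1, 16), "s": (1, 16)}


def _parse_entries(raw: Any, value_key: str, where: str, errors: list[str]) -> dict:
    out: dict[tuple[int, int, int], float] = {}
    if not isinstance(raw, list):
        errors.append(f"{where}: expected a list of entries, got {type(raw).__name__}")
        return out
    for pos, entry in enumerate(raw):
        label = f"{where}[{pos}]"
        if not isinstance(entry, dict):
            errors.append(f"{label}: expected a mapping")
            continue
        extra = set(entry) - {"e", "d", "s", value_key}
        if extra:
            errors.append(f"{label}: unknown keys {sorted(extra)}")
        bad = False
        idx = []
        for axis in ("e", "d", "s"):
            v = entry.get(axis)
            lo, hi = _RANGES[axis]
            if not isinstance(v, int) or isinstance(v, bool) or not lo <= v <= hi:
                errors.append(f"{label}: field {axis!r} must be an integer in {lo}..{hi}, got {v!r}")
                bad = True
            idx.append(v)
        p = entry.get(value_key)
        if not isinstance(p, (int, float)) or isinstance(p, bool) or not 0 <= p <= 1:
            errors.append(f"{label}: field {value_key!r} must be a probability, got {p!r}")
            bad = True
        if bad:
            continue
        key = tuple(idx)
        if key in out:
            errors.append(f"{label}: duplicate type {key}")
        out[key] = float(p)
    return out


def parse_population(data: Any) -> PopulationSpec:
    """Validate a decoded population document and build the spec."""
    errors: list[str] = []
    if not isinstance(data, dict):
        raise SchemaError(["document root must be a mapping"])
    keys = set(data)
    conditional = "p_c" in keys or "mass_given_c" in keys
    expected = _CONDITIONAL_KEYS if conditional else _DIRECT_KEYS
    extra = keys - expected
    if extra:
        errors.append(f"unknown keys {sorted(extra)}")
    missing = expected - keys
    if missing:
        errors.append(f"missing keys {sorted(missing)}")
    n_total = data.get("n_total")
    if not isinstance(n_total, (int, float)) or isinstance(n_total, bool) or not n_total > 0:
        errors.append(f"n_total must be a positive number, got {n_total!r}")
    if conditional:
        p_c = data.get("p_c")
        if not isinstance(p_c, (int, float)) or isinstance(p_c, bool) or not 0 <= p_c <= 1:
            errors.append(f"p_c must be a probability, got {p_c!r}")
        m1 = _parse_entries(data.get("mass_given_c", []), "p", "mass_given_c", errors)
        m0 = _parse_entries(data.get("mass_given_not_c", []), "p", "mass_given_not_c", errors)
        for name, m in (("mass_given_c", m1), ("mass_given_not_c", m0)):
            total = math.fsum(m.values())
            if not errors and abs(total - 1.0) > 1e-9:
                errors.append(f"{name} sums to {total!r}, not 1")
        if errors:
            raise SchemaError(errors)
        try:
            return PopulationSpec.from_conditional(float(n_total), float(p_c), m1, m0)
        except PopulationError as exc:
            raise SchemaError([str(exc)]) from exc
    mass = _parse_entries(data.get("mass", []), "p", "mass", errors)
    cgt = _parse_entries(data.get("c_given_type", []), "p_c", "c_given_type", errors)
    total = math.fsum(mass.values())
    if abs(total - 1.0) > 1e-9:
        errors.append(f"mass sums to {total!r}, not 1")
    for t, p in mass.items():
        if p > 0 and t not in cgt:
            errors.append(f"c_given_type missing entry for positive-mass type {t}")
    if errors:
        raise SchemaError(errors)
    try:
        return PopulationSpec(float(n_total), mass, cgt)
    except PopulationError as exc:
        raise SchemaError([str(exc)]) from exc


def population_to_dict(pop: PopulationSpec) -> dict:
    """Direct-parameterization document for a spec (round-trips exactly)."""
    return {
        "n_total": pop.n_total,
        "mass": [
            {"e": t[0], "d": t[1], "s": t[2], "p": p}
            for t, p in sorted(pop.mass.items())
            if p > 0
        ],
        "c_given_type": [
            {"e": t[0], "d": t[1], "s": t[2], "p_c": pop.c_given_type[t]}
            for t in sorted(pop.mass)
            if pop.mass[t] > 0
        ],
    }


def load_population(path: str | Path) -> PopulationSpec:
    """Read and validate a population spec from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return parse_population(data)


def save_population(pop: PopulationSpec, path: str | Path) -> None:
    path = Path(path)
    doc = population_to_dict(pop)
    if path.suffix.lower() == ".json":
        # full float precision: population files must round-trip exactly
        path.write_text(json.dumps(doc, sort_keys=True, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=True))


def _canonical(obj):
    if isinstance(obj, float):
        if obj != obj or obj in (float("inf"), float("-inf")):
            return None
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    return obj


def canonical_json(obj: Any) -> str:
    """Deterministic JSON: sorted keys, floats at 12 significant digits."""
    return json.dumps(_canonical(obj), sort_keys=True, indent=2) + "\n"
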