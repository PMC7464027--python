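"""Drug-likeness rule filters (Lipinski, Ghose, Veber, Egan, Muegge).

The bound tables live in ``data/filter_bounds.yaml`` and are inclusive on
both ends; each rule also carries a violation policy (Lipinski classically
tolerates one violation, the others none).  All rules evaluate a plain
property dict, so they can run on computed properties or on externally
supplied ones.  The logP used throughout is the Crippen SlogP estimate —
a single consistent flavor rather than per-rule estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

from .chem_io import MoleculeRecord
from .descriptors import molecular_properties

__all__ = [
    "Violation",
    "RuleResult",
    "FilterReport",
    "evaluate_rule",
    "lipinski",
    "ghose",
    "veber",
    "egan",
    "muegge",
    "filter_report",
    "cascade",
    "RULE_NAMES",
]

RULE_NAMES = ("lipinski", "ghose", "veber", "egan", "muegge")


@dataclass(frozen=True)
class Violation:
    """One bound violation: which property, its value, and the broken bound."""

    property: str
    value: float
    bound: str  # e.g. "max 500" or "min 160"

    def __str__(self) -> str:
        return f"{self.property}={self.value:g} violates {self.bound}"


@dataclass(frozen=True)
class RuleResult:
    rule: str
    passed: bool
    violations: tuple[Violation, ...]
    max_violations: int


@dataclass(frozen=True)
class FilterReport:
    molecule_id: str
    results: Mapping[str, RuleResult]

    def passed(self, rules: Iterable[str] | None = None) -> bool:
        names = list(rules) if rules is not None else list(self.results)
        return all(self.results[r].passed for r in names)


@lru_cache(maxsize=1)
def _bounds() -> dict:
    text = resources.files("adscreen.data").joinpath("filter_bounds.yaml").read_text()
    return yaml.safe_load(text)


def evaluate_rule(
    rule: str, props: Mapping[str, float], *, max_violations: int | None = None
) -> RuleResult:
    """Check one named rule against a property dict.

    Raises ``KeyError`` naming any property the rule needs but the dict
    lacks — a missing property is never treated as passing.
    """
    spec = _bounds().get(rule)
    if spec is None:
        raise ValueError(f"unknown rule {rule!r}; known: {', '.join(_bounds())}")
    allowed = (
        max_violations
        if max_violations is not None
        else int(spec["policy"]["max_violations"])
    )
    violations: list[Violation] = []
    for prop, bound in spec["bounds"].items():
        if prop not in props:
            raise KeyError(f"rule {rule!r} needs property {prop!r}, absent from input")
        value = float(props[prop])
        if "min" in bound and value < float(bound["min"]):
            violations.append(Violation(prop, value, f"min {bound['min']}"))
        if "max" in bound and value > float(bound["max"]):
            violations.append(Violation(prop, value, f"max {bound['max']}"))
    return RuleResult(
        rule=rule,
        passed=len(violations) <= allowed,
        violations=tuple(violations),
        max_violations=allowed,
    )


def lipinski(props: Mapping[str, float], *, strict: bool = False) -> RuleResult:
    """Rule of five; classically passes with <= 1 violation (strict: 0)."""
    return evaluate_rule("lipinski", props, max_violations=0 if strict else None)


def ghose(props: Mapping[str, float]) -> RuleResult:
    return evaluate_rule("ghose", props)


def veber(props: Mapping[str, float]) -> RuleResult:
    return evaluate_rule("veber", props)


def egan(props: Mapping[str, float]) -> RuleResult:
    return evaluate_rule("egan", props)


def muegge(props: Mapping[str, float]) -> RuleResult:
    return evaluate_rule("muegge", props)


def filter_report(
    record: MoleculeRecord, rules: Sequence[str] = RULE_NAMES
) -> FilterReport:
    """Evaluate the named rules on computed molecular properties."""
    props = molecular_properties(record)
    return FilterReport(
        molecule_id=record.id,
        results={r: evaluate_rule(r, props) for r in rules},
    )


@dataclass
class CascadeResult:
    survivors: list[MoleculeRecord]
    stage_counts: list[dict]  # per stage: {rule, entering, surviving}
    reports: dict[str, FilterReport] = field(default_factory=dict)


def cascade(
    records: Sequence[MoleculeRecord], stages: Sequence[str]
) -> CascadeResult:
    """Apply rule stages in order, recording the survivor funnel.

    Because every rule is a pure predicate on one molecule, the survivor
    *membership* is the intersection of the per-rule pass sets and is
    independent of stage order; only the per-stage counts depend on it.
    """
    if not stages:
        raise ValueError("cascade needs at least one stage")
    current = list(records)
    counts = []
    reports: dict[str, FilterReport] = {
        rec.id: filter_report(rec, stages) for rec in records
    }
    for stage in stages:
        entering = len(current)
        current = [rec for rec in current if reports[rec.id].results[stage].passed]
        counts.append({"rule": stage, "entering": entering, "surviving": len(current)})
    return CascadeResult(survivors=current, stage_counts=counts, reports=reports)
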