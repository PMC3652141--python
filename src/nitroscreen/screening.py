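"""Drug-likeness and CNS-penetration screens.

Two CNS-penetration criteria sets from the BBB literature are shipped as
data (users can define their own):

* ``CNS_A`` — FW ≤ 400, Log P ≤ 5, H-bond donors ≤ 3, H-bond acceptors ≤ 7;
* ``CNS_B`` — PSA ≤ 90 Å², FW ≤ 450.

The Rule of 5 counts violations of {donors > 5, acceptors > 10,
FW ≥ 500 Da, Log P > 5}; a compound is drug-like when it has at most one
violation. Boundary conventions are literal: "less than 500 daltons" makes
FW = 500 a violation, "not greater than 5" makes Log P = 5 compliant.
"""

from __future__ import annotations

import dataclasses
import json
import operator
from pathlib import Path
from typing import Mapping, Sequence

from .chem_io import DescriptorRecord, DescriptorTable
from .errors import FormatError

_OPS = {
    "<=": operator.le,
    "<": operator.lt,
    ">=": operator.ge,
    ">": operator.gt,
}


@dataclasses.dataclass(frozen=True)
class Criterion:
    field: str
    op: str  # one of <=, <, >=, >
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise FormatError(f"unknown comparator {self.op!r}")
        if not (self.threshold == self.threshold and abs(self.threshold) != float("inf")):
            raise FormatError("criterion threshold must be finite")

    def passes(self, r: DescriptorRecord) -> bool:
        r.require([self.field])
        return _OPS[self.op](getattr(r, self.field), self.threshold)

    def label(self) -> str:
        return f"{self.field}{self.op}{self.threshold:g}"


@dataclasses.dataclass(frozen=True)
class CriteriaSet:
    name: str
    bounds: tuple[Criterion, ...]


#: FW ≤ 400, Log P ≤ 5, donors ≤ 3, acceptors ≤ 7.
CNS_A = CriteriaSet(
    "cns_a",
    (
        Criterion("fw", "<=", 400),
        Criterion("log_p", "<=", 5),
        Criterion("n_ohnh", "<=", 3),
        Criterion("n_on", "<=", 7),
    ),
)

#: PSA ≤ 90 Å² and FW ≤ 450.
CNS_B = CriteriaSet(
    "cns_b",
    (
        Criterion("psa", "<=", 90),
        Criterion("fw", "<=", 450),
    ),
)

BUILTIN_CRITERIA: Mapping[str, CriteriaSet] = {"cns_a": CNS_A, "cns_b": CNS_B}


def criteria_from_json(path: str | Path) -> CriteriaSet:
    """Load a criteria set from JSON: {"name": ..., "bounds": [{field, op, value}]}."""
    with open(path) as fh:
        spec = json.load(fh)
    bounds = tuple(
        Criterion(b["field"], b["op"], float(b["value"])) for b in spec["bounds"]
    )
    return CriteriaSet(spec["name"], bounds)


@dataclasses.dataclass(frozen=True)
class ScreenResult:
    """Per-compound verdicts against one criteria set."""

    agent_id: str
    criteria_set: str
    verdicts: tuple[tuple[str, bool], ...]  # (criterion label, passed)
    overall_pass: bool
    ro5_violations: int

    def __post_init__(self) -> None:
        assert self.overall_pass == all(v for _, v in self.verdicts)


def rule_of_five_violations(r: DescriptorRecord) -> int:
    """Number (0-4) of Rule-of-5 violations for one record."""
    r.require(["log_p", "fw", "n_on", "n_ohnh"])
    return sum(
        (
            r.n_ohnh > 5,
            r.n_on > 10,
            r.fw >= 500,
            r.log_p > 5,
        )
    )


def is_druglike(r: DescriptorRecord) -> bool:
    """At most one Rule-of-5 violation."""
    return rule_of_five_violations(r) <= 1


def cns_pass(r: DescriptorRecord, criteria: CriteriaSet) -> ScreenResult:
    """Evaluate one record against one criteria set."""
    verdicts = tuple((c.label(), c.passes(r)) for c in criteria.bounds)
    return ScreenResult(
        agent_id=r.agent_id,
        criteria_set=criteria.name,
        verdicts=verdicts,
        overall_pass=all(v for _, v in verdicts),
        ro5_violations=rule_of_five_violations(r),
    )


@dataclasses.dataclass(frozen=True)
class LibraryReport:
    """Screen of a whole table: per-record results plus pass statistics."""

    results: tuple[tuple[ScreenResult, ...], ...]  # per record, per criteria set
    criteria_names: tuple[str, ...]
    pass_counts: Mapping[str, int]
    pass_fractions: Mapping[str, float]
    n_records: int

    @property
    def n_pass_all(self) -> int:
        """Records passing every requested criteria set with 0 Ro5 violations."""
        return sum(
            1
            for per_record in self.results
            if all(s.overall_pass for s in per_record)
            and (not per_record or per_record[0].ro5_violations == 0)
        )


def screen_library(
    table: DescriptorTable, sets: Sequence[CriteriaSet] = (CNS_A, CNS_B)
) -> LibraryReport:
    """Screen every record of ``table`` against each criteria set."""
    if len(table) == 0:
        raise FormatError("cannot screen an empty table")
    results = tuple(
        tuple(cns_pass(r, c) for c in sets) for r in table
    )
    names = tuple(c.name for c in sets)
    counts = {
        c.name: sum(per_record[i].overall_pass for per_record in results)
        for i, c in enumerate(sets)
    }
    fractions = {k: v / len(table) for k, v in counts.items()}
    return LibraryReport(
        results=results,
        criteria_names=names,
        pass_counts=counts,
        pass_fractions=fractions,
        n_records=len(table),
    )
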