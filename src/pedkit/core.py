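"""Pedigree data model, structural validation, and graph traversal.

A :class:`Pedigree` is a collection of :class:`Individual` records keyed
by id, forming a directed acyclic parent-to-child graph.  Individuals
with no recorded parents are *founders*; an individual named as a parent
but never registered is auto-created as an unknown-sex founder, matching
the convention that unknown parents receive founder status.

All mutations are atomic: a rejected mutation raises before touching any
state, so a pedigree that validated before a call still validates after
it.  Mutating methods return the list of :class:`Event` records they
produced, which the persistence layer turns into audit entries.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Iterator, Mapping

from .errors import (
    CycleError,
    DependencyError,
    DomainError,
    DuplicateIdError,
    SameParentError,
    SelfParentError,
    SexRoleError,
    UnknownIdError,
)

__all__ = [
    "Sex",
    "Individual",
    "Event",
    "Violation",
    "ValidationReport",
    "Pedigree",
    "add_individual",
    "set_parents",
    "validate",
    "founders",
    "ancestors",
    "edge_list",
]


class Sex(enum.Enum):
    """Recorded sex of an animal; files encode male=1, female=2, unknown=0."""

    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"

    @property
    def code(self) -> int:
        return {"male": 1, "female": 2, "unknown": 0}[self.value]

    @classmethod
    def parse(cls, value: object) -> "Sex":
        """Accept enum members, 0/1/2 codes, or words (m/f/male/female/...)."""
        if isinstance(value, cls):
            return value
        text = str(value).strip().lower()
        table = {
            "1": cls.MALE, "m": cls.MALE, "male": cls.MALE,
            "2": cls.FEMALE, "f": cls.FEMALE, "female": cls.FEMALE,
            "0": cls.UNKNOWN, "u": cls.UNKNOWN, "unknown": cls.UNKNOWN,
            "": cls.UNKNOWN,
        }
        try:
            return table[text]
        except KeyError:
            raise DomainError(f"unparseable sex value: {value!r}") from None


def _as_founder_f(value: object) -> Fraction:
    f = Fraction(value) if not isinstance(value, Fraction) else value
    if not 0 <= f < 1:
        raise DomainError(f"founder_f must lie in [0, 1), got {f}")
    return f


@dataclass(frozen=True)
class Individual:
    """One animal: identity, sex, parent links, and optional founder F.

    ``founder_f`` is the known inbreeding coefficient of a founder (an
    animal whose parents are not recorded); it defaults to 0 and is
    meaningful only while both parent slots are empty.  ``meta`` holds
    uninterpreted extra columns carried through spreadsheet round-trips.
    """

    id: str
    sex: Sex = Sex.UNKNOWN
    sire_id: str | None = None
    dam_id: str | None = None
    founder_f: Fraction = Fraction(0)
    label: str | None = None
    meta: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ident = self.id.strip() if isinstance(self.id, str) else self.id
        if not ident:
            raise DomainError("individual id must be a non-empty string")
        object.__setattr__(self, "id", ident)
        for slot in ("sire_id", "dam_id"):
            val = getattr(self, slot)
            if val is not None:
                val = val.strip()
                object.__setattr__(self, slot, val or None)
        object.__setattr__(self, "sex", Sex.parse(self.sex))
        object.__setattr__(self, "founder_f", _as_founder_f(self.founder_f))
        if self.sire_id == self.id or self.dam_id == self.id:
            raise SelfParentError(
                f"{self.id!r} cannot be its own parent", ids=(self.id,)
            )
        if self.sire_id is not None and self.sire_id == self.dam_id:
            raise SameParentError(
                f"{self.id!r}: sire and dam are the same animal "
                f"({self.sire_id!r})",
                ids=(self.id, self.sire_id),
            )
        if self.is_founder:
            pass
        elif self.founder_f != 0:
            raise DomainError(
                f"{self.id!r}: founder_f is only meaningful for founders"
            )

    @property
    def is_founder(self) -> bool:
        return self.sire_id is None and self.dam_id is None

    @property
    def parent_ids(self) -> tuple[str, ...]:
        return tuple(p for p in (self.sire_id, self.dam_id) if p is not None)

    def to_record(self) -> dict:
        """Plain-dict snapshot used by audit payloads and store snapshots."""
        return {
            "id": self.id,
            "sex": self.sex.value,
            "sire_id": self.sire_id,
            "dam_id": self.dam_id,
            "founder_f": str(self.founder_f),
            "label": self.label,
            "meta": dict(self.meta),
        }

    @classmethod
    def from_record(cls, rec: Mapping) -> "Individual":
        return cls(
            id=rec["id"],
            sex=Sex.parse(rec.get("sex", "unknown")),
            sire_id=rec.get("sire_id"),
            dam_id=rec.get("dam_id"),
            founder_f=Fraction(rec.get("founder_f", 0) or 0),
            label=rec.get("label"),
            meta=dict(rec.get("meta") or {}),
        )


@dataclass(frozen=True)
class Event:
    """Side effect of one pedigree mutation, consumed by the audit log."""

    action: str  # add | update | delete | sex_inferred
    entity_id: str
    before: dict | None
    after: dict | None


@dataclass(frozen=True)
class Violation:
    rule_code: str
    ids: tuple[str, ...]
    message: str


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[Violation, ...]

    @property
    def is_valid(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.is_valid:
            return "valid pedigree (no violations)"
        return "\n".join(
            f"{v.rule_code} [{', '.join(v.ids)}]: {v.message}"
            for v in self.violations
        )


_ROLE_FORBIDDEN = {"sire": Sex.FEMALE, "dam": Sex.MALE}
_ROLE_FIXES_TO = {"sire": Sex.MALE, "dam": Sex.FEMALE}


class Pedigree:
    """Validated, order-independent collection of individuals.

    Iteration and ``ids()`` are always in lexicographic id order so that
    every derived artifact (exports, matrices, reports) is deterministic.
    """

    def __init__(self, members: Iterable[Individual] = ()) -> None:
        self._members: dict[str, Individual] = {}
        for rec in members:
            self.add_individual(rec)

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, ident: str) -> bool:
        return ident in self._members

    def __iter__(self) -> Iterator[Individual]:
        for ident in self.ids():
            yield self._members[ident]

    def __getitem__(self, ident: str) -> Individual:
        try:
            return self._members[ident]
        except KeyError:
            raise UnknownIdError(f"no individual with id {ident!r}", ids=(ident,))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return self._members == other._members

    def ids(self) -> list[str]:
        return sorted(self._members)

    def copy(self) -> "Pedigree":
        clone = Pedigree()
        clone._members = dict(self._members)
        return clone

    # -- mutations ----------------------------------------------------------

    def add_individual(self, rec: Individual, *, infer_sex: bool = True) -> list[Event]:
        """Register a new animal; named-but-absent parents are auto-created
        as unknown-sex founders.  ``infer_sex=False`` (used by bulk
        imports, where the file's recorded sexes are authoritative)
        suppresses role-based sex fixing of unknown-sex parents."""
        if rec.id in self._members:
            raise DuplicateIdError(
                f"id {rec.id!r} is already registered", ids=(rec.id,)
            )
        events = self._check_parent_roles(rec, infer=infer_sex)
        # A new member has no children, so it cannot close a cycle; the
        # auto-created parents are founders and cannot either.
        for parent_id in rec.parent_ids:
            if parent_id not in self._members:
                ghost = Individual(id=parent_id, sex=Sex.UNKNOWN)
                self._members[parent_id] = ghost
                events.append(Event("add", parent_id, None, ghost.to_record()))
        self._members[rec.id] = rec
        events.append(Event("add", rec.id, None, rec.to_record()))
        return events

    def set_parents(
        self,
        child_id: str,
        sire_id: str | None = None,
        dam_id: str | None = None,
        *,
        infer_sex: bool = True,
    ) -> list[Event]:
        """Rewrite the parent links of an existing animal."""
        child = self[child_id]
        if sire_id is not None:
            sire_id = sire_id.strip() or None
        if dam_id is not None:
            dam_id = dam_id.strip() or None
        if child_id in (sire_id, dam_id):
            raise SelfParentError(
                f"{child_id!r} cannot be its own parent", ids=(child_id,)
            )
        if sire_id is not None and sire_id == dam_id:
            raise SameParentError(
                f"{child_id!r}: sire and dam are the same animal ({sire_id!r})",
                ids=(child_id, sire_id),
            )
        new_child = replace(
            child,
            sire_id=sire_id,
            dam_id=dam_id,
            founder_f=child.founder_f if (sire_id is None and dam_id is None)
            else Fraction(0),
        )
        # Cycle check first (it must precede any sex-fixing side effect so a
        # rejected call leaves the pedigree untouched): the child must not
        # already be an ancestor of either new parent.
        for parent_id in new_child.parent_ids:
            if parent_id in self._members and (
                child_id in self._ancestors_of(parent_id)
            ):
                raise CycleError(
                    f"setting {parent_id!r} as parent of {child_id!r} "
                    "would make the pedigree cyclic",
                    ids=(child_id, parent_id),
                )
        events = self._check_parent_roles(new_child, infer=infer_sex)
        for parent_id in new_child.parent_ids:
            if parent_id not in self._members:
                ghost = Individual(id=parent_id, sex=Sex.UNKNOWN)
                self._members[parent_id] = ghost
                events.append(Event("add", parent_id, None, ghost.to_record()))
        self._members[child_id] = new_child
        events.append(
            Event("update", child_id, child.to_record(), new_child.to_record())
        )
        return events

    def remove_individual(self, ident: str) -> list[Event]:
        """Delete an animal; refused while other records reference it."""
        rec = self[ident]
        children = [c.id for c in self if ident in c.parent_ids]
        if children:
            raise DependencyError(
                f"cannot remove {ident!r}: recorded as parent of "
                f"{', '.join(sorted(children))}",
                ids=(ident, *children),
            )
        del self._members[ident]
        return [Event("delete", ident, rec.to_record(), None)]

    def _check_parent_roles(self, rec: Individual, *, infer: bool = True) -> list[Event]:
        """Validate sire/dam sexes; fix the sex of registered unknown-sex
        parents to match their role (sire -> male, dam -> female)."""
        events: list[Event] = []
        fixes: list[tuple[Individual, Individual]] = []
        for role, parent_id in (("sire", rec.sire_id), ("dam", rec.dam_id)):
            if parent_id is None or parent_id not in self._members:
                continue
            parent = self._members[parent_id]
            if parent.sex is _ROLE_FORBIDDEN[role]:
                raise SexRoleError(
                    f"{parent_id!r} is recorded as {parent.sex.value} and "
                    f"cannot serve as {role} of {rec.id!r}",
                    ids=(rec.id, parent_id),
                )
            if infer and parent.sex is Sex.UNKNOWN:
                fixes.append((parent, replace(parent, sex=_ROLE_FIXES_TO[role])))
        for parent, fixed in fixes:  # applied only once both roles validated
            self._members[parent.id] = fixed
            events.append(
                Event("sex_inferred", parent.id,
                      parent.to_record(), fixed.to_record())
            )
        return events

    # -- queries ------------------------------------------------------------

    def founders(self) -> set[str]:
        return {rec.id for rec in self._members.values() if rec.is_founder}

    def _ancestors_of(self, ident: str) -> set[str]:
        seen: set[str] = set()
        stack = [p for p in self._members[ident].parent_ids]
        while stack:
            current = stack.pop()
            if current in seen or current not in self._members:
                continue
            seen.add(current)
            stack.extend(self._members[current].parent_ids)
        return seen

    def ancestors(self, ident: str) -> set[str]:
        """Transitive closure over parent links, excluding ``ident``."""
        if ident not in self._members:
            raise UnknownIdError(f"no individual with id {ident!r}", ids=(ident,))
        return self._ancestors_of(ident)

    def children_of(self, ident: str) -> list[str]:
        return sorted(c.id for c in self if ident in c.parent_ids)

    def edge_list(self) -> list[tuple[str, str, str]]:
        """All known parent->child edges, sorted lexicographically."""
        edges = []
        for rec in self._members.values():
            if rec.sire_id is not None:
                edges.append((rec.sire_id, rec.id, "sire"))
            if rec.dam_id is not None:
                edges.append((rec.dam_id, rec.id, "dam"))
        return sorted(edges)

    def generation_depth(self) -> dict[str, int]:
        """Longest founder-to-individual path length for every member."""
        depth: dict[str, int] = {}

        def visit(ident: str) -> int:
            if ident in depth:
                return depth[ident]
            rec = self._members[ident]
            parents = [p for p in rec.parent_ids if p in self._members]
            depth[ident] = 1 + max(map(visit, parents)) if parents else 0
            return depth[ident]

        for ident in self._members:
            visit(ident)
        return depth

    def validate(self) -> ValidationReport:
        """Report every structural violation; never raises."""
        violations: list[Violation] = []
        for rec in self:
            if rec.id in (rec.sire_id, rec.dam_id):
                violations.append(Violation(
                    SelfParentError.rule_code, (rec.id,),
                    f"{rec.id!r} is recorded as its own parent"))
            if rec.sire_id is not None and rec.sire_id == rec.dam_id:
                violations.append(Violation(
                    SameParentError.rule_code, (rec.id, rec.sire_id),
                    f"{rec.id!r} lists the same animal as sire and dam"))
            for role, parent_id in (("sire", rec.sire_id), ("dam", rec.dam_id)):
                if parent_id is None:
                    continue
                if parent_id not in self._members:
                    violations.append(Violation(
                        UnknownIdError.rule_code, (rec.id, parent_id),
                        f"{role} {parent_id!r} of {rec.id!r} is not registered"))
                elif self._members[parent_id].sex is _ROLE_FORBIDDEN[role]:
                    violations.append(Violation(
                        SexRoleError.rule_code, (rec.id, parent_id),
                        f"{parent_id!r} serves as {role} of {rec.id!r} but is "
                        f"recorded as {self._members[parent_id].sex.value}"))
            if not rec.is_founder and rec.founder_f != 0:
                violations.append(Violation(
                    DomainError.rule_code, (rec.id,),
                    f"{rec.id!r} has founder_f set but recorded parents"))
        violations.extend(self._cycle_violations())
        return ValidationReport(tuple(violations))

    def _cycle_violations(self) -> list[Violation]:
        WHITE, GREY, BLACK = 0, 1, 2
        color = dict.fromkeys(self._members, WHITE)
        cycles: list[Violation] = []

        def visit(ident: str) -> None:
            stack = [(ident, iter(self._members[ident].parent_ids))]
            color[ident] = GREY
            while stack:
                node, parents = stack[-1]
                advanced = False
                for parent in parents:
                    if parent not in self._members:
                        continue
                    if color[parent] == GREY:
                        cycles.append(Violation(
                            CycleError.rule_code, (node, parent),
                            f"circular parentage through {parent!r}"))
                    elif color[parent] == WHITE:
                        color[parent] = GREY
                        stack.append((parent, iter(self._members[parent].parent_ids)))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()

        for ident in self.ids():
            if color[ident] == WHITE:
                visit(ident)
        return cycles


# -- module-level functional wrappers ---------------------------------------

def add_individual(ped: Pedigree, rec: Individual) -> Pedigree:
    ped.add_individual(rec)
    return ped


def set_parents(
    ped: Pedigree, child_id: str,
    sire_id: str | None = None, dam_id: str | None = None,
) -> Pedigree:
    ped.set_parents(child_id, sire_id, dam_id)
    return ped


def validate(ped: Pedigree) -> ValidationReport:
    return ped.validate()


def founders(ped: Pedigree) -> set[str]:
    return ped.founders()


def ancestors(ped: Pedigree, ident: str) -> set[str]:
    return ped.ancestors(ident)


def edge_list(ped: Pedigree) -> list[tuple[str, str, str]]:
    return ped.edge_list()
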