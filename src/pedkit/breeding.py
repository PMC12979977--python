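"""Virtual breeding: simulate matings and preview offspring inbreeding.

A :class:`BreedingSession` overlays an ordered set of provisional
(virtual) offspring on a permanent pedigree.  Proposing a mating never
touches the permanent store; the prospective offspring's F and risk
band are computed over the combined view in real time.  Virtual
animals may themselves parent further proposals (multi-generation
planning chains), remain hypothetical, be discarded, or be committed —
at which point they become permanent records and audit entries are
written.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .core import Individual, Pedigree, Sex
from .errors import (
    DependencyError,
    DuplicateIdError,
    SameParentError,
    UnknownIdError,
)
from .relatedness import KinshipCalculator, RiskBand, classify_f

__all__ = ["VirtualOffspring", "BreedingSession", "propose", "commit", "discard"]


@dataclass
class VirtualOffspring:
    """A hypothetical child of a selected sire x dam, uncommitted until
    confirmed.  ``f`` is computed at proposal time over the combined
    pedigree and recomputed against the permanent store on commit."""

    id: str
    sire_id: str
    dam_id: str
    sex: Sex = Sex.UNKNOWN
    f: Fraction = Fraction(0)
    band: RiskBand = RiskBand.NONE
    committed: bool = False


class BreedingSession:
    """One planning session over a permanent pedigree (or store).

    ``target`` is either a bare :class:`Pedigree` or a persistence-layer
    store exposing ``pedigree`` and ``add_individual(rec, action=...)``;
    with a store, commits are written through it so every committed
    virtual animal lands in the audit trail.
    """

    def __init__(self, target: Pedigree | object) -> None:
        if isinstance(target, Pedigree):
            self._store = None
            self._base = target
        else:
            self._store = target
            self._base = target.pedigree
        self.provisional: dict[str, VirtualOffspring] = {}

    @property
    def base(self) -> Pedigree:
        return self._base

    def combined(self) -> Pedigree:
        """The permanent pedigree plus all provisional offspring."""
        view = self._base.copy()
        for virt in self.provisional.values():
            view.add_individual(Individual(
                id=virt.id, sex=virt.sex,
                sire_id=virt.sire_id, dam_id=virt.dam_id,
            ))
        return view

    def propose(
        self, sire: str, dam: str, child_id: str,
        sex: Sex | str = Sex.UNKNOWN,
    ) -> VirtualOffspring:
        """Simulate a mating; returns the virtual offspring with its
        prospective F and risk band.  The permanent store is unchanged."""
        if sire == dam:
            raise SameParentError(
                "sire and dam must be distinct animals", ids=(sire,)
            )
        view = self.combined()
        for ident in (sire, dam):
            if ident not in view:
                raise UnknownIdError(
                    f"no individual with id {ident!r}", ids=(ident,)
                )
        if child_id in view:
            raise DuplicateIdError(
                f"id {child_id!r} is already in use", ids=(child_id,)
            )
        # Raises SexRoleError on role conflicts; mutates only the view.
        view.add_individual(Individual(
            id=child_id, sex=sex, sire_id=sire, dam_id=dam,
        ))
        f = KinshipCalculator(view).phi(sire, dam)
        virt = VirtualOffspring(
            id=child_id, sire_id=sire, dam_id=dam,
            sex=Sex.parse(sex), f=f, band=classify_f(f),
        )
        self.provisional[child_id] = virt
        return virt

    def _provisional_ancestry(self, child_id: str) -> list[str]:
        """Provisional ancestors of a proposal (including itself), in
        topological (parents-first) order."""
        order: list[str] = []
        seen: set[str] = set()

        def visit(ident: str) -> None:
            if ident in seen or ident not in self.provisional:
                return
            seen.add(ident)
            virt = self.provisional[ident]
            visit(virt.sire_id)
            visit(virt.dam_id)
            order.append(ident)

        visit(child_id)
        return order

    def commit(self, child_id: str, *, cascade: bool = True) -> Pedigree:
        """Make a virtual offspring permanent.

        Provisional ancestors are committed first, in topological
        order; with ``cascade=False`` their presence is an error
        instead.  F is recomputed against the permanent pedigree after
        each insertion, so the stored chain is self-consistent.
        """
        if child_id not in self.provisional:
            raise UnknownIdError(
                f"no provisional offspring with id {child_id!r}", ids=(child_id,)
            )
        chain = self._provisional_ancestry(child_id)
        if len(chain) > 1 and not cascade:
            raise DependencyError(
                f"{child_id!r} depends on uncommitted provisional ancestors "
                f"{', '.join(chain[:-1])} and cascade is disabled",
                ids=tuple(chain),
            )
        for ident in chain:
            virt = self.provisional[ident]
            rec = Individual(
                id=virt.id, sex=virt.sex,
                sire_id=virt.sire_id, dam_id=virt.dam_id,
            )
            if self._store is not None:
                self._store.add_individual(rec, action="commit_virtual")
                self._base = self._store.pedigree
            else:
                self._base.add_individual(rec)
            virt.f = KinshipCalculator(self._base).f(virt.id)
            virt.band = classify_f(virt.f)
            virt.committed = True
            del self.provisional[ident]
        return self._base

    def discard(self, child_id: str) -> "BreedingSession":
        """Drop a proposal and every provisional descendant of it; the
        permanent store and its audit log are untouched."""
        if child_id not in self.provisional:
            raise UnknownIdError(
                f"no provisional offspring with id {child_id!r}", ids=(child_id,)
            )
        doomed = {child_id}
        changed = True
        while changed:
            changed = False
            for ident, virt in self.provisional.items():
                if ident not in doomed and (
                    virt.sire_id in doomed or virt.dam_id in doomed
                ):
                    doomed.add(ident)
                    changed = True
        for ident in doomed:
            del self.provisional[ident]
        return self


# -- functional wrappers ----------------------------------------------------

def propose(
    session: BreedingSession, sire: str, dam: str, child_id: str,
    sex: Sex | str = Sex.UNKNOWN,
) -> VirtualOffspring:
    return session.propose(sire, dam, child_id, sex)


def commit(session: BreedingSession, child_id: str, *, cascade: bool = True) -> Pedigree:
    return session.commit(child_id, cascade=cascade)


def discard(session: BreedingSession, child_id: str) -> BreedingSession:
    return session.discard(child_id)
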