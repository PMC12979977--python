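"""Exact kinship and inbreeding computation with risk classification.

Two independent routes are provided:

* :func:`kinship` — the recursive tabular (coancestry) method.  For two
  distinct animals where ``a`` is not an ancestor of ``b``,
  ``phi(a, b) = 1/2 * (phi(sire_a, b) + phi(dam_a, b))``, a missing
  parent contributing 0 as an unrelated non-inbred founder; on the
  diagonal ``phi(x, x) = 1/2 * (1 + F_x)``.  Memoized, so each pair
  costs linear work after caching.  This is the production path.

* :func:`wright_f` — generalized Wright path counting.  Every
  common-ancestor loop (a sire-side leg and a dam-side leg meeting at
  ancestor X, sharing no individual except X) contributes
  ``(1/2)^(n_a + n_b + 1) * (1 + F_X)``.  The ``(1 + F_X)`` factor
  extends the textbook formula (which assumes non-inbred common
  ancestors) to arbitrary pedigrees; without it, chains in which a
  common ancestor is itself inbred are not reproduced.  Enumeration is
  exponential in pedigree depth and is reserved for verification on
  small pedigrees.

An offspring's inbreeding coefficient F equals the kinship of its
parents, so the two routes must agree exactly; all arithmetic uses
:class:`fractions.Fraction` (every pedigree F is a dyadic rational).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from fractions import Fraction

import numpy as np
import pandas as pd

from .core import Individual, Pedigree
from .errors import DomainError, InvalidPedigreeError, SameParentError

__all__ = [
    "RiskBand",
    "KinshipValue",
    "AncestorPath",
    "FResult",
    "classify_f",
    "kinship",
    "inbreeding",
    "kinship_matrix",
    "wright_paths",
    "wright_f",
    "format_f",
    "PATH_ENUMERATION_LIMIT",
]

#: wright_paths refuses pedigrees larger than this unless overridden;
#: path enumeration is exponential and meant for small-pedigree checks.
PATH_ENUMERATION_LIMIT = 64


class RiskBand(enum.Enum):
    """Five-level inbreeding-risk classification.

    Anchored to relationship equivalences: first cousins (F = 0.0625),
    half sibs (0.125), and full sibs / parent-offspring (0.25).
    Intervals are closed on the left: a boundary value belongs to the
    higher band.
    """

    NONE = "None"
    LOW = "Low"
    MODERATE = "Moderate"
    HIGH = "High"
    VERY_HIGH = "Very High"


def classify_f(f: Fraction | float) -> RiskBand:
    """Classify an inbreeding coefficient into its risk band."""
    f = Fraction(f)
    if not 0 <= f < 1:
        raise DomainError(f"inbreeding coefficient must lie in [0, 1), got {f}")
    if f == 0:
        return RiskBand.NONE
    if f < Fraction(1, 16):
        return RiskBand.LOW
    if f < Fraction(1, 8):
        return RiskBand.MODERATE
    if f < Fraction(1, 4):
        return RiskBand.HIGH
    return RiskBand.VERY_HIGH


def format_f(f: Fraction | float, places: int = 4) -> str:
    """Render F as a fixed-point decimal, half-even rounding."""
    quantum = Decimal(1).scaleb(-places)
    frac = Fraction(f)
    dec = Decimal(frac.numerator) / Decimal(frac.denominator)
    return str(dec.quantize(quantum, rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class KinshipValue:
    pair: tuple[str, str]
    phi: Fraction

    def __float__(self) -> float:
        return float(self.phi)


@dataclass(frozen=True)
class FResult:
    individual_id: str
    f: Fraction
    band: RiskBand

    def __float__(self) -> float:
        return float(self.f)


@dataclass(frozen=True)
class AncestorPath:
    """One common-ancestor loop in Wright's decomposition.

    ``n_a``/``n_b`` are the parent-offspring step counts from the
    common ancestor to the sire-side and dam-side endpoints; ``f_x`` is
    the ancestor's own inbreeding coefficient.
    """

    ancestor_id: str
    n_a: int
    n_b: int
    f_x: Fraction

    @property
    def contribution(self) -> Fraction:
        return Fraction(1, 2) ** (self.n_a + self.n_b + 1) * (1 + self.f_x)


def _require_valid(ped: Pedigree) -> None:
    report = ped.validate()
    if not report.is_valid:
        raise InvalidPedigreeError(
            f"pedigree fails validation:\n{report}",
            ids=tuple(i for v in report.violations for i in v.ids),
        )


class KinshipCalculator:
    """Memoized recursive coancestry over one (validated) pedigree.

    Reusable across many queries; build once per pedigree state.
    """

    def __init__(self, ped: Pedigree, *, validate: bool = True) -> None:
        if validate:
            _require_valid(ped)
        self._ped = ped
        self._depth = ped.generation_depth()
        self._phi: dict[frozenset[str], Fraction] = {}

    def _parents(self, ident: str) -> tuple[str | None, str | None]:
        rec = self._ped[ident]
        return rec.sire_id, rec.dam_id

    def phi(self, a: str, b: str) -> Fraction:
        """Kinship coefficient phi(a, b)."""
        self._ped[a], self._ped[b]  # raise UnknownIdError early
        return self._phi_known(a, b)

    def _phi_known(self, a: str, b: str) -> Fraction:
        if a == b:
            return Fraction(1, 2) * (1 + self.f(a))
        key = frozenset((a, b))
        cached = self._phi.get(key)
        if cached is not None:
            return cached
        # Expand the deeper individual: with longest-path depths an
        # ancestor is always strictly shallower than its descendant, so
        # the expanded one is never an ancestor of the other.
        if self._depth[a] < self._depth[b]:
            a, b = b, a
        sire, dam = self._parents(a)
        value = Fraction(1, 2) * (
            (self._phi_known(sire, b) if sire is not None else Fraction(0))
            + (self._phi_known(dam, b) if dam is not None else Fraction(0))
        )
        self._phi[key] = value
        return value

    def f(self, ident: str) -> Fraction:
        """Inbreeding coefficient: kinship of the parents, or the
        recorded founder F; a missing parent forces F = 0."""
        rec = self._ped[ident]
        if rec.is_founder:
            return rec.founder_f
        if rec.sire_id is None or rec.dam_id is None:
            return Fraction(0)
        return self._phi_known(rec.sire_id, rec.dam_id)


def kinship(ped: Pedigree, a: str, b: str) -> KinshipValue:
    """Kinship (coancestry) phi between two animals."""
    return KinshipValue(pair=(a, b), phi=KinshipCalculator(ped).phi(a, b))


def inbreeding(ped: Pedigree, ident: str) -> FResult:
    """Inbreeding coefficient F of one animal, with its risk band."""
    f = KinshipCalculator(ped).f(ident)
    return FResult(individual_id=ident, f=f, band=classify_f(f))


def kinship_matrix(ped: Pedigree) -> pd.DataFrame:
    """Full symmetric kinship matrix as a float DataFrame.

    Rows/columns are all member ids in lexicographic order; the
    diagonal is ``1/2 * (1 + F)``.  Twice this matrix is the numerator
    relationship matrix (symmetric positive semidefinite).
    """
    calc = KinshipCalculator(ped)
    ids = ped.ids()
    n = len(ids)
    mat = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j in range(i, n):
            mat[i, j] = mat[j, i] = float(calc._phi_known(a, ids[j]))
    return pd.DataFrame(mat, index=ids, columns=ids)


# -- Wright path counting ---------------------------------------------------

def _ascending_paths(ped: Pedigree, start: str, target: str) -> list[tuple[str, ...]]:
    """All simple parent-ward paths from ``start`` up to ``target``."""
    paths: list[tuple[str, ...]] = []

    def walk(node: str, trail: tuple[str, ...]) -> None:
        if node == target:
            paths.append(trail)
            return
        for parent in ped[node].parent_ids:
            if parent in ped and parent not in trail:
                walk(parent, trail + (parent,))

    walk(start, (start,))
    return paths


def wright_paths(
    ped: Pedigree, sire: str, dam: str, *, max_members: int = PATH_ENUMERATION_LIMIT
) -> list[AncestorPath]:
    """Enumerate every common-ancestor loop between a prospective pair.

    A loop pairs one sire-side leg with one dam-side leg, each a simple
    parent-ward path ending at the common ancestor X, the two sharing
    no individual except X.  Results are ordered by (ancestor id, n_a,
    n_b).  Refuses pedigrees above ``max_members`` (enumeration is
    exponential; raise the limit explicitly for larger checks).
    """
    _require_valid(ped)
    if sire == dam:
        raise SameParentError(
            "sire and dam must be distinct animals", ids=(sire,)
        )
    if len(ped) > max_members:
        raise DomainError(
            f"path enumeration limited to {max_members} members "
            f"(pedigree has {len(ped)}); pass max_members to override"
        )
    ped[sire], ped[dam]
    f_cache: dict[str, Fraction] = {}

    def wright_f_of(ident: str) -> Fraction:
        # F of a common ancestor, computed by path counting itself so
        # this route never leans on the recursive method.
        if ident in f_cache:
            return f_cache[ident]
        rec: Individual = ped[ident]
        if rec.is_founder:
            value = rec.founder_f
        elif rec.sire_id is None or rec.dam_id is None:
            value = Fraction(0)
        else:
            value = sum(
                (p.contribution for p in _loops(rec.sire_id, rec.dam_id)),
                Fraction(0),
            )
        f_cache[ident] = value
        return value

    def _loops(s: str, d: str) -> list[AncestorPath]:
        found: list[AncestorPath] = []
        shared = ({s} | ped.ancestors(s)) & ({d} | ped.ancestors(d))
        for x in sorted(shared):
            for leg_a in _ascending_paths(ped, s, x):
                body_a = set(leg_a[:-1])
                for leg_b in _ascending_paths(ped, d, x):
                    if body_a.isdisjoint(leg_b[:-1]):
                        found.append(AncestorPath(
                            ancestor_id=x,
                            n_a=len(leg_a) - 1,
                            n_b=len(leg_b) - 1,
                            f_x=wright_f_of(x),
                        ))
        found.sort(key=lambda p: (p.ancestor_id, p.n_a, p.n_b))
        return found

    return _loops(sire, dam)


def wright_f(
    ped: Pedigree, sire: str, dam: str, *, max_members: int = PATH_ENUMERATION_LIMIT
) -> Fraction:
    """Prospective offspring F by generalized Wright path counting."""
    return sum(
        (p.contribution for p in wright_paths(ped, sire, dam, max_members=max_members)),
        Fraction(0),
    )
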