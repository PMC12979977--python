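"""Durable record store, audit trail, and import/export.

The storage contract is an append-only audit log plus a portable
snapshot: every mutating transaction on a :class:`PedigreeStore` emits
time-stamped :class:`AuditEntry` records (with monotonic sequence
numbers breaking timestamp ties), and replaying the log over an empty
store reconstructs the exact pedigree state.  Snapshots are single
JSON files holding both the member records and the log.

Spreadsheet exchange uses the template CSV header
``id,sex,sire,dam,f,label`` (sex coded 1=male, 2=female, 0=unknown;
words accepted on import; blank cell = unknown parent).  The ``f``
column is output-only: on import it is checked against recomputation
and disagreements surface as warnings, never as stored values — except
for founder rows, where a supplied ``f`` is the only way to declare a
known-inbred founder and is adopted as its founder F.  Extra columns
are carried through verbatim but uninterpreted.

Pedigree graphs export as Graphviz DOT: box = male, ellipse = female,
diamond = unknown sex; labels carry the id and F (4 decimals); fill
color encodes the risk band.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, replace
from datetime import datetime, timezone
from fractions import Fraction
from pathlib import Path
from typing import Iterable

from .core import Individual, Pedigree, Sex, ValidationReport, Violation
from .errors import CorruptLogError, FormatError, PedkitError
from .relatedness import KinshipCalculator, classify_f, format_f

__all__ = [
    "AuditEntry",
    "PedigreeStore",
    "import_table",
    "export_table",
    "export_dot",
    "replay",
    "snapshot",
    "restore",
    "export_audit_csv",
]

AUDIT_ACTIONS = frozenset(
    {"add", "update", "delete", "commit_virtual", "import", "sex_inferred"}
)

_TEMPLATE_COLUMNS = ("id", "sex", "sire", "dam", "f", "label")
_REQUIRED_COLUMNS = ("id", "sex", "sire", "dam")

_F_MISMATCH = "F_MISMATCH"


@dataclass(frozen=True)
class AuditEntry:
    """One time-stamped transaction on the store (append-only)."""

    timestamp: str  # ISO-8601 UTC
    seq: int
    action: str
    entity_id: str
    payload: dict  # {"before": record|None, "after": record|None}

    def to_json(self) -> dict:
        return {
            "timestamp": self.timestamp,
            "seq": self.seq,
            "action": self.action,
            "entity_id": self.entity_id,
            "payload": self.payload,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "AuditEntry":
        try:
            entry = cls(
                timestamp=obj["timestamp"],
                seq=int(obj["seq"]),
                action=obj["action"],
                entity_id=obj["entity_id"],
                payload=dict(obj["payload"]),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise CorruptLogError(f"malformed audit entry: {obj!r}") from exc
        if entry.action not in AUDIT_ACTIONS:
            raise CorruptLogError(f"unknown audit action {entry.action!r}")
        return entry


class PedigreeStore:
    """A pedigree plus its append-only audit trail.

    All mutations go through the store so that every transaction is
    logged; the wrapped pedigree is exposed read-only via ``pedigree``.
    """

    def __init__(self) -> None:
        self._ped = Pedigree()
        self._log: list[AuditEntry] = []
        self._seq = 0

    @property
    def pedigree(self) -> Pedigree:
        return self._ped

    @property
    def log(self) -> tuple[AuditEntry, ...]:
        return tuple(self._log)

    def _stamp(self, action: str, entity_id: str, payload: dict) -> AuditEntry:
        self._seq += 1
        entry = AuditEntry(
            timestamp=datetime.now(timezone.utc).isoformat(timespec="microseconds"),
            seq=self._seq,
            action=action,
            entity_id=entity_id,
            payload=payload,
        )
        self._log.append(entry)
        return entry

    def record(self, action: str, entity_id: str, payload: dict) -> AuditEntry:
        """Append one entry to the audit trail."""
        if action not in AUDIT_ACTIONS:
            raise CorruptLogError(f"unknown audit action {action!r}")
        return self._stamp(action, entity_id, payload)

    def _log_events(self, events, action_override: str | None = None) -> None:
        for ev in events:
            action = ev.action
            if action_override is not None and action == "add":
                action = action_override
            self._stamp(action, ev.entity_id,
                        {"before": ev.before, "after": ev.after})

    # -- mutating transactions ---------------------------------------------

    def add_individual(self, rec: Individual, *, action: str = "add") -> None:
        self._log_events(self._ped.add_individual(rec),
                         None if action == "add" else action)

    def set_parents(self, child_id: str, sire_id: str | None = None,
                    dam_id: str | None = None) -> None:
        self._log_events(self._ped.set_parents(child_id, sire_id, dam_id))

    def remove_individual(self, ident: str) -> None:
        self._log_events(self._ped.remove_individual(ident))

    def import_pedigree(self, ped: Pedigree) -> None:
        """Absorb a whole pedigree (e.g. from a CSV import) as one
        ``import``-tagged transaction per record.

        Records are inserted parents-first so no placeholder founders
        are created, and the source's recorded sexes are kept verbatim.
        """
        depth = ped.generation_depth()
        for ident in sorted(ped.ids(), key=lambda i: (depth[i], i)):
            events = self._ped.add_individual(ped[ident], infer_sex=False)
            self._log_events(events, "import")


def replay(entries: Iterable[AuditEntry | dict], since: int = 0) -> Pedigree:
    """Reconstruct the pedigree state by applying audit entries in order.

    ``since`` skips entries with seq <= since (replay over a snapshot).
    Entries are applied primitively — each already names the exact
    before/after record — so replay is deterministic by construction.
    """
    ped = Pedigree()
    members = ped._members  # primitive application bypasses re-validation
    for raw in entries:
        entry = raw if isinstance(raw, AuditEntry) else AuditEntry.from_json(raw)
        if entry.seq <= since:
            continue
        after = entry.payload.get("after")
        if entry.action in ("add", "commit_virtual", "import"):
            if entry.entity_id in members:
                raise CorruptLogError(
                    f"log adds {entry.entity_id!r} twice (seq {entry.seq})"
                )
            members[entry.entity_id] = Individual.from_record(after)
        elif entry.action in ("update", "sex_inferred"):
            if entry.entity_id not in members:
                raise CorruptLogError(
                    f"log updates unknown {entry.entity_id!r} (seq {entry.seq})"
                )
            members[entry.entity_id] = Individual.from_record(after)
        elif entry.action == "delete":
            if entry.entity_id not in members:
                raise CorruptLogError(
                    f"log deletes unknown {entry.entity_id!r} (seq {entry.seq})"
                )
            del members[entry.entity_id]
        else:  # pragma: no cover - from_json already rejects these
            raise CorruptLogError(f"unknown audit action {entry.action!r}")
    return ped


def snapshot(store: PedigreeStore, path: str | Path) -> None:
    """Write the store (members + audit log) to one portable JSON file."""
    doc = {
        "format": "pedkit-store",
        "version": 1,
        "members": [rec.to_record() for rec in store.pedigree],
        "log": [entry.to_json() for entry in store.log],
        "seq": store._seq,
    }
    Path(path).write_text(
        json.dumps(doc, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )


def restore(path: str | Path) -> PedigreeStore:
    """Load a snapshot written by :func:`snapshot`."""
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise CorruptLogError(f"unreadable snapshot {path}: {exc}") from exc
    if doc.get("format") != "pedkit-store":
        raise CorruptLogError(f"{path} is not a pedkit store snapshot")
    store = PedigreeStore()
    ped = Pedigree()
    for rec in doc.get("members", ()):
        ped._members[rec["id"]] = Individual.from_record(rec)
    store._ped = ped
    store._log = [AuditEntry.from_json(e) for e in doc.get("log", ())]
    store._seq = int(doc.get("seq", len(store._log)))
    return store


# -- CSV template exchange --------------------------------------------------

def import_table(
    source: str | Path | io.TextIOBase, *, strict: bool = True
) -> tuple[Pedigree, ValidationReport]:
    """Build a pedigree from a template CSV.

    Rows are processed in two passes (register every id, then link
    parents) so row order never matters.  In strict mode any violation
    rejects the whole import atomically (FormatError); in lenient mode
    offending rows lose their links (or are dropped) and every problem
    is reported.  An ``f`` value that disagrees with recomputation is
    always a warning — the recomputed value wins.
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as handle:
            return import_table(handle, strict=strict)

    reader = csv.DictReader(source)
    if reader.fieldnames is None:
        raise FormatError("empty file: a header row is required")
    fields = [name.strip() for name in reader.fieldnames]
    missing = [c for c in _REQUIRED_COLUMNS if c not in fields]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    extra_cols = [c for c in fields if c not in _TEMPLATE_COLUMNS]

    rows = []
    for lineno, raw in enumerate(reader, start=2):
        rows.append((lineno, {k.strip(): (v or "").strip()
                              for k, v in raw.items() if k is not None}))

    problems: list[Violation] = []
    ped = Pedigree()
    linked: list[tuple[int, dict]] = []

    for lineno, row in rows:  # pass 1: register every id
        try:
            rec = Individual(
                id=row.get("id", ""),
                sex=Sex.parse(row.get("sex", "")),
                label=row.get("label") or None,
                meta={c: row.get(c, "") for c in extra_cols},
            )
            ped.add_individual(rec)
        except PedkitError as exc:
            problems.append(Violation(exc.rule_code, exc.ids,
                                      f"line {lineno}: {exc}"))
            continue
        if row.get("sire") or row.get("dam"):
            linked.append((lineno, row))

    for lineno, row in linked:  # pass 2: link parents
        try:
            ped.set_parents(row["id"], row.get("sire") or None,
                            row.get("dam") or None, infer_sex=False)
        except PedkitError as exc:
            problems.append(Violation(exc.rule_code, exc.ids,
                                      f"line {lineno}: {exc}"))

    # pass 3: interpret the f column — adopt founder F first, then check
    # every stated non-founder f against recomputation
    stated_f: list[tuple[int, str, Fraction]] = []
    for lineno, row in rows:
        text = row.get("f", "")
        if not text or row.get("id", "") not in ped:
            continue
        ident = row["id"]
        try:
            stated = Fraction(text)
        except (ValueError, ZeroDivisionError):
            problems.append(Violation(FormatError.rule_code, (ident,),
                                      f"line {lineno}: unparseable f {text!r}"))
            continue
        rec = ped[ident]
        if rec.is_founder and 0 < stated < 1:
            ped._members[ident] = replace(rec, founder_f=stated)
        elif not rec.is_founder:
            stated_f.append((lineno, ident, stated))

    warnings: list[Violation] = []
    if stated_f and ped.validate().is_valid:
        calc = KinshipCalculator(ped, validate=False)
        for lineno, ident, stated in stated_f:
            computed = calc.f(ident)
            if abs(stated - computed) > Fraction(1, 10**12):
                warnings.append(Violation(
                    _F_MISMATCH, (ident,),
                    f"line {lineno}: stated f={stated} disagrees with "
                    f"recomputed {format_f(computed)}; recomputed value kept",
                ))

    structural = ped.validate().violations
    report = ValidationReport(tuple(problems) + structural + tuple(warnings))
    hard = tuple(v for v in report.violations if v.rule_code != _F_MISMATCH)
    if strict and hard:
        raise FormatError(
            "import rejected (strict mode):\n"
            + "\n".join(f"{v.rule_code} [{', '.join(v.ids)}]: {v.message}"
                        for v in hard)
        )
    return ped, report


def export_table(ped: Pedigree, path: str | Path | io.TextIOBase) -> None:
    """Write the template CSV: one row per individual, lexicographic id
    order, F recomputed; extra imported columns are appended verbatim."""
    if isinstance(path, (str, Path)):
        with open(path, "w", newline="", encoding="utf-8") as handle:
            export_table(ped, handle)
        return
    calc = KinshipCalculator(ped)
    extra_cols = sorted({c for rec in ped for c in rec.meta})
    writer = csv.writer(path, lineterminator="\n")
    writer.writerow(list(_TEMPLATE_COLUMNS) + extra_cols)
    for rec in ped:
        f = calc.f(rec.id)
        writer.writerow([
            rec.id,
            rec.sex.code,
            rec.sire_id or "",
            rec.dam_id or "",
            _decimal_exact(f),
            rec.label or "",
        ] + [rec.meta.get(c, "") for c in extra_cols])


def _decimal_exact(f: Fraction) -> str:
    """Exact finite decimal for a dyadic rational (e.g. 1/16 -> 0.0625)."""
    if f == 0:
        return "0"
    num, den = f.numerator, f.denominator
    k = den.bit_length() - 1
    if den != 1 << k:  # non-dyadic founder F: fall back to high precision
        return format_f(f, places=12).rstrip("0").rstrip(".")
    digits = num * 5**k  # f = digits / 10^k
    text = str(digits).rjust(k + 1, "0")
    return (text[:-k] + "." + text[-k:]) if k else text


# -- DOT graph export -------------------------------------------------------

_BAND_FILL = {
    "None": "white",
    "Low": "palegreen",
    "Moderate": "gold",
    "High": "orange",
    "Very High": "tomato",
}
_SEX_SHAPE = {Sex.MALE: "box", Sex.FEMALE: "ellipse", Sex.UNKNOWN: "diamond"}


def export_dot(ped: Pedigree, path: str | Path | io.TextIOBase) -> None:
    """Write a Graphviz digraph of the pedigree.

    Node shape encodes sex, the label carries id and F (4 decimals),
    and the fill color encodes the risk band; edges run parent->child.
    """
    if isinstance(path, (str, Path)):
        with open(path, "w", encoding="utf-8") as handle:
            export_dot(ped, handle)
        return
    calc = KinshipCalculator(ped)
    lines = ["digraph pedigree {", "  rankdir=TB;"]
    for rec in ped:
        f = calc.f(rec.id)
        band = classify_f(f)
        lines.append(
            f'  "{rec.id}" [shape={_SEX_SHAPE[rec.sex]}, style=filled, '
            f'fillcolor="{_BAND_FILL[band.value]}", '
            f'label="{rec.label or rec.id}\\nF={format_f(f)}"];'
        )
    for parent, child, _role in ped.edge_list():
        lines.append(f'  "{parent}" -> "{child}";')
    path.write("\n".join(lines) + "\n")


def export_audit_csv(store: PedigreeStore, path: str | Path | io.TextIOBase) -> None:
    """Export the audit trail as plain CSV
    (``timestamp,seq,action,entity_id,payload``)."""
    if isinstance(path, (str, Path)):
        with open(path, "w", newline="", encoding="utf-8") as handle:
            export_audit_csv(store, handle)
        return
    writer = csv.writer(path, lineterminator="\n")
    writer.writerow(["timestamp", "seq", "action", "entity_id", "payload"])
    for entry in store.log:
        writer.writerow([
            entry.timestamp, entry.seq, entry.action, entry.entity_id,
            json.dumps(entry.payload, sort_keys=True),
        ])
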