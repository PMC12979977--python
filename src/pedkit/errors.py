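"""Exception hierarchy for pedigree validation and computation.

Every rule violation carries a stable ``rule_code`` so that batch
validation reports and CLI exit messages can be matched by scripts.
"""

from __future__ import annotations


class PedkitError(Exception):
    """Base class for all pedkit errors."""

    rule_code = "ERROR"

    def __init__(self, message: str, *, ids: tuple[str, ...] = ()) -> None:
        super().__init__(message)
        self.ids = ids


class DuplicateIdError(PedkitError):
    rule_code = "DUPLICATE_ID"


class UnknownIdError(PedkitError, KeyError):
    rule_code = "UNKNOWN_ID"

    def __str__(self) -> str:  # KeyError quotes its arg; keep the plain message
        return self.args[0] if self.args else ""


class SelfParentError(PedkitError):
    rule_code = "SELF_PARENT"


class SameParentError(PedkitError):
    rule_code = "SAME_PARENT"


class SexRoleError(PedkitError):
    rule_code = "SEX_ROLE"


class CycleError(PedkitError):
    rule_code = "CYCLE"


class DependencyError(PedkitError):
    rule_code = "DEPENDENCY"


class DomainError(PedkitError, ValueError):
    rule_code = "DOMAIN"


class InvalidPedigreeError(PedkitError):
    rule_code = "INVALID_PEDIGREE"


class FormatError(PedkitError):
    rule_code = "FORMAT"


class CorruptLogError(PedkitError):
    rule_code = "CORRUPT_LOG"
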