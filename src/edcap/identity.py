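"""Subject identity model: patient records, ID-number types with checksum
validation, and cross-device identity conflict detection.

A subject is described by a small fixed set of optional direct identifiers
(forename, surname, date of birth, sex/gender coded M/F/X, plus address,
e-mail, GP and free-text "other" details) and an arbitrary number of
numbered ID types whose meaning ("NHS number", "Research ID", ...) is
configured per server.  Whether a given combination of fields is
*sufficient* is decided elsewhere, by the identification policies in
:mod:`edcap.policy`; here any field may simply be absent.

ID-number types may declare a validation method.  The NHS number scheme is
supported: a 10-digit number whose last digit is a modulus-11 check digit
over the first nine (weights 10 down to 2; check = 11 - (sum mod 11), with
11 mapping to 0 and 10 meaning the number is unissuable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Iterable, Mapping, Optional

__all__ = [
    "Sex",
    "ValidationMethod",
    "IdNumDefinition",
    "PatientRecord",
    "IdNumVerdict",
    "IdentityConflict",
    "validate_idnum",
    "nhs_check_digit",
    "detect_identity_conflicts",
]


class Sex(str, Enum):
    M = "M"
    F = "F"
    X = "X"


class ValidationMethod(str, Enum):
    NONE = "none"
    NHS_MODULUS_11 = "nhs_modulus_11"


@dataclass(frozen=True)
class IdNumDefinition:
    """Administrator-defined meaning of one ID number type."""

    which_idnum: int
    description: str
    short_description: str = ""
    validation_method: ValidationMethod = ValidationMethod.NONE

    def __post_init__(self) -> None:
        if self.which_idnum < 1:
            raise ValueError("which_idnum must be >= 1")
        if not self.description.strip():
            raise ValueError("description must be non-empty")


# Direct-identifier attribute names, as used by the policy language.
TEXT_FIELDS = ("forename", "surname", "address", "email", "gp", "otherdetails")


@dataclass
class PatientRecord:
    """One snapshot of a subject's identity fields plus ID numbers.

    Every field may be absent (None); sufficiency is a policy question.
    """

    forename: Optional[str] = None
    surname: Optional[str] = None
    dob: Optional[date] = None
    sex: Optional[Sex] = None
    address: Optional[str] = None
    email: Optional[str] = None
    gp: Optional[str] = None
    otherdetails: Optional[str] = None
    idnums: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex is not None:
            self.sex = Sex(self.sex)
        for which, value in self.idnums.items():
            if not (isinstance(value, int) and value > 0):
                raise ValueError(
                    f"idnum {which}: values must be positive integers, got {value!r}"
                )

    def has(self, attr: str) -> bool:
        """True iff the named identity attribute is present and non-empty.

        Text fields count as present only if non-empty after trimming;
        ``idnumN`` refers to ID number type N; ``anyidnum`` is true when
        any ID number at all is present.
        """
        attr = attr.lower()
        if attr == "sex":
            return self.sex is not None
        if attr == "dob":
            return self.dob is not None
        if attr in TEXT_FIELDS:
            value = getattr(self, attr)
            return value is not None and value.strip() != ""
        if attr == "anyidnum":
            return bool(self.idnums)
        if attr.startswith("idnum"):
            try:
                which = int(attr[5:])
            except ValueError:
                raise KeyError(f"unknown identity attribute: {attr!r}") from None
            return which in self.idnums
        raise KeyError(f"unknown identity attribute: {attr!r}")


@dataclass(frozen=True)
class IdNumVerdict:
    valid: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.valid


def nhs_check_digit(first_nine: Iterable[int]) -> int:
    """Modulus-11 check digit for the first nine digits of an NHS number.

    Returns 0-9, or 10 for combinations that cannot be issued.
    """
    digits = list(first_nine)
    if len(digits) != 9:
        raise ValueError("need exactly nine digits")
    weighted = sum(d * w for d, w in zip(digits, range(10, 1, -1)))
    check = 11 - (weighted % 11)
    return 0 if check == 11 else check


def validate_idnum(defn: IdNumDefinition, value: int) -> IdNumVerdict:
    """Check an ID-number value against its type's validation method."""
    if value < 0:
        raise ValueError("ID number values must be non-negative")
    if defn.validation_method is ValidationMethod.NONE:
        if value > 0:
            return IdNumVerdict(True)
        return IdNumVerdict(False, "ID numbers must be positive")
    # NHS modulus-11
    digits = [int(c) for c in str(value)]
    if len(digits) != 10:
        return IdNumVerdict(False, f"NHS numbers have 10 digits, got {len(digits)}")
    expected = nhs_check_digit(digits[:9])
    if expected == 10:
        return IdNumVerdict(False, "invalid NHS number (check digit would be 10)")
    if digits[9] != expected:
        return IdNumVerdict(
            False, f"checksum failure (check digit {digits[9]}, expected {expected})"
        )
    return IdNumVerdict(True)


@dataclass(frozen=True)
class IdentityConflict:
    """Incompatible information across records believed to be one person."""

    field_name: str
    values_seen: tuple
    severity: str = "warning"


def _normalize(field_name: str, value) -> object:
    if field_name in ("forename", "surname") and isinstance(value, str):
        return " ".join(value.split()).lower()
    return value


def detect_identity_conflicts(
    records: Iterable[PatientRecord | Mapping],
) -> list[IdentityConflict]:
    """Compare identity records that are linked as the same subject.

    Several devices can hold copies of one patient's details, and copies may
    disagree (misspelled names, non-matching dates of birth).  A conflict is
    reported per field where two or more distinct non-absent values occur;
    an absent field is compatible with anything.  Name comparison is
    case-insensitive and whitespace-normalized.
    """
    records = [
        r if isinstance(r, PatientRecord) else PatientRecord(**r) for r in records
    ]
    if not records:
        raise ValueError("no records to compare")
    conflicts: list[IdentityConflict] = []
    fields = ("forename", "surname", "dob", "sex", "address", "email", "gp",
              "otherdetails")
    for name in fields:
        seen: dict[object, object] = {}  # normalized -> first original
        for rec in records:
            value = getattr(rec, name)
            if value is None or (isinstance(value, str) and not value.strip()):
                continue
            seen.setdefault(_normalize(name, value), value)
        if len(seen) >= 2:
            conflicts.append(IdentityConflict(name, tuple(seen.values())))
    # ID numbers: same type with two different values is also incompatible.
    idnum_seen: dict[int, set[int]] = {}
    for rec in records:
        for which, value in rec.idnums.items():
            idnum_seen.setdefault(which, set()).add(value)
    for which in sorted(idnum_seen):
        values = idnum_seen[which]
        if len(values) >= 2:
            conflicts.append(IdentityConflict(f"idnum{which}", tuple(sorted(values))))
    return conflicts
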