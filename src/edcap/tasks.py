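"""Task framework: definitions, raw-data instances, completeness/validity
checking, live summary scoring, string tables, use-context gating, and
schedule due-task computation.

The central storage principle is DRY: only raw answers are ever stored;
summary scores (a PHQ-9 total, a body-mass index) are pure functions of the
raw values and are computed live at every request.  Deleting and
recomputing all summaries therefore reproduces identical outputs.

Three exemplar tasks ship:

* ``phq9`` — the Patient Health Questionnaire-9, a nine-item depression
  questionnaire scored 0-3 per item (total 0-27), plus a tenth
  functional-impact item that is answered but not scored;
* ``bmi`` — a clinical measurement task storing height (m) and mass (kg),
  with BMI computed on demand;
* ``anon_survey`` — an intrinsically anonymous one-question survey,
  exercising the pathway in which no subject link exists at any stage.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Any, Callable, Iterable, Mapping, Optional, Sequence

from lxml import etree

from ._time import parse_iso, to_utc

__all__ = [
    "FieldSpec",
    "TaskDefinition",
    "TaskInstance",
    "CheckResult",
    "UnknownFieldError",
    "validate_instance",
    "phq9_summary",
    "bmi_summary",
    "PHQ9_SEVERITY_BANDS",
    "StringTable",
    "UseContextVerdict",
    "check_use_context",
    "Schedule",
    "ScheduleItem",
    "DueSlot",
    "tasks_due",
    "TASK_REGISTRY",
    "get_task",
]


class UnknownFieldError(KeyError):
    """An instance carries a field its task does not declare.

    Signals a malformed upload: the server will not add new fields or
    tables on the claims of an uploading agent.
    """


@dataclass(frozen=True)
class FieldSpec:
    name: str
    value_type: str  # integer | real | text | date | datetime | boolean | blob_ref
    mandatory: bool = False
    min_value: Optional[float] = None
    max_value: Optional[float] = None
    allowed_values: Optional[tuple] = None

    _PY_TYPES = {
        "integer": int,
        "real": (int, float),
        "text": str,
        "boolean": bool,
        "date": str,
        "datetime": str,
        "blob_ref": str,
    }

    def check(self, value: Any) -> Optional[str]:
        """Return a problem description for a *present* value, or None."""
        expected = self._PY_TYPES[self.value_type]
        if self.value_type == "integer" and isinstance(value, bool):
            return f"{self.name}: expected integer, got boolean"
        if not isinstance(value, expected):
            return f"{self.name}: expected {self.value_type}, got {type(value).__name__}"
        if self.allowed_values is not None and value not in self.allowed_values:
            return f"{self.name}: value {value!r} not in permitted set"
        if self.min_value is not None and value < self.min_value:
            return f"{self.name}: value {value!r} below minimum {self.min_value}"
        if self.max_value is not None and value > self.max_value:
            return f"{self.name}: value {value!r} above maximum {self.max_value}"
        return None


@dataclass(frozen=True)
class TaskDefinition:
    """Schema and behaviour of one task type."""

    table_name: str
    long_name: str
    fields: tuple[FieldSpec, ...]
    is_anonymous: bool = False
    summary_fns: Mapping[str, Callable[["TaskInstance"], Any]] = field(
        default_factory=dict
    )
    # Per use context: "allowed" or "prohibited".
    permitted_contexts: Mapping[str, str] = field(
        default_factory=lambda: {
            "clinical": "allowed",
            "research": "allowed",
            "educational": "allowed",
            "commercial": "allowed",
        }
    )
    restricted_strings: bool = False
    key_text_fn: Optional[Callable[["TaskInstance"], str]] = None

    def field_map(self) -> dict[str, FieldSpec]:
        return {f.name: f for f in self.fields}

    def key_text(self, inst: "TaskInstance") -> str:
        if self.key_text_fn is not None:
            return self.key_text_fn(inst)
        return self.long_name


@dataclass
class TaskInstance:
    """Raw answers for one administration of a task.

    Summaries are never part of an instance; they are computed on demand by
    the task's summary functions.
    """

    table_name: str
    values: dict[str, Any] = field(default_factory=dict)
    when_created: Optional[str] = None       # ISO-8601 with timezone
    when_first_exited: Optional[str] = None
    first_exit_was_finish: Optional[bool] = None
    first_exit_was_abort: Optional[bool] = None
    patient_link: Optional[int] = None       # client patient key; None if anonymous
    clinician_name: Optional[str] = None

    def get(self, name: str) -> Any:
        return self.values.get(name)

    def present(self, name: str) -> bool:
        value = self.values.get(name)
        if value is None:
            return False
        if isinstance(value, str) and not value.strip():
            return False
        return True


@dataclass(frozen=True)
class CheckResult:
    complete: bool
    valid: bool
    problems: tuple[str, ...] = ()


def validate_instance(defn: TaskDefinition, inst: TaskInstance) -> CheckResult:
    """Check that task information is complete and valid.

    *Valid* means every present value lies within its declared type, range
    or enumeration.  *Complete* means valid and, additionally, every
    mandatory field present.  Unknown field names raise
    :class:`UnknownFieldError` (a malformed upload, not a mere
    incompleteness).
    """
    if inst.table_name != defn.table_name:
        raise ValueError(
            f"instance table {inst.table_name!r} != definition {defn.table_name!r}"
        )
    fmap = defn.field_map()
    unknown = [name for name in inst.values if name not in fmap]
    if unknown:
        raise UnknownFieldError(
            f"fields not declared by task {defn.table_name!r}: {sorted(unknown)}"
        )
    problems: list[str] = []
    valid = True
    for spec in defn.fields:
        if inst.present(spec.name):
            problem = spec.check(inst.values[spec.name])
            if problem:
                problems.append(problem)
                valid = False
    complete = valid
    for spec in defn.fields:
        if spec.mandatory and not inst.present(spec.name):
            problems.append(f"{spec.name}: mandatory field absent")
            complete = False
    if inst.when_first_exited is not None and inst.when_created is not None:
        if to_utc(parse_iso(inst.when_first_exited)) < to_utc(
            parse_iso(inst.when_created)
        ):
            problems.append("when_first_exited precedes when_created")
            valid = complete = False
    return CheckResult(complete=complete, valid=valid, problems=tuple(problems))


# --------------------------------------------------------------- PHQ-9

# Severity bands for the PHQ-9 total, from the instrument's scoring guide.
PHQ9_SEVERITY_BANDS = (
    (0, 4, "none/minimal"),
    (5, 9, "mild"),
    (10, 14, "moderate"),
    (15, 19, "moderately severe"),
    (20, 27, "severe"),
)

_PHQ9_SCORED = tuple(f"q{i}" for i in range(1, 10))


def phq9_severity_band(total: int) -> str:
    for lo, hi, label in PHQ9_SEVERITY_BANDS:
        if lo <= total <= hi:
            return label
    raise ValueError(f"PHQ-9 total out of range: {total}")


def phq9_summary(inst: TaskInstance) -> dict[str, Any]:
    """Live PHQ-9 summary: total over q1-q9, severity band, completeness.

    q10 (functional impact) is required for a complete administration but is
    excluded from the total.  When any scored item is absent the total is
    withheld (None) rather than computed over a subset.
    """
    defn = get_task("phq9")
    check = validate_instance(defn, inst)
    if not check.complete:
        return {"total": None, "severity_band": None, "complete": False}
    total = sum(inst.values[q] for q in _PHQ9_SCORED)
    return {"total": total, "severity_band": phq9_severity_band(total),
            "complete": True}


def phq9_total(inst: TaskInstance) -> Optional[int]:
    return phq9_summary(inst)["total"]


# ----------------------------------------------------------------- BMI

def bmi_summary(inst: TaskInstance) -> dict[str, Any]:
    """Body-mass index (kg/m^2) computed live from stored height and mass."""
    height = inst.get("height_m")
    mass = inst.get("mass_kg")
    if height is None or mass is None:
        return {"bmi": None, "complete": False}
    if height <= 0 or mass <= 0:
        raise ValueError("height and mass must be positive")
    return {"bmi": mass / height**2, "complete": True}


def bmi_value(inst: TaskInstance) -> Optional[float]:
    return bmi_summary(inst)["bmi"]


# ------------------------------------------------------- task registry

def _phq9_key_text(inst: TaskInstance) -> str:
    s = phq9_summary(inst)
    if not s["complete"]:
        return "PHQ-9 (incomplete)"
    return f"PHQ-9 total {s['total']}/27 ({s['severity_band']})"


def _bmi_key_text(inst: TaskInstance) -> str:
    s = bmi_summary(inst)
    if not s["complete"]:
        return "BMI (incomplete)"
    return f"BMI {s['bmi']:.1f} kg/m2"


def _phq9_fields() -> tuple[FieldSpec, ...]:
    items = tuple(
        FieldSpec(f"q{i}", "integer", mandatory=True,
                  allowed_values=(0, 1, 2, 3))
        for i in range(1, 11)
    )
    return items


PHQ9 = TaskDefinition(
    table_name="phq9",
    long_name="Patient Health Questionnaire-9",
    fields=_phq9_fields(),
    summary_fns={
        "total": phq9_total,
        "severity_band": lambda inst: phq9_summary(inst)["severity_band"],
    },
    key_text_fn=_phq9_key_text,
)

BMI = TaskDefinition(
    table_name="bmi",
    long_name="Body mass index",
    fields=(
        FieldSpec("height_m", "real", mandatory=True, min_value=0.1, max_value=3.0),
        FieldSpec("mass_kg", "real", mandatory=True, min_value=0.1, max_value=700.0),
        FieldSpec("comment", "text"),
    ),
    summary_fns={"bmi": bmi_value},
    key_text_fn=_bmi_key_text,
)

ANON_SURVEY = TaskDefinition(
    table_name="anon_survey",
    long_name="Anonymous service-experience survey",
    fields=(
        FieldSpec("satisfaction", "integer", mandatory=True, min_value=0,
                  max_value=10),
        FieldSpec("comment", "text"),
    ),
    is_anonymous=True,
    summary_fns={"satisfaction": lambda inst: inst.get("satisfaction")},
    # Demonstrates the restricted-content pathway: shipped with
    # copyright-free placeholder strings only.
    restricted_strings=True,
    permitted_contexts={
        "clinical": "allowed",
        "research": "allowed",
        "educational": "allowed",
        "commercial": "prohibited",
    },
)

TASK_REGISTRY: dict[str, TaskDefinition] = {
    t.table_name: t for t in (PHQ9, BMI, ANON_SURVEY)
}


def get_task(table_name: str) -> TaskDefinition:
    try:
        return TASK_REGISTRY[table_name]
    except KeyError:
        raise KeyError(f"unknown task table: {table_name!r}") from None


def compute_summaries(defn: TaskDefinition, inst: TaskInstance) -> dict[str, Any]:
    """All declared summary values for an instance, computed now."""
    return {name: fn(inst) for name, fn in defn.summary_fns.items()}


# ------------------------------------------------------- string tables

# Shipped strings for the unrestricted exemplar tasks (English only; other
# languages fall back to the configured default).
_SHIPPED_STRINGS: dict[str, dict[str, dict[str, str]]] = {
    "phq9": {
        "q1": {"en": "1. Little interest or pleasure in doing things"},
        "a0": {"en": "Not at all"},
        "a1": {"en": "Several days"},
        "a2": {"en": "More than half the days"},
        "a3": {"en": "Nearly every day"},
    },
    "bmi": {
        "height_m": {"en": "Height (m)"},
        "mass_kg": {"en": "Mass (kg)"},
    },
}

_QNUM_RE = re.compile(r"^q(\d+)$")


class StringTable:
    """Task strings with an institution-override and placeholder chain.

    Lookup order: institution-supplied XML entry, then shipped entry, then
    (for tasks shipped with placeholder text only, for licensing reasons) a
    copyright-free placeholder such as "Question 1".  A missing language
    falls back to the default language.  The chain is total: every
    (task, key) yields some text.
    """

    def __init__(self, default_language: str = "en"):
        self.default_language = default_language
        self._shipped: dict[str, dict[str, dict[str, str]]] = {
            task: {k: dict(v) for k, v in entries.items()}
            for task, entries in _SHIPPED_STRINGS.items()
        }
        self._institution: dict[str, dict[str, dict[str, str]]] = {}

    def load_institution_xml(self, source) -> int:
        """Load an institution add-on XML file.

        Format: ``<strings><task name="..."><string name="..."
        language="en">text</string></task></strings>``.  Returns the number
        of strings loaded.  Entries override shipped strings.
        """
        if isinstance(source, bytes):
            root = etree.fromstring(source)
        elif isinstance(source, str) and source.lstrip().startswith("<"):
            root = etree.fromstring(source.encode("utf-8"))
        else:  # path or file-like
            root = etree.parse(source).getroot()
        count = 0
        for task_el in root.findall("task"):
            task = task_el.get("name")
            for s in task_el.findall("string"):
                key = s.get("name")
                lang = s.get("language", self.default_language)
                self._institution.setdefault(task, {}).setdefault(key, {})[
                    lang
                ] = s.text or ""
                count += 1
        return count

    @staticmethod
    def _pick(per_lang: dict[str, str], language: str, default: str
              ) -> Optional[str]:
        if language in per_lang:
            return per_lang[language]
        if default in per_lang:
            return per_lang[default]
        if per_lang:  # any language beats a placeholder
            return next(iter(per_lang.values()))
        return None

    def resolve(self, task: str, key: str, language: Optional[str] = None) -> str:
        language = language or self.default_language
        for layer in (self._institution, self._shipped):
            per_lang = layer.get(task, {}).get(key)
            if per_lang:
                text = self._pick(per_lang, language, self.default_language)
                if text is not None:
                    return text
        m = _QNUM_RE.match(key)
        if m:
            return f"Question {m.group(1)}"
        m = re.match(r"^a(\d+)$", key)
        if m:
            return f"Answer {m.group(1)}"
        return key  # last-resort placeholder: the key itself


def resolve_string(table: StringTable, task: str, key: str,
                   language: Optional[str] = None) -> str:
    return table.resolve(task, key, language)


# ---------------------------------------------------- use-context gating

@dataclass(frozen=True)
class UseContextVerdict:
    permitted: bool
    blocking_context: Optional[str] = None
    reason: str = ""

    def __bool__(self) -> bool:
        return self.permitted


_CONTEXTS = ("clinical", "research", "educational", "commercial")


def check_use_context(
    defn: TaskDefinition, declared: Mapping[str, str]
) -> UseContextVerdict:
    """Gate a task on the declared use contexts.

    ``declared`` maps each of clinical/research/educational/commercial to
    "yes", "no" or "unknown".  A task prohibited for a context is refused
    when that context is declared "yes"; "unknown" is treated
    conservatively as blocking for prohibited contexts.
    """
    missing = [c for c in _CONTEXTS if c not in declared]
    if missing:
        raise ValueError(f"use-context flags missing: {missing}")
    for ctx in _CONTEXTS:
        flag = declared[ctx]
        if flag not in ("yes", "no", "unknown"):
            raise ValueError(f"{ctx}: flag must be yes/no/unknown, got {flag!r}")
        if defn.permitted_contexts.get(ctx, "allowed") == "prohibited":
            if flag == "yes":
                return UseContextVerdict(
                    False, ctx, f"task prohibited for {ctx} use"
                )
            if flag == "unknown":
                return UseContextVerdict(
                    False, ctx,
                    f"{ctx} use unknown; treated as not permitted for a "
                    f"task prohibited in that context",
                )
    return UseContextVerdict(True)


# ----------------------------------------------------------- scheduling

@dataclass(frozen=True)
class ScheduleItem:
    table_name: str
    repeat_interval: timedelta
    total_duration: timedelta
    anchor: datetime  # aware

    def __post_init__(self):
        if self.repeat_interval <= timedelta(0):
            raise ValueError("repeat_interval must be positive")
        if self.total_duration < self.repeat_interval:
            raise ValueError("total_duration must be >= repeat_interval")

    @property
    def n_slots(self) -> int:
        return math.ceil(self.total_duration / self.repeat_interval)


@dataclass(frozen=True)
class Schedule:
    items: tuple[ScheduleItem, ...] = ()


@dataclass(frozen=True)
class DueSlot:
    table_name: str
    slot_index: int
    slot_start: datetime
    slot_end: datetime


def tasks_due(
    schedule: Schedule,
    completed: Iterable[tuple[str, datetime]],
    now: datetime,
) -> list[DueSlot]:
    """Administrations due under a schedule, given completions so far.

    Each item defines ceil(total/interval) half-open slots
    [anchor + k*interval, anchor + (k+1)*interval).  A slot is due when
    `now` lies within or past it and no completion of that task falls
    inside the slot (so "a weekly PHQ-9 for 6 weeks" with nothing done and
    `now` well past the end yields six due administrations).
    """
    completed = [(t, to_utc(ts)) for t, ts in completed]
    now = to_utc(now)
    due: list[DueSlot] = []
    for item in schedule.items:
        anchor = to_utc(item.anchor)
        for k in range(item.n_slots):
            start = anchor + k * item.repeat_interval
            end = start + item.repeat_interval
            if now < start:
                continue
            done = any(
                t == item.table_name and start <= ts < end for t, ts in completed
            )
            if not done:
                due.append(DueSlot(item.table_name, k, start, end))
    return due
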