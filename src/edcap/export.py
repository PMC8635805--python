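"""Research and clinical views of stored data.

Everything here is computed at the moment of request from the raw rows:
summary scores appear in dumps, trackers and XML only because they are
recomputed live, never because they were stored.  Every read path filters
through record-level authorization, so no dump, search, tracker or view
can contain a record its requester may not see, and every bulk export
emits an audit event.

Formats: TSV (UTF-8, tab separator, header row, ISO-8601 datetimes, empty
string for null), XLSX (one sheet per task table, same tabular model),
per-task XML, and a single-file SQLite database.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional

import pandas as pd
from lxml import etree

from ._time import parse_iso, to_utc
from .access import User
from .identity import PatientRecord, detect_identity_conflicts
from .store import (
    ERA_NOW,
    IDNUM_TABLE,
    PATIENT_TABLE,
    PermissionDenied,
    Server,
)
from .tasks import TASK_REGISTRY, TaskDefinition, compute_summaries, get_task

__all__ = [
    "DumpSpec",
    "research_dump",
    "write_dump",
    "task_to_xml",
    "clinical_text_view",
    "text_search",
    "tracker",
    "TrackerSeries",
]

ENVELOPE_EXPORT_COLS = (
    "_pk", "_device", "_group_id", "_client_pk", "_era", "_current",
    "_when_added",
)

SUPPORTED_FORMATS = ("tsv", "xlsx", "xml", "sqlite")


@dataclass(frozen=True)
class DumpSpec:
    """What to dump, for whom, in which format."""

    username: str
    fmt: str = "tsv"
    tables: Optional[tuple[str, ...]] = None       # default: all task tables
    group_ids: Optional[tuple[int, ...]] = None
    since: Optional[str] = None                    # ISO datetime, inclusive
    until: Optional[str] = None                    # ISO datetime, exclusive
    patient_key: Optional[int] = None              # linking-ID filter
    include_history: bool = False                  # include superseded rows

    def __post_init__(self):
        if self.fmt not in SUPPORTED_FORMATS:
            raise ValueError(
                f"unsupported dump format {self.fmt!r}; "
                f"supported: {', '.join(SUPPORTED_FORMATS)}"
            )


def _instance_from_row(defn: TaskDefinition, row: Mapping):
    from .store import Server as _S
    return _S._row_to_instance(defn, dict(row) | {"client_pk": row["_client_pk"]})


def _patient_for_row(server: Server, row: Mapping) -> Optional[dict]:
    cpk = row["patient_client_pk"]
    if cpk is None:
        return None
    p = server.conn.execute(
        f"SELECT * FROM {PATIENT_TABLE} WHERE _device = ? AND _era = ? "
        "AND _client_pk = ? AND _current = 1",
        (row["_device"], row["_era"], cpk),
    ).fetchone()
    idnums = server.conn.execute(
        f"SELECT which_idnum, idnum_value FROM {IDNUM_TABLE} "
        "WHERE _device = ? AND _era = ? AND patient_client_pk = ? "
        "AND _current = 1 ORDER BY which_idnum",
        (row["_device"], row["_era"], cpk),
    ).fetchall()
    out: dict[str, Any] = {}
    if p is not None:
        for f in ("forename", "surname", "dob", "sex"):
            out[f] = p[f]
    for r in idnums:
        out[f"idnum{r['which_idnum']}"] = r["idnum_value"]
    return out


def _row_in_window(row: Mapping, since: Optional[str], until: Optional[str]
                   ) -> bool:
    when = row["when_created"] or row["_when_added"]
    t = to_utc(parse_iso(when))
    if since is not None and t < to_utc(parse_iso(since)):
        return False
    if until is not None and t >= to_utc(parse_iso(until)):
        return False
    return True


def _authorized_task_rows(
    server: Server,
    user: User,
    table: str,
    has_patient_filter: bool,
    group_ids: Optional[Iterable[int]] = None,
    patient_key: Optional[int] = None,
    include_history: bool = False,
) -> list[sqlite3.Row]:
    sql = f'SELECT * FROM "{table}"'
    clauses, params = [], []
    if not include_history:
        clauses.append("_current = 1")
    if group_ids is not None:
        gids = list(group_ids)
        clauses.append(f"_group_id IN ({','.join('?' * len(gids))})")
        params += gids
    if clauses:
        sql += " WHERE " + " AND ".join(clauses)
    sql += " ORDER BY _pk"
    out = []
    for row in server.conn.execute(sql, params):
        if patient_key is not None:
            if server._row_patient_key(table, row) != patient_key:
                continue
        if server.authorize_view_row(user, table, row, has_patient_filter):
            out.append(row)
    return out


def research_dump(server: Server, spec: DumpSpec) -> dict[str, pd.DataFrame]:
    """One-row-per-task-instance tabular dump.

    Columns, in deterministic order: envelope metadata, subject
    identifiers (as permitted by the owning group's policy — i.e., exactly
    what was stored), raw task fields, then summary fields computed at
    request time.  Requires bulk-export permission in every group touched;
    emission is audited.
    """
    user = server.get_user(spec.username)
    tables = spec.tables or tuple(TASK_REGISTRY)
    groups = server.groups()
    gids = spec.group_ids if spec.group_ids is not None else tuple(groups)
    if not user.is_superuser:
        memberships = server.memberships_of(user.user_id)
        for gid in gids:
            if not any(m.group_id == gid and m.may_dump for m in memberships):
                server.audit(spec.username, "export_refused",
                             f"dump without may_dump in group {gid}")
                raise PermissionDenied(
                    f"bulk export requires may_dump in group {gid}"
                )
    frames: dict[str, pd.DataFrame] = {}
    has_filter = spec.patient_key is not None
    for table in tables:
        defn = get_task(table)
        rows = _authorized_task_rows(
            server, user, table, has_filter, gids, spec.patient_key,
            spec.include_history,
        )
        records = []
        for row in rows:
            if not _row_in_window(row, spec.since, spec.until):
                continue
            rec: dict[str, Any] = {c: row[c] for c in ENVELOPE_EXPORT_COLS}
            if not defn.is_anonymous:
                patient = _patient_for_row(server, row) or {}
                for key, value in patient.items():
                    rec[f"patient_{key}"] = value
            inst = _instance_from_row(defn, row)
            for f in ("when_created", "when_first_exited"):
                rec[f] = row[f]
            for f in defn.fields:
                rec[f.name] = row[f.name]
            for name, value in compute_summaries(defn, inst).items():
                rec[f"summary_{name}"] = value
            records.append(rec)
        frames[table] = pd.DataFrame.from_records(records)
        if records:
            frames[table] = frames[table][list(records[0].keys())]
    server.audit(spec.username, "export",
                 f"dump fmt={spec.fmt} tables={','.join(tables)} "
                 f"rows={sum(len(f) for f in frames.values())}")
    return frames


def write_dump(server: Server, spec: DumpSpec, out_dir: str | Path) -> list[Path]:
    """Materialize a research dump to files; returns the paths written."""
    frames = research_dump(server, spec)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if spec.fmt == "tsv":
        for table, frame in frames.items():
            path = out_dir / f"{table}.tsv"
            frame.to_csv(path, sep="\t", index=False, na_rep="",
                         encoding="utf-8")
            written.append(path)
    elif spec.fmt == "xlsx":
        path = out_dir / "dump.xlsx"
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            for table, frame in frames.items():
                (frame if not frame.empty else pd.DataFrame({"empty": []})
                 ).to_excel(writer, sheet_name=table[:31], index=False)
        written.append(path)
    elif spec.fmt == "sqlite":
        path = out_dir / "dump.sqlite"
        conn = sqlite3.connect(path)
        try:
            for table, frame in frames.items():
                frame.to_sql(table, conn, index=False, if_exists="replace")
        finally:
            conn.close()
        written.append(path)
    elif spec.fmt == "xml":
        user = server.get_user(spec.username)
        root = etree.Element("dump")
        for table, frame in frames.items():
            for pk in frame.get("_pk", []):
                root.append(task_to_xml(server, table, int(pk), spec.username,
                                        _audit=False))
        path = out_dir / "dump.xml"
        path.write_bytes(etree.tostring(root, pretty_print=True,
                                        xml_declaration=True, encoding="UTF-8"))
        written.append(path)
    return written


def task_to_xml(
    server: Server, table: str, server_pk: int, username: str,
    _audit: bool = True,
) -> etree._Element:
    """One task instance as structured XML: envelope, patient block (unless
    anonymous), raw fields with type attributes, then calculated values."""
    user = server.get_user(username)
    defn = get_task(table)
    row = server.get_row(table, server_pk)
    if not server.authorize_view_row(user, table, row, has_patient_filter=True):
        raise PermissionDenied(f"not authorized to view {table}._pk={server_pk}")
    el = etree.Element("task", table=table)
    envelope = etree.SubElement(el, "envelope")
    for c in ENVELOPE_EXPORT_COLS:
        child = etree.SubElement(envelope, c.lstrip("_"))
        child.text = "" if row[c] is None else str(row[c])
    if not defn.is_anonymous:
        patient = _patient_for_row(server, row) or {}
        pblock = etree.SubElement(el, "patient")
        for key, value in patient.items():
            child = etree.SubElement(pblock, key)
            child.text = "" if value is None else str(value)
    raw = etree.SubElement(el, "raw")
    for f in ("when_created", "when_first_exited", "clinician_name"):
        child = etree.SubElement(raw, f, type="datetime"
                                 if f.startswith("when") else "text")
        child.text = "" if row[f] is None else str(row[f])
    for f in defn.fields:
        child = etree.SubElement(raw, f.name, type=f.value_type)
        child.text = "" if row[f.name] is None else str(row[f.name])
    inst = _instance_from_row(defn, row)
    calc = etree.SubElement(el, "calculated")
    for name, value in compute_summaries(defn, inst).items():
        child = etree.SubElement(calc, name)
        child.text = "" if value is None else str(value)
    if _audit:
        server.audit(username, "export", f"xml {table}._pk={server_pk}")
    return el


def parse_task_xml(xml: bytes | str) -> dict[str, str]:
    """Raw fields of a task XML document (round-trip helper)."""
    root = etree.fromstring(xml.encode() if isinstance(xml, str) else xml)
    return {child.tag: child.text or "" for child in root.find("raw")}


# ------------------------------------------------------------ clinical views

@dataclass(frozen=True)
class ClinicalEntry:
    table: str
    server_pk: int
    when: str
    key_text: str
    summaries: Mapping[str, Any]
    warnings: tuple[str, ...] = ()


def clinical_text_view(
    server: Server,
    username: str,
    patient_key: int,
    since: Optional[str] = None,
    until: Optional[str] = None,
) -> list[ClinicalEntry]:
    """Chronological key-text listing of a patient's tasks across all groups
    the user may see, with live summaries and identity-conflict warnings."""
    user = server.get_user(username)
    entries: list[ClinicalEntry] = []
    warnings = _conflict_warnings(server, user, patient_key)
    for table, defn in TASK_REGISTRY.items():
        if defn.is_anonymous:
            continue
        for row in _authorized_task_rows(
            server, user, table, has_patient_filter=True,
            patient_key=patient_key,
        ):
            if not _row_in_window(row, since, until):
                continue
            inst = _instance_from_row(defn, row)
            entries.append(
                ClinicalEntry(
                    table=table,
                    server_pk=row["_pk"],
                    when=row["when_created"] or row["_when_added"],
                    key_text=defn.key_text(inst),
                    summaries=compute_summaries(defn, inst),
                    warnings=warnings,
                )
            )
    entries.sort(key=lambda e: to_utc(parse_iso(e.when)))
    server.audit(username, "view", f"clinical text view patient {patient_key}")
    return entries


def _conflict_warnings(server: Server, user: User, patient_key: int
                       ) -> tuple[str, ...]:
    """Identity-conflict warnings across device copies of one subject."""
    idents = server.conn.execute(
        f"SELECT * FROM {IDNUM_TABLE} WHERE which_idnum = ? "
        "AND idnum_value = ? AND _current = 1",
        (server.config.linking_idnum, patient_key),
    ).fetchall()
    records = []
    for ident in idents:
        p = server.conn.execute(
            f"SELECT * FROM {PATIENT_TABLE} WHERE _device = ? AND _era = ? "
            "AND _client_pk = ? AND _current = 1",
            (ident["_device"], ident["_era"], ident["patient_client_pk"]),
        ).fetchone()
        if p is None:
            continue
        if not server.authorize_view_row(user, PATIENT_TABLE, p, True):
            continue
        rec = {
            f: p[f] for f in
            ("forename", "surname", "address", "email", "gp", "otherdetails")
            if p[f]
        }
        if p["dob"]:
            from datetime import date
            rec["dob"] = date.fromisoformat(p["dob"])
        if p["sex"]:
            rec["sex"] = p["sex"]
        records.append(PatientRecord(**rec))
    if len(records) < 2:
        return ()
    return tuple(
        f"identity conflict on {c.field_name}: "
        + " vs ".join(str(v) for v in c.values_seen)
        for c in detect_identity_conflicts(records)
    )


def text_search(server: Server, username: str, needle: str) -> list[tuple]:
    """Case-insensitive substring search across text fields of all records
    the user may view; returns (table, server_pk) references."""
    user = server.get_user(username)
    needle_l = needle.lower()
    hits: list[tuple] = []
    for table, defn in TASK_REGISTRY.items():
        text_fields = [f.name for f in defn.fields if f.value_type == "text"]
        text_fields.append("clinician_name")
        for row in _authorized_task_rows(
            server, user, table, has_patient_filter=True
        ):
            for fname in text_fields:
                value = row[fname]
                if isinstance(value, str) and needle_l in value.lower():
                    hits.append((table, row["_pk"]))
                    break
    server.audit(username, "view", f"text search ({len(hits)} hits)")
    return hits


@dataclass(frozen=True)
class TrackerSeries:
    patient_key: int
    table: str
    metric: str
    points: tuple[tuple[str, float], ...]  # (ISO timestamp, value), time-ordered


def tracker(
    server: Server, username: str, patient_key: int, table: str, metric: str
) -> TrackerSeries:
    """Numeric time series of a declared summary metric for one patient.

    One point per complete instance, values computed live; incomplete
    administrations are skipped rather than plotted as partial scores.
    """
    defn = get_task(table)
    if metric not in defn.summary_fns:
        raise KeyError(f"{metric!r} is not a declared summary of {table!r}")
    user = server.get_user(username)
    points = []
    for row in _authorized_task_rows(
        server, user, table, has_patient_filter=True, patient_key=patient_key
    ):
        inst = _instance_from_row(defn, row)
        from .tasks import validate_instance
        if not validate_instance(defn, inst).complete:
            continue
        value = defn.summary_fns[metric](inst)
        if not isinstance(value, (int, float)):
            continue
        when = row["when_created"] or row["_when_added"]
        points.append((when, float(value)))
    points.sort(key=lambda p: to_utc(parse_iso(p[0])))
    server.audit(username, "view",
                 f"tracker {table}.{metric} patient {patient_key}")
    return TrackerSeries(patient_key, table, metric, tuple(points))
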