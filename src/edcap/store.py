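"""The server-side versioned record store.

Uploads from registered client devices land in per-task relational tables
(plus a subject table and a linked ID-number table).  The server wraps
every uploaded row in a version envelope:

* ``_era`` — the literal string ``"NOW"`` while the source record is still
  live on the device, or the ISO-8601 instant at which the device's records
  were finalized (moved) to the server;
* ``_current`` — marks the live version within a supersede chain.  When a
  record is re-uploaded changed, the old row is closed (no longer current,
  removal time and removing user stamped, successor linked) and a new
  current row is inserted pointing back at its predecessor;
* addition/removal stamps and predecessor/successor links, giving a
  complete modification history whose granularity is the upload frequency.

Uploads are atomic: a batch succeeds in its entirety or leaves the store
bit-identical to its prior state.  Old versions are never physically
removed by uploads or content erasure; only whole-patient deletion removes
rows.  The data channel is one-way — the store accepts uploads but never
returns previously uploaded task content to a device client.
"""

from __future__ import annotations

import json
import secrets
import sqlite3
from dataclasses import dataclass, field as dc_field
from datetime import date, datetime
from typing import Any, Iterable, Mapping, Optional, Sequence

from ._time import format_iso, now_utc, parse_iso
from .access import (
    ACTION_FLAGS,
    Decision,
    Group,
    Membership,
    User,
    UserStatus,
    authorize_action,
    authorize_view,
    visible_groups,
)
from .identity import (
    IdNumDefinition,
    PatientRecord,
    ValidationMethod,
    validate_idnum,
)
from .policy import IdPolicy, parse_policy
from .security import AuthConfig, AuthService, hash_password
from .tasks import (
    TASK_REGISTRY,
    StringTable,
    TaskDefinition,
    TaskInstance,
    UnknownFieldError,
    get_task,
    validate_instance,
)

__all__ = [
    "StoreError",
    "PermissionDenied",
    "DeviceNotRegistered",
    "PolicyMismatch",
    "UploadPolicyViolation",
    "FinalizePolicyViolation",
    "UnknownTableError",
    "UploadBatch",
    "UploadReport",
    "DeviceRecord",
    "Server",
    "ERA_NOW",
]

ERA_NOW = "NOW"

PATIENT_TABLE = "patient"
IDNUM_TABLE = "patient_idnum"

PATIENT_CONTENT_FIELDS = (
    "forename", "surname", "dob", "sex", "address", "email", "gp",
    "otherdetails",
)
IDNUM_CONTENT_FIELDS = ("patient_client_pk", "which_idnum", "idnum_value")
TASK_META_FIELDS = (
    "patient_client_pk", "when_created", "when_first_exited",
    "first_exit_was_finish", "first_exit_was_abort", "clinician_name",
)

_SQL_TYPES = {
    "integer": "INTEGER",
    "real": "REAL",
    "text": "TEXT",
    "date": "TEXT",
    "datetime": "TEXT",
    "boolean": "INTEGER",
    "blob_ref": "TEXT",
}


class StoreError(Exception):
    pass


class PermissionDenied(StoreError):
    pass


class DeviceNotRegistered(StoreError):
    pass


class PolicyMismatch(StoreError):
    """The device's registration-time policy snapshot no longer matches the
    server's current policies; the device must re-register."""


class UploadPolicyViolation(StoreError):
    def __init__(self, offenders: Sequence[int]):
        super().__init__(
            f"patients failing the upload policy (client pks): {list(offenders)}"
        )
        self.offenders = list(offenders)


class FinalizePolicyViolation(StoreError):
    def __init__(self, offenders: Sequence[int]):
        super().__init__(
            f"patients failing the finalizing policy (client pks): "
            f"{list(offenders)}"
        )
        self.offenders = list(offenders)


class UnknownTableError(StoreError):
    pass


# ------------------------------------------------------------------ batches

@dataclass
class UploadBatch:
    """One client upload: full device state plus mode and marks.

    ``mode`` is the three-way client choice: ``move`` (finalize
    everything), ``move_keeping_patients`` (finalize tasks, retain basic
    identity rows on the device), or ``copy`` (duplicate to server, moving
    only rows explicitly marked finished).
    """

    device_id: str
    username: str
    group_id: int
    mode: str  # copy | move | move_keeping_patients
    patients: list[dict] = dc_field(default_factory=list)
    idnums: list[dict] = dc_field(default_factory=list)
    tasks: dict[str, list[dict]] = dc_field(default_factory=dict)
    finished_patients: list[int] = dc_field(default_factory=list)
    finished_anonymous: dict[str, list[int]] = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("copy", "move", "move_keeping_patients"):
            raise ValueError(f"unknown upload mode: {self.mode!r}")

    # JSON is the canonical payload dialect.
    @classmethod
    def from_json(cls, text: str | bytes) -> "UploadBatch":
        data = json.loads(text)
        return cls(
            device_id=data["device_id"],
            username=data["username"],
            group_id=int(data["group_id"]),
            mode=data["mode"],
            patients=data.get("patients", []),
            idnums=data.get("idnums", []),
            tasks=data.get("tasks", {}),
            finished_patients=data.get("finished_patients", []),
            finished_anonymous=data.get("finished_anonymous", {}),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "device_id": self.device_id,
                "username": self.username,
                "group_id": self.group_id,
                "mode": self.mode,
                "patients": self.patients,
                "idnums": self.idnums,
                "tasks": self.tasks,
                "finished_patients": self.finished_patients,
                "finished_anonymous": self.finished_anonymous,
            },
            indent=2,
        )

    @classmethod
    def from_sqlite(cls, path: str) -> "UploadBatch":
        """Read a batch from an SQLite payload file.

        The file carries a ``_upload_meta`` key/value table plus the same
        row structure as the JSON dialect.
        """
        conn = sqlite3.connect(path)
        conn.row_factory = sqlite3.Row
        try:
            meta = {
                r["key"]: r["value"]
                for r in conn.execute("SELECT key, value FROM _upload_meta")
            }
            def rows(table: str) -> list[dict]:
                try:
                    cur = conn.execute(f'SELECT * FROM "{table}"')
                except sqlite3.OperationalError:
                    return []
                return [
                    {k: v for k, v in dict(r).items() if v is not None}
                    for r in cur
                ]
            tasks = {}
            for t in json.loads(meta.get("task_tables", "[]")):
                tasks[t] = rows(t)
            return cls(
                device_id=meta["device_id"],
                username=meta["username"],
                group_id=int(meta["group_id"]),
                mode=meta["mode"],
                patients=rows(PATIENT_TABLE),
                idnums=rows(IDNUM_TABLE),
                tasks=tasks,
                finished_patients=json.loads(meta.get("finished_patients", "[]")),
                finished_anonymous=json.loads(
                    meta.get("finished_anonymous", "{}")
                ),
            )
        finally:
            conn.close()


@dataclass
class UploadReport:
    inserted: int = 0
    superseded: int = 0
    unchanged: int = 0
    finalized: int = 0
    when: str = ""

    # The exchange is one-way: the report deliberately carries counts only,
    # never record content.


@dataclass(frozen=True)
class DeviceRecord:
    device_id: str
    friendly_name: str
    registered_by: str
    registered_at: str
    group_id: int
    upload_policy: str
    finalize_policy: str
    iddefs_snapshot: str  # JSON


# ------------------------------------------------------------------- server

@dataclass
class ServerConfig:
    idnum_definitions: dict[int, IdNumDefinition] = dc_field(default_factory=dict)
    linking_idnum: int = 1  # institutional linking key for record merge
    default_language: str = "en"
    auth: AuthConfig = dc_field(default_factory=AuthConfig)


def _envelope_ddl() -> str:
    return (
        "_pk INTEGER PRIMARY KEY AUTOINCREMENT, "
        "_device TEXT NOT NULL, "
        "_group_id INTEGER NOT NULL, "
        "_client_pk INTEGER NOT NULL, "
        "_era TEXT NOT NULL, "
        "_current INTEGER NOT NULL, "
        "_when_added TEXT NOT NULL, "
        "_adding_user TEXT NOT NULL, "
        "_when_removed TEXT, "
        "_removing_user TEXT, "
        "_predecessor_pk INTEGER, "
        "_successor_pk INTEGER, "
        "_when_last_modified TEXT"
    )


def _task_content_columns(defn: TaskDefinition) -> list[tuple[str, str]]:
    cols = [
        ("patient_client_pk", "INTEGER"),
        ("when_created", "TEXT"),
        ("when_first_exited", "TEXT"),
        ("first_exit_was_finish", "INTEGER"),
        ("first_exit_was_abort", "INTEGER"),
        ("clinician_name", "TEXT"),
    ]
    cols += [(f.name, _SQL_TYPES[f.value_type]) for f in defn.fields]
    return cols


class Server:
    """A record store plus its users, groups, devices and audit trail.

    Backed by a single SQLite file (or ``:memory:``).  All mutating
    operations are audited; uploads are atomic transactions.
    """

    def __init__(self, path: str = ":memory:",
                 config: Optional[ServerConfig] = None):
        self.config = config or ServerConfig()
        self.conn = sqlite3.connect(path)
        self.conn.row_factory = sqlite3.Row
        self.conn.isolation_level = None  # explicit BEGIN/COMMIT
        self.strings = StringTable(self.config.default_language)
        self.auth = AuthService(
            lookup=self._auth_lookup,
            config=self.config.auth,
            audit=lambda what, details: self.audit("-", what, details),
        )
        self._init_db()

    # ------------------------------------------------------------- schema

    def _init_db(self) -> None:
        c = self.conn
        c.execute("PRAGMA foreign_keys = ON")
        c.executescript(
            """
            CREATE TABLE IF NOT EXISTS idnum_definitions (
                which_idnum INTEGER PRIMARY KEY,
                description TEXT NOT NULL,
                short_description TEXT NOT NULL DEFAULT '',
                validation_method TEXT NOT NULL DEFAULT 'none'
            );
            CREATE TABLE IF NOT EXISTS groups (
                group_id INTEGER PRIMARY KEY AUTOINCREMENT,
                name TEXT UNIQUE NOT NULL,
                upload_policy TEXT NOT NULL,
                finalize_policy TEXT NOT NULL
            );
            CREATE TABLE IF NOT EXISTS group_visibility (
                group_id INTEGER NOT NULL,
                can_see_group_id INTEGER NOT NULL,
                PRIMARY KEY (group_id, can_see_group_id)
            );
            CREATE TABLE IF NOT EXISTS users (
                user_id INTEGER PRIMARY KEY AUTOINCREMENT,
                username TEXT UNIQUE NOT NULL,
                password_hash TEXT NOT NULL,
                password_set_at TEXT,
                status TEXT NOT NULL DEFAULT 'staff',
                locked_patient_key INTEGER
            );
            CREATE TABLE IF NOT EXISTS memberships (
                user_id INTEGER NOT NULL,
                group_id INTEGER NOT NULL,
                may_upload INTEGER NOT NULL DEFAULT 0,
                may_register_devices INTEGER NOT NULL DEFAULT 0,
                may_login_web INTEGER NOT NULL DEFAULT 0,
                may_view_all_patients_unfiltered INTEGER NOT NULL DEFAULT 0,
                may_dump INTEGER NOT NULL DEFAULT 0,
                may_run_reports INTEGER NOT NULL DEFAULT 0,
                may_add_notes INTEGER NOT NULL DEFAULT 0,
                is_group_admin INTEGER NOT NULL DEFAULT 0,
                PRIMARY KEY (user_id, group_id)
            );
            CREATE TABLE IF NOT EXISTS devices (
                device_id TEXT PRIMARY KEY,
                friendly_name TEXT NOT NULL,
                registered_by TEXT NOT NULL,
                registered_at TEXT NOT NULL,
                group_id INTEGER NOT NULL,
                upload_policy TEXT NOT NULL,
                finalize_policy TEXT NOT NULL,
                iddefs_snapshot TEXT NOT NULL
            );
            CREATE TABLE IF NOT EXISTS audit (
                audit_id INTEGER PRIMARY KEY AUTOINCREMENT,
                when_ TEXT NOT NULL,
                who TEXT NOT NULL,
                what TEXT NOT NULL,
                details TEXT NOT NULL DEFAULT ''
            );
            CREATE TABLE IF NOT EXISTS annotations (
                annotation_id INTEGER PRIMARY KEY AUTOINCREMENT,
                table_name TEXT NOT NULL,
                server_pk INTEGER NOT NULL,
                who TEXT NOT NULL,
                when_ TEXT NOT NULL,
                note TEXT NOT NULL
            );
            CREATE TABLE IF NOT EXISTS finalized_client_pks (
                device_id TEXT NOT NULL,
                table_name TEXT NOT NULL,
                client_pk INTEGER NOT NULL,
                PRIMARY KEY (device_id, table_name, client_pk)
            );
            """
        )
        env = _envelope_ddl()
        c.execute(
            f"CREATE TABLE IF NOT EXISTS {PATIENT_TABLE} ({env}, "
            + ", ".join(f"{f} TEXT" for f in PATIENT_CONTENT_FIELDS)
            + ")"
        )
        c.execute(
            f"CREATE TABLE IF NOT EXISTS {IDNUM_TABLE} ({env}, "
            "patient_client_pk INTEGER, which_idnum INTEGER, idnum_value INTEGER)"
        )
        for defn in TASK_REGISTRY.values():
            cols = ", ".join(
                f'"{name}" {sqltype}'
                for name, sqltype in _task_content_columns(defn)
            )
            c.execute(
                f'CREATE TABLE IF NOT EXISTS "{defn.table_name}" ({env}, {cols})'
            )
        for which, defn in self.config.idnum_definitions.items():
            c.execute(
                "INSERT OR REPLACE INTO idnum_definitions VALUES (?, ?, ?, ?)",
                (defn.which_idnum, defn.description, defn.short_description,
                 defn.validation_method.value),
            )

    def close(self) -> None:
        self.conn.close()

    # -------------------------------------------------------------- audit

    def audit(self, who: str, what: str, details: str = "") -> None:
        self.conn.execute(
            "INSERT INTO audit (when_, who, what, details) VALUES (?, ?, ?, ?)",
            (format_iso(now_utc()), who, what, details),
        )

    def audit_events(self, what: Optional[str] = None) -> list[sqlite3.Row]:
        if what is None:
            return list(self.conn.execute("SELECT * FROM audit ORDER BY audit_id"))
        return list(
            self.conn.execute(
                "SELECT * FROM audit WHERE what = ? ORDER BY audit_id", (what,)
            )
        )

    # ----------------------------------------------------- administration

    def idnum_definitions(self) -> dict[int, IdNumDefinition]:
        return {
            r["which_idnum"]: IdNumDefinition(
                r["which_idnum"], r["description"], r["short_description"],
                ValidationMethod(r["validation_method"]),
            )
            for r in self.conn.execute(
                "SELECT * FROM idnum_definitions ORDER BY which_idnum"
            )
        }

    def add_idnum_definition(self, defn: IdNumDefinition) -> None:
        self.conn.execute(
            "INSERT OR REPLACE INTO idnum_definitions VALUES (?, ?, ?, ?)",
            (defn.which_idnum, defn.description, defn.short_description,
             defn.validation_method.value),
        )

    def create_group(
        self,
        name: str,
        upload_policy: str,
        finalize_policy: str,
        can_see: Iterable[int] = (),
    ) -> int:
        known = set(self.idnum_definitions())
        parse_policy(upload_policy, "upload", known or None)
        parse_policy(finalize_policy, "finalize", known or None)
        cur = self.conn.execute(
            "INSERT INTO groups (name, upload_policy, finalize_policy) "
            "VALUES (?, ?, ?)",
            (name, upload_policy, finalize_policy),
        )
        gid = cur.lastrowid
        for other in can_see:
            self.conn.execute(
                "INSERT INTO group_visibility VALUES (?, ?)", (gid, other)
            )
        return gid

    def set_group_visibility(self, group_id: int, can_see: Iterable[int]) -> None:
        self.conn.execute(
            "DELETE FROM group_visibility WHERE group_id = ?", (group_id,)
        )
        for other in can_see:
            self.conn.execute(
                "INSERT INTO group_visibility VALUES (?, ?)", (group_id, other)
            )

    def groups(self) -> dict[int, Group]:
        known = set(self.idnum_definitions()) or None
        vis: dict[int, set[int]] = {}
        for r in self.conn.execute("SELECT * FROM group_visibility"):
            vis.setdefault(r["group_id"], set()).add(r["can_see_group_id"])
        out = {}
        for r in self.conn.execute("SELECT * FROM groups"):
            gid = r["group_id"]
            out[gid] = Group(
                group_id=gid,
                name=r["name"],
                upload_policy=parse_policy(r["upload_policy"], "upload", known),
                finalize_policy=parse_policy(
                    r["finalize_policy"], "finalize", known
                ),
                can_see_groups=frozenset(vis.get(gid, set())),
            )
        return out

    def create_user(
        self,
        username: str,
        password: str,
        status: str = "staff",
        locked_patient_key: Optional[int] = None,
    ) -> int:
        cur = self.conn.execute(
            "INSERT INTO users (username, password_hash, password_set_at, "
            "status, locked_patient_key) VALUES (?, ?, ?, ?, ?)",
            (
                username,
                hash_password(password, self.config.auth.hash_cost),
                format_iso(now_utc()),
                status,
                locked_patient_key,
            ),
        )
        return cur.lastrowid

    def get_user(self, username: str) -> User:
        r = self.conn.execute(
            "SELECT * FROM users WHERE username = ?", (username,)
        ).fetchone()
        if r is None:
            raise KeyError(f"unknown user: {username!r}")
        return User(
            user_id=r["user_id"],
            username=r["username"],
            status=UserStatus(r["status"]),
            locked_patient_key=r["locked_patient_key"],
        )

    def _auth_lookup(self, username: str):
        r = self.conn.execute(
            "SELECT user_id, password_hash, password_set_at FROM users "
            "WHERE username = ?",
            (username,),
        ).fetchone()
        if r is None:
            return None
        set_at = parse_iso(r["password_set_at"]) if r["password_set_at"] else None
        return (r["user_id"], r["password_hash"], set_at)

    def add_membership(self, username: str, group_id: int, **flags: bool) -> None:
        allowed = set(Membership.__dataclass_fields__) - {"user_id", "group_id"}
        bad = set(flags) - allowed
        if bad:
            raise KeyError(f"unknown membership flags: {sorted(bad)}")
        user = self.get_user(username)
        cols = sorted(allowed)
        self.conn.execute(
            f"INSERT OR REPLACE INTO memberships (user_id, group_id, "
            f"{', '.join(cols)}) VALUES (?, ?, {', '.join('?' * len(cols))})",
            (user.user_id, group_id, *[int(bool(flags.get(c, False)))
                                       for c in cols]),
        )

    def memberships_of(self, user_id: int) -> list[Membership]:
        out = []
        for r in self.conn.execute(
            "SELECT * FROM memberships WHERE user_id = ?", (user_id,)
        ):
            d = dict(r)
            out.append(
                Membership(
                    user_id=d.pop("user_id"),
                    group_id=d.pop("group_id"),
                    **{k: bool(v) for k, v in d.items()},
                )
            )
        return out

    # -------------------------------------------------- access-control glue

    def groups_with_patient(self, patient_key: int) -> set[int]:
        """Groups holding records for the patient with this linking ID value."""
        rows = self.conn.execute(
            f"SELECT DISTINCT _group_id FROM {IDNUM_TABLE} "
            "WHERE which_idnum = ? AND idnum_value = ?",
            (self.config.linking_idnum, patient_key),
        )
        return {r["_group_id"] for r in rows}

    def visible_groups_for(self, user: User) -> frozenset[int]:
        locked = (
            self.groups_with_patient(user.locked_patient_key)
            if user.status is UserStatus.PATIENT_LOCKED
            else None
        )
        return visible_groups(
            user, self.memberships_of(user.user_id), self.groups(), locked
        )

    def authorize_view_row(
        self, user: User, table: str, row: Mapping, has_patient_filter: bool
    ) -> Decision:
        patient_key = self._row_patient_key(table, row)
        locked = (
            self.groups_with_patient(user.locked_patient_key)
            if user.status is UserStatus.PATIENT_LOCKED
            else None
        )
        return authorize_view(
            user,
            self.memberships_of(user.user_id),
            self.groups(),
            row["_group_id"],
            has_patient_filter,
            record_patient_key=patient_key,
            groups_with_locked_patient=locked,
        )

    def _row_patient_key(self, table: str, row: Mapping) -> Optional[int]:
        """Linking-ID value of the subject a stored row belongs to, if any."""
        if table == IDNUM_TABLE:
            cpk = row["patient_client_pk"]
        elif table == PATIENT_TABLE:
            cpk = row["_client_pk"]
        else:
            cpk = row["patient_client_pk"]
        if cpk is None:
            return None
        r = self.conn.execute(
            f"SELECT idnum_value FROM {IDNUM_TABLE} "
            "WHERE _device = ? AND _era = ? AND patient_client_pk = ? "
            "AND which_idnum = ? AND _current = 1",
            (row["_device"], row["_era"], cpk, self.config.linking_idnum),
        ).fetchone()
        return r["idnum_value"] if r else None

    def _check_action(self, user: User, action: str, group_id: int) -> None:
        decision = authorize_action(
            user, self.memberships_of(user.user_id), action, group_id
        )
        if not decision:
            raise PermissionDenied(
                f"{user.username}: {action} in group {group_id}: {decision.reason}"
            )

    # -------------------------------------------------- device registration

    def register_device(
        self, username: str, friendly_name: str, group_id: int
    ) -> DeviceRecord:
        """Register a client device and hand it the group's policy snapshot.

        The client reads the ID descriptions and both policies at
        registration and the server re-checks them before every upload.
        """
        user = self.get_user(username)
        self._check_action(user, "register_device", group_id)
        group = self.groups().get(group_id)
        if group is None:
            raise KeyError(f"unknown group: {group_id}")
        record = DeviceRecord(
            device_id=secrets.token_hex(24),  # long random identifier
            friendly_name=friendly_name,
            registered_by=username,
            registered_at=format_iso(now_utc()),
            group_id=group_id,
            upload_policy=group.upload_policy.source_text,
            finalize_policy=group.finalize_policy.source_text,
            iddefs_snapshot=self._iddefs_json(),
        )
        self.conn.execute(
            "INSERT INTO devices VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
            (
                record.device_id, record.friendly_name, record.registered_by,
                record.registered_at, record.group_id, record.upload_policy,
                record.finalize_policy, record.iddefs_snapshot,
            ),
        )
        self.audit(username, "registration",
                   f"device {record.device_id[:8]}… ({friendly_name})")
        return record

    def _iddefs_json(self) -> str:
        return json.dumps(
            {
                str(k): [d.description, d.short_description,
                         d.validation_method.value]
                for k, d in sorted(self.idnum_definitions().items())
            },
            sort_keys=True,
        )

    def get_device(self, device_id: str) -> Optional[sqlite3.Row]:
        return self.conn.execute(
            "SELECT * FROM devices WHERE device_id = ?", (device_id,)
        ).fetchone()

    # -------------------------------------------------------------- uploads

    def _content_fields(self, table: str) -> tuple[str, ...]:
        if table == PATIENT_TABLE:
            return PATIENT_CONTENT_FIELDS
        if table == IDNUM_TABLE:
            return IDNUM_CONTENT_FIELDS
        defn = get_task(table)
        return TASK_META_FIELDS + tuple(f.name for f in defn.fields)

    def _current_now_row(
        self, table: str, device_id: str, client_pk: int
    ) -> Optional[sqlite3.Row]:
        return self.conn.execute(
            f'SELECT * FROM "{table}" WHERE _device = ? AND _client_pk = ? '
            "AND _era = ? AND _current = 1",
            (device_id, client_pk, ERA_NOW),
        ).fetchone()

    @staticmethod
    def _norm(value: Any) -> Any:
        if isinstance(value, bool):
            return int(value)
        if isinstance(value, (date, datetime)):
            return value.isoformat()
        return value

    def _patient_record_from_rows(
        self, patient: Mapping, idnums: Iterable[Mapping]
    ) -> PatientRecord:
        kwargs: dict[str, Any] = {}
        for f in PATIENT_CONTENT_FIELDS:
            value = patient.get(f) if isinstance(patient, dict) else patient[f]
            if value in (None, ""):
                continue
            if f == "dob":
                value = date.fromisoformat(str(value))
            kwargs[f] = value
        kwargs["idnums"] = {
            int(r["which_idnum"]): int(r["idnum_value"]) for r in idnums
        }
        return PatientRecord(**kwargs)

    def _stored_patient_record(
        self, device_id: str, client_pk: int
    ) -> Optional[PatientRecord]:
        row = self._current_now_row(PATIENT_TABLE, device_id, client_pk)
        if row is None:
            return None
        idnum_rows = self.conn.execute(
            f"SELECT * FROM {IDNUM_TABLE} WHERE _device = ? AND _era = ? "
            "AND _current = 1 AND patient_client_pk = ?",
            (device_id, ERA_NOW, client_pk),
        ).fetchall()
        return self._patient_record_from_rows(row, idnum_rows)

    def _validate_batch(self, batch: UploadBatch) -> tuple[User, sqlite3.Row]:
        device = self.get_device(batch.device_id)
        if device is None:
            raise DeviceNotRegistered(
                "uploads are accepted from registered devices only"
            )
        user = self.get_user(batch.username)
        self._check_action(user, "upload", batch.group_id)
        group = self.groups().get(batch.group_id)
        if group is None:
            raise KeyError(f"unknown group: {batch.group_id}")

        # Policy re-check: the snapshot the device took at registration must
        # still match the server's current policies and ID definitions.
        if (
            device["group_id"] != batch.group_id
            or device["upload_policy"] != group.upload_policy.source_text
            or device["finalize_policy"] != group.finalize_policy.source_text
            or device["iddefs_snapshot"] != self._iddefs_json()
        ):
            raise PolicyMismatch(
                "server policies changed since registration; re-register device"
            )

        # Reserved/unknown tables and fields are refused outright.
        for table in batch.tasks:
            if table in (PATIENT_TABLE, IDNUM_TABLE):
                raise UnknownTableError(f"reserved table: {table!r}")
            if table not in TASK_REGISTRY:
                raise UnknownTableError(f"unknown task table: {table!r}")
        for p in batch.patients:
            unknown = (
                set(p) - set(PATIENT_CONTENT_FIELDS)
                - {"client_pk", "when_last_modified"}
            )
            if unknown:
                raise UnknownFieldError(
                    f"unknown patient fields: {sorted(unknown)}"
                )
        for r in batch.idnums:
            unknown = (
                set(r) - set(IDNUM_CONTENT_FIELDS)
                - {"client_pk", "when_last_modified"}
            )
            if unknown:
                raise UnknownFieldError(f"unknown idnum fields: {sorted(unknown)}")

        # ID-number checksum validation.
        iddefs = self.idnum_definitions()
        for r in batch.idnums:
            which = int(r["which_idnum"])
            defn = iddefs.get(which)
            if defn is None:
                raise UnknownFieldError(f"unconfigured ID number type {which}")
            verdict = validate_idnum(defn, int(r["idnum_value"]))
            if not verdict:
                raise StoreError(
                    f"invalid ID number (type {which}): {verdict.reason}"
                )

        # Upload-policy check for every patient in the batch.
        idnums_by_patient: dict[int, list[Mapping]] = {}
        for r in batch.idnums:
            idnums_by_patient.setdefault(int(r["patient_client_pk"]), []).append(r)
        offenders = []
        batch_records: dict[int, PatientRecord] = {}
        for p in batch.patients:
            cpk = int(p["client_pk"])
            rec = self._patient_record_from_rows(
                p, idnums_by_patient.get(cpk, [])
            )
            batch_records[cpk] = rec
            if not group.upload_policy.satisfied_by(rec):
                offenders.append(cpk)
        if offenders:
            raise UploadPolicyViolation(offenders)

        # Task validity (completeness is not required to upload, validity is).
        for table, rows in batch.tasks.items():
            defn = get_task(table)
            for row in rows:
                inst = self._row_to_instance(defn, row)
                if defn.is_anonymous and inst.patient_link is not None:
                    raise StoreError(
                        f"anonymous task {table!r} must not reference a patient"
                    )
                if not defn.is_anonymous and inst.patient_link is None:
                    raise StoreError(
                        f"task {table!r} requires a patient link"
                    )
                if (
                    inst.patient_link is not None
                    and inst.patient_link not in batch_records
                    and self._stored_patient_record(
                        batch.device_id, inst.patient_link
                    )
                    is None
                ):
                    raise StoreError(
                        f"task row references unknown patient "
                        f"{inst.patient_link}"
                    )
                check = validate_instance(defn, inst)
                if not check.valid:
                    raise StoreError(
                        f"invalid {table} row (client pk "
                        f"{row.get('client_pk')}): {'; '.join(check.problems)}"
                    )

        # Copy-mode finished rows may not be re-uploaded once finalized.
        self._check_not_refinalized(batch)

        # Move: the finalizing policy must hold for every patient that will
        # be finalized — both those in this batch and any still stored
        # era-NOW for the device.
        if batch.mode in ("move", "move_keeping_patients"):
            fin_offenders = []
            checked = set()
            for cpk, rec in batch_records.items():
                checked.add(cpk)
                if not group.finalize_policy.satisfied_by(rec):
                    fin_offenders.append(cpk)
            for row in self.conn.execute(
                f"SELECT * FROM {PATIENT_TABLE} WHERE _device = ? "
                "AND _era = ? AND _current = 1",
                (batch.device_id, ERA_NOW),
            ):
                cpk = row["_client_pk"]
                if cpk in checked:
                    continue
                rec = self._stored_patient_record(batch.device_id, cpk)
                if rec is not None and not group.finalize_policy.satisfied_by(rec):
                    fin_offenders.append(cpk)
            if fin_offenders:
                raise FinalizePolicyViolation(sorted(fin_offenders))
        elif batch.mode == "copy":
            fin_offenders = [
                cpk
                for cpk in batch.finished_patients
                if cpk in batch_records
                and not group.finalize_policy.satisfied_by(batch_records[cpk])
            ]
            if fin_offenders:
                raise FinalizePolicyViolation(sorted(fin_offenders))
        return user, device

    def _check_not_refinalized(self, batch: UploadBatch) -> None:
        def finalized(table: str, cpk: int) -> bool:
            return (
                self.conn.execute(
                    "SELECT 1 FROM finalized_client_pks WHERE device_id = ? "
                    "AND table_name = ? AND client_pk = ?",
                    (batch.device_id, table, cpk),
                ).fetchone()
                is not None
            )

        for p in batch.patients:
            if finalized(PATIENT_TABLE, int(p["client_pk"])):
                raise StoreError(
                    f"patient client pk {p['client_pk']} was finalized "
                    "earlier and cannot be re-uploaded"
                )
        for table, rows in batch.tasks.items():
            for row in rows:
                if finalized(table, int(row["client_pk"])):
                    raise StoreError(
                        f"{table} client pk {row['client_pk']} was finalized "
                        "earlier and cannot be re-uploaded"
                    )

    @staticmethod
    def _row_to_instance(defn: TaskDefinition, row: Mapping) -> TaskInstance:
        meta = {"client_pk", "when_last_modified", *TASK_META_FIELDS}
        values = {
            k: v for k, v in row.items()
            if k not in meta and not k.startswith("_") and v is not None
        }
        return TaskInstance(
            table_name=defn.table_name,
            values=values,
            when_created=row.get("when_created"),
            when_first_exited=row.get("when_first_exited"),
            first_exit_was_finish=row.get("first_exit_was_finish"),
            first_exit_was_abort=row.get("first_exit_was_abort"),
            patient_link=row.get("patient_client_pk"),
            clinician_name=row.get("clinician_name"),
        )

    def _upsert_row(
        self,
        table: str,
        batch: UploadBatch,
        row: Mapping,
        now_iso: str,
        username: str,
        report: UploadReport,
        fault_hook,
    ) -> None:
        content_fields = self._content_fields(table)
        client_pk = int(row["client_pk"])
        new_values = {
            f: self._norm(row.get(f)) for f in content_fields if f in row
        }
        last_mod = row.get("when_last_modified")
        old = self._current_now_row(table, batch.device_id, client_pk)

        if fault_hook is not None:
            fault_hook()

        if old is not None:
            if last_mod is not None and old["_when_last_modified"] == last_mod:
                report.unchanged += 1
                return
            unchanged = all(
                self._norm(old[f]) == new_values.get(f) for f in content_fields
            )
            if unchanged:
                report.unchanged += 1
                return

        cols = ["_device", "_group_id", "_client_pk", "_era", "_current",
                "_when_added", "_adding_user", "_predecessor_pk",
                "_when_last_modified"]
        vals = [
            batch.device_id, batch.group_id, client_pk, ERA_NOW, 1,
            now_iso, username, old["_pk"] if old is not None else None,
            last_mod,
        ]
        for f in content_fields:
            cols.append(f'"{f}"')
            vals.append(new_values.get(f))
        cur = self.conn.execute(
            f'INSERT INTO "{table}" ({", ".join(cols)}) '
            f'VALUES ({", ".join("?" * len(vals))})',
            vals,
        )
        new_pk = cur.lastrowid
        if old is not None:
            self.conn.execute(
                f'UPDATE "{table}" SET _current = 0, _when_removed = ?, '
                "_removing_user = ?, _successor_pk = ? WHERE _pk = ?",
                (now_iso, username, new_pk, old["_pk"]),
            )
            report.superseded += 1
        else:
            report.inserted += 1

    def _all_tables(self) -> list[str]:
        return [PATIENT_TABLE, IDNUM_TABLE, *TASK_REGISTRY]

    def _finalize_rows(self, table: str, where: str, params: Sequence,
                       now_iso: str, report: UploadReport) -> None:
        cur = self.conn.execute(
            f'UPDATE "{table}" SET _era = ? WHERE _era = ? AND {where}',
            (now_iso, ERA_NOW, *params),
        )
        report.finalized += cur.rowcount

    def apply_upload(
        self,
        batch: UploadBatch,
        fault_hook=None,
    ) -> UploadReport:
        """Apply one upload batch atomically.

        ``fault_hook``, if given, is called at every row-operation boundary
        and may raise to simulate a mid-batch crash; any failure rolls the
        store back to its exact pre-batch state.
        """
        user, device = self._validate_batch(batch)
        now_iso = format_iso(now_utc())
        report = UploadReport(when=now_iso)
        conn = self.conn
        conn.execute("BEGIN IMMEDIATE")
        try:
            for p in batch.patients:
                self._upsert_row(PATIENT_TABLE, batch, p, now_iso,
                                 batch.username, report, fault_hook)
            for r in batch.idnums:
                self._upsert_row(IDNUM_TABLE, batch, r, now_iso,
                                 batch.username, report, fault_hook)
            for table, rows in batch.tasks.items():
                for row in rows:
                    self._upsert_row(table, batch, row, now_iso,
                                     batch.username, report, fault_hook)

            if fault_hook is not None:
                fault_hook()

            if batch.mode == "move":
                for table in self._all_tables():
                    self._finalize_rows(table, "_device = ?",
                                        (batch.device_id,), now_iso, report)
                # The device wipes itself after a move and restarts its
                # client-pk sequence, so forget its finished-row memory.
                conn.execute(
                    "DELETE FROM finalized_client_pks WHERE device_id = ?",
                    (batch.device_id,),
                )
            elif batch.mode == "move_keeping_patients":
                # Identity rows are finalized with everything else, then
                # re-created fresh in era NOW, linked to their finalized
                # ancestors, mirroring the retained copies on the device.
                keep: list[tuple[str, sqlite3.Row]] = []
                for table in (PATIENT_TABLE, IDNUM_TABLE):
                    for row in conn.execute(
                        f'SELECT * FROM "{table}" WHERE _device = ? '
                        "AND _era = ? AND _current = 1",
                        (batch.device_id, ERA_NOW),
                    ):
                        keep.append((table, row))
                for table in self._all_tables():
                    self._finalize_rows(table, "_device = ?",
                                        (batch.device_id,), now_iso, report)
                for table, row in keep:
                    if fault_hook is not None:
                        fault_hook()
                    content_fields = self._content_fields(table)
                    cols = ["_device", "_group_id", "_client_pk", "_era",
                            "_current", "_when_added", "_adding_user",
                            "_predecessor_pk", "_when_last_modified"]
                    vals = [batch.device_id, row["_group_id"],
                            row["_client_pk"], ERA_NOW, 1, now_iso,
                            batch.username, row["_pk"],
                            row["_when_last_modified"]]
                    for f in content_fields:
                        cols.append(f'"{f}"')
                        vals.append(row[f])
                    conn.execute(
                        f'INSERT INTO "{table}" ({", ".join(cols)}) '
                        f'VALUES ({", ".join("?" * len(vals))})',
                        vals,
                    )
                conn.execute(
                    "DELETE FROM finalized_client_pks WHERE device_id = ?",
                    (batch.device_id,),
                )
            else:  # copy: only explicitly finished rows are finalized
                for cpk in batch.finished_patients:
                    self._finalize_rows(
                        PATIENT_TABLE, "_device = ? AND _client_pk = ?",
                        (batch.device_id, cpk), now_iso, report,
                    )
                    self._finalize_rows(
                        IDNUM_TABLE, "_device = ? AND patient_client_pk = ?",
                        (batch.device_id, cpk), now_iso, report,
                    )
                    conn.execute(
                        "INSERT OR IGNORE INTO finalized_client_pks VALUES "
                        "(?, ?, ?)",
                        (batch.device_id, PATIENT_TABLE, cpk),
                    )
                    for table in TASK_REGISTRY:
                        marked = conn.execute(
                            f'SELECT DISTINCT _client_pk FROM "{table}" '
                            "WHERE _device = ? AND patient_client_pk = ? "
                            "AND _era = ?",
                            (batch.device_id, cpk, ERA_NOW),
                        ).fetchall()
                        self._finalize_rows(
                            table, "_device = ? AND patient_client_pk = ?",
                            (batch.device_id, cpk), now_iso, report,
                        )
                        for m in marked:
                            conn.execute(
                                "INSERT OR IGNORE INTO finalized_client_pks "
                                "VALUES (?, ?, ?)",
                                (batch.device_id, table, m["_client_pk"]),
                            )
                for table, cpks in batch.finished_anonymous.items():
                    for cpk in cpks:
                        self._finalize_rows(
                            table, "_device = ? AND _client_pk = ?",
                            (batch.device_id, cpk), now_iso, report,
                        )
                        conn.execute(
                            "INSERT OR IGNORE INTO finalized_client_pks "
                            "VALUES (?, ?, ?)",
                            (batch.device_id, table, cpk),
                        )

            self.conn.execute(
                "INSERT INTO audit (when_, who, what, details) "
                "VALUES (?, ?, ?, ?)",
                (
                    now_iso, batch.username, "upload",
                    f"device {batch.device_id[:8]}… mode={batch.mode} "
                    f"+{report.inserted} ~{report.superseded} "
                    f"={report.unchanged} fin={report.finalized}",
                ),
            )
            conn.execute("COMMIT")
        except BaseException:
            conn.execute("ROLLBACK")
            raise
        return report

    # -------------------------------------------------------------- history

    def history_chain(self, table: str, server_pk: int) -> list[sqlite3.Row]:
        """The full predecessor→successor version chain containing a row,
        ordered oldest first."""
        row = self.get_row(table, server_pk)
        seen = {row["_pk"]}
        # to root
        chain = [row]
        cur = row
        while cur["_predecessor_pk"] is not None:
            cur = self.get_row(table, cur["_predecessor_pk"])
            if cur["_pk"] in seen:
                raise StoreError("cycle in version chain")
            seen.add(cur["_pk"])
            chain.insert(0, cur)
        cur = row
        while cur["_successor_pk"] is not None:
            cur = self.get_row(table, cur["_successor_pk"])
            if cur["_pk"] in seen:
                raise StoreError("cycle in version chain")
            seen.add(cur["_pk"])
            chain.append(cur)
        return chain

    def get_row(self, table: str, server_pk: int) -> sqlite3.Row:
        if table not in self._all_tables():
            raise UnknownTableError(table)
        row = self.conn.execute(
            f'SELECT * FROM "{table}" WHERE _pk = ?', (server_pk,)
        ).fetchone()
        if row is None:
            raise KeyError(f"no row {server_pk} in {table}")
        return row

    # --------------------------------------- erase / delete / annotate

    def _require_group_admin(self, user: User, group_id: int) -> None:
        if user.is_superuser:
            return
        for m in self.memberships_of(user.user_id):
            if m.group_id == group_id and m.is_group_admin:
                return
        raise PermissionDenied(
            f"{user.username} is not an administrator of group {group_id}"
        )

    def erase_task(self, table: str, server_pk: int, username: str) -> None:
        """Erase a task row's content, keeping envelope and audit intact."""
        if table not in TASK_REGISTRY:
            raise UnknownTableError(table)
        user = self.get_user(username)
        row = self.get_row(table, server_pk)
        self._require_group_admin(user, row["_group_id"])
        defn = get_task(table)
        fields = [f.name for f in defn.fields] + ["clinician_name"]
        self.conn.execute(
            f'UPDATE "{table}" SET '
            + ", ".join(f'"{f}" = NULL' for f in fields)
            + " WHERE _pk = ?",
            (server_pk,),
        )
        self.audit(username, "erase", f"{table}._pk={server_pk}")

    def delete_patient(
        self, patient_key: int, group_id: int, username: str
    ) -> int:
        """Delete every record for a patient within a group, across eras.

        The patient is identified by the value of the server's linking ID
        number type.  Returns the number of rows removed.  This is the one
        operation that physically removes rows (records-management and
        consent-withdrawal requirement); it is itself audited.
        """
        user = self.get_user(username)
        self._require_group_admin(user, group_id)
        idents = self.conn.execute(
            f"SELECT DISTINCT _device, patient_client_pk FROM {IDNUM_TABLE} "
            "WHERE which_idnum = ? AND idnum_value = ? AND _group_id = ?",
            (self.config.linking_idnum, patient_key, group_id),
        ).fetchall()
        removed = 0
        self.conn.execute("BEGIN IMMEDIATE")
        try:
            for ident in idents:
                device, cpk = ident["_device"], ident["patient_client_pk"]
                for table in TASK_REGISTRY:
                    cur = self.conn.execute(
                        f'DELETE FROM "{table}" WHERE _device = ? '
                        "AND patient_client_pk = ? AND _group_id = ?",
                        (device, cpk, group_id),
                    )
                    removed += cur.rowcount
                cur = self.conn.execute(
                    f"DELETE FROM {IDNUM_TABLE} WHERE _device = ? "
                    "AND patient_client_pk = ? AND _group_id = ?",
                    (device, cpk, group_id),
                )
                removed += cur.rowcount
                cur = self.conn.execute(
                    f"DELETE FROM {PATIENT_TABLE} WHERE _device = ? "
                    "AND _client_pk = ? AND _group_id = ?",
                    (device, cpk, group_id),
                )
                removed += cur.rowcount
            self.conn.execute(
                "INSERT INTO audit (when_, who, what, details) "
                "VALUES (?, ?, ?, ?)",
                (
                    format_iso(now_utc()), username, "delete",
                    f"patient linking-id {patient_key} in group {group_id}: "
                    f"{removed} rows",
                ),
            )
            self.conn.execute("COMMIT")
        except BaseException:
            self.conn.execute("ROLLBACK")
            raise
        return removed

    def annotate(self, table: str, server_pk: int, username: str,
                 note: str) -> int:
        """Append a manual note to a record without altering its content."""
        user = self.get_user(username)
        row = self.get_row(table, server_pk)
        decision = authorize_action(
            user, self.memberships_of(user.user_id), "add_notes",
            row["_group_id"],
        )
        if not decision:
            raise PermissionDenied(decision.reason)
        cur = self.conn.execute(
            "INSERT INTO annotations (table_name, server_pk, who, when_, note) "
            "VALUES (?, ?, ?, ?, ?)",
            (table, server_pk, username, format_iso(now_utc()), note),
        )
        self.audit(username, "annotate", f"{table}._pk={server_pk}")
        return cur.lastrowid

    def annotations_for(self, table: str, server_pk: int) -> list[sqlite3.Row]:
        return list(
            self.conn.execute(
                "SELECT * FROM annotations WHERE table_name = ? "
                "AND server_pk = ? ORDER BY annotation_id",
                (table, server_pk),
            )
        )

    # ------------------------------------------------------------ debugging

    def dump_state(self, include_audit: bool = False) -> dict[str, list[tuple]]:
        """Full store contents as plain tuples, for snapshot comparison."""
        tables = self._all_tables() + ["devices", "groups", "users",
                                       "memberships", "annotations",
                                       "finalized_client_pks"]
        if include_audit:
            tables.append("audit")
        out = {}
        for table in tables:
            rows = self.conn.execute(f'SELECT * FROM "{table}"').fetchall()
            out[table] = sorted(tuple(r) for r in rows)
        return out
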