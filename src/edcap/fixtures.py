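"""Deterministic synthetic-data generator.

Produces a complete exercising dataset — server bootstrap (ID-number
definitions, groups with policies, users, memberships) plus client upload
batches — without touching any external data.  Two policy scenarios mirror
the canonical deployment patterns:

* ``research_pseudonym`` — a pseudonymised study: policy
  ``sex AND idnum1 AND NOT (forename OR surname OR dob)``; generated
  subjects carry a sex code and a research ID and nothing else.
* ``clinical_multi_hospital`` — a fully identifiable clinical service
  spanning hospitals: upload policy
  ``forename AND surname AND dob AND sex AND (idnum1 OR idnum2 OR idnum3)``
  and a stricter finalizing policy requiring the home institution's
  idnum1.  A configurable fraction of patients arrive with only the other
  hospital's number, so they upload fine but cannot be finalized until
  idnum1 is filled in.

Generated NHS numbers are valid by construction (the modulus-11 check
digit is computed, and nine-digit prefixes whose check digit would be 10
are re-drawn).  PHQ-9 answers are uniform on 0-3; a configurable fraction
of instances are left incomplete; a configurable fraction of patients get
a duplicate device record with a one-character surname misspelling, to
trigger identity-conflict detection.  The same seed always yields
byte-identical payloads.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Optional

from ._time import format_iso
from .identity import IdNumDefinition, ValidationMethod, nhs_check_digit
from .store import Server, ServerConfig, UploadBatch
from .security import AuthConfig

__all__ = ["FixtureConfig", "Fixture", "generate", "build_server"]

RESEARCH_UPLOAD_POLICY = "sex AND idnum1"
RESEARCH_FINALIZE_POLICY = (
    "sex AND idnum1 AND NOT (forename OR surname OR dob)"
)
CLINICAL_UPLOAD_POLICY = (
    "forename AND surname AND dob AND sex AND (idnum1 OR idnum2 OR idnum3)"
)
CLINICAL_FINALIZE_POLICY = "forename AND surname AND dob AND sex AND idnum1"

# Small neutral word lists; combinations are not real-person likenesses.
_FORENAMES = (
    "Alex", "Blake", "Casey", "Drew", "Ellis", "Frankie", "Gray", "Harper",
    "Indigo", "Jules", "Kit", "Lane", "Morgan", "Noor", "Oak", "Perry",
    "Quinn", "Reese", "Sage", "Tatum",
)
_SURNAMES = (
    "Abbey", "Birch", "Cedarwood", "Dunmore", "Eastfield", "Fernly",
    "Garnet", "Hollis", "Ivywell", "Juniper", "Kestrel", "Larkspur",
    "Midford", "Northgate", "Oakden", "Pimlico", "Quarry", "Rowanby",
    "Stonely", "Thistle",
)

_EPOCH = datetime(2020, 1, 6, 9, 0, 0, tzinfo=timezone.utc)


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    n_patients: int = 10
    n_devices: int = 2
    n_groups: int = 2
    tasks_per_patient: int = 3
    fraction_incomplete: float = 0.1
    conflict_rate: float = 0.0     # fraction given a misspelled duplicate
    # fraction of clinical patients lacking idnum1 (fail finalize policy)
    fraction_unfinalizable: float = 0.0
    policy_scenario: str = "research_pseudonym"
    hash_cost: int = 1000          # fast hashing for synthetic users

    def __post_init__(self):
        for name in ("fraction_incomplete", "conflict_rate",
                     "fraction_unfinalizable"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.policy_scenario not in (
            "research_pseudonym", "clinical_multi_hospital"
        ):
            raise ValueError(
                f"unknown policy scenario: {self.policy_scenario!r}"
            )


@dataclass
class Fixture:
    """Everything needed to bootstrap a server and feed it uploads."""

    config: FixtureConfig
    idnum_definitions: dict[int, IdNumDefinition]
    upload_policy: str
    finalize_policy: str
    batches: list[UploadBatch]
    # patients that deliberately fail the finalizing policy (clinical
    # scenario: missing idnum1)
    unfinalizable_patients: list[int] = field(default_factory=list)
    # client pks of patients given a conflicting duplicate on another device
    conflicted_patients: list[int] = field(default_factory=list)

    def payload_json(self) -> str:
        return json.dumps([json.loads(b.to_json()) for b in self.batches],
                          indent=2, sort_keys=True)


def _nhs_number(rng: random.Random) -> int:
    while True:
        first_nine = [rng.randrange(1, 10)] + [rng.randrange(10)
                                               for _ in range(8)]
        check = nhs_check_digit(first_nine)
        if check != 10:
            return int("".join(map(str, first_nine + [check])))


def _phq9_values(rng: random.Random, incomplete: bool) -> dict:
    values = {f"q{i}": rng.randrange(4) for i in range(1, 11)}
    if incomplete:
        del values[f"q{rng.randrange(1, 11)}"]
    return values


def generate(config: FixtureConfig) -> Fixture:
    """Generate a deterministic fixture for the configured scenario."""
    rng = random.Random(config.seed)
    research = config.policy_scenario == "research_pseudonym"

    if research:
        iddefs = {1: IdNumDefinition(1, "Research ID", "RID")}
        upload_policy, finalize_policy = (
            RESEARCH_UPLOAD_POLICY, RESEARCH_FINALIZE_POLICY,
        )
    else:
        iddefs = {
            1: IdNumDefinition(1, "Hospital A number", "HospA"),
            2: IdNumDefinition(2, "Hospital B number", "HospB"),
            3: IdNumDefinition(3, "NHS number", "NHS",
                               ValidationMethod.NHS_MODULUS_11),
        }
        upload_policy, finalize_policy = (
            CLINICAL_UPLOAD_POLICY, CLINICAL_FINALIZE_POLICY,
        )

    devices = [f"device-{d}" for d in range(config.n_devices)]
    batches: list[UploadBatch] = []
    unfinalizable: list[int] = []
    conflicted: list[int] = []

    per_device: dict[str, dict] = {
        d: {"patients": [], "idnums": [], "tasks": {}, "next_idnum_pk": 1,
            "next_task_pk": {}}
        for d in devices
    }

    when = _EPOCH
    for i in range(config.n_patients):
        device = devices[i % len(devices)]
        state = per_device[device]
        cpk = len(state["patients"]) + 1
        when += timedelta(hours=1)

        patient: dict = {"client_pk": cpk,
                         "when_last_modified": format_iso(when)}
        idnum_rows: list[dict] = []

        def add_idnum(which: int, value: int) -> None:
            idnum_rows.append({
                "client_pk": state["next_idnum_pk"],
                "patient_client_pk": cpk,
                "which_idnum": which,
                "idnum_value": value,
                "when_last_modified": format_iso(when),
            })
            state["next_idnum_pk"] += 1

        if research:
            patient["sex"] = rng.choice(["M", "F", "X"])
            add_idnum(1, 10_000 + i)
        else:
            patient["forename"] = rng.choice(_FORENAMES)
            patient["surname"] = rng.choice(_SURNAMES)
            patient["dob"] = (
                f"{rng.randrange(1940, 2006)}-"
                f"{rng.randrange(1, 13):02d}-{rng.randrange(1, 29):02d}"
            )
            patient["sex"] = rng.choice(["M", "F", "X"])
            add_idnum(3, _nhs_number(rng))
            if i < round(config.fraction_unfinalizable * config.n_patients):
                # Seen at Hospital B only: no idnum1 yet, so the record
                # uploads but cannot be finalized.
                add_idnum(2, 500_000 + i)
                unfinalizable.append(cpk)
            else:
                add_idnum(1, 100_000 + i)

        state["patients"].append(patient)
        state["idnums"].extend(idnum_rows)

        for _ in range(config.tasks_per_patient):
            when += timedelta(minutes=17)
            table = rng.choice(["phq9", "bmi"])
            pks = state["next_task_pk"]
            pks.setdefault(table, 1)
            row: dict = {
                "client_pk": pks[table],
                "patient_client_pk": cpk,
                "when_created": format_iso(when),
                "when_first_exited": format_iso(when + timedelta(minutes=4)),
                "first_exit_was_finish": True,
                "first_exit_was_abort": False,
                "when_last_modified": format_iso(when + timedelta(minutes=4)),
            }
            incomplete = rng.random() < config.fraction_incomplete
            if table == "phq9":
                row.update(_phq9_values(rng, incomplete))
            else:
                row["height_m"] = round(rng.uniform(1.45, 1.95), 2)
                if not incomplete:
                    row["mass_kg"] = round(rng.uniform(45, 120), 1)
            pks[table] += 1
            state["tasks"].setdefault(table, []).append(row)

        if (
            not research
            and i < round(config.conflict_rate * config.n_patients)
        ):
            # A second device holds a copy with a one-character surname slip.
            other = devices[(i + 1) % len(devices)]
            if other != device:
                ostate = per_device[other]
                ocpk = len(ostate["patients"]) + 1
                dup = dict(patient, client_pk=ocpk)
                surname = dup.get("surname", "Anon")
                pos = rng.randrange(len(surname))
                dup["surname"] = (
                    surname[:pos]
                    + rng.choice("aeiouy".replace(surname[pos].lower(), "")
                                 or "z")
                    + surname[pos + 1:]
                )
                ostate["patients"].append(dup)
                for r in idnum_rows:
                    ostate["idnums"].append(dict(
                        r, client_pk=ostate["next_idnum_pk"],
                        patient_client_pk=ocpk,
                    ))
                    ostate["next_idnum_pk"] += 1
                conflicted.append(cpk)

    # One anonymous survey per device exercises the anonymous pathway.
    for d_i, device in enumerate(devices):
        state = per_device[device]
        when += timedelta(minutes=3)
        state["tasks"].setdefault("anon_survey", []).append({
            "client_pk": 1,
            "satisfaction": rng.randrange(11),
            "when_created": format_iso(when),
            "when_last_modified": format_iso(when),
        })

    for d_i, device in enumerate(devices):
        state = per_device[device]
        batches.append(
            UploadBatch(
                device_id=device,
                username="uploader",
                group_id=1,
                mode="copy",
                patients=state["patients"],
                idnums=state["idnums"],
                tasks=state["tasks"],
            )
        )

    return Fixture(
        config=config,
        idnum_definitions=iddefs,
        upload_policy=upload_policy,
        finalize_policy=finalize_policy,
        batches=batches,
        unfinalizable_patients=unfinalizable,
        conflicted_patients=conflicted,
    )


def build_server(
    fixture: Fixture,
    path: str = ":memory:",
    apply_uploads: bool = True,
) -> Server:
    """Bootstrap a server from a fixture and (optionally) apply its batches.

    Creates the groups (group 1 receives the uploads; further groups are
    empty bystanders for visibility tests), an ``admin`` superuser and an
    ``uploader`` staff user, and registers each fixture device.  Device IDs
    in the batches are rewritten to the server-issued identifiers.
    """
    cfg = fixture.config
    server = Server(
        path,
        ServerConfig(
            idnum_definitions=fixture.idnum_definitions,
            linking_idnum=1 if cfg.policy_scenario == "research_pseudonym"
            else 3,
            auth=AuthConfig(hash_cost=cfg.hash_cost),
        ),
    )
    server.create_user("admin", "admin-password", status="superuser")
    server.create_user("uploader", "uploader-password")
    gid = server.create_group("g1", fixture.upload_policy,
                              fixture.finalize_policy)
    for g in range(2, cfg.n_groups + 1):
        server.create_group(f"g{g}", fixture.upload_policy,
                            fixture.finalize_policy)
    server.add_membership("uploader", gid, may_upload=True,
                          may_register_devices=True)
    mapping: dict[str, str] = {}
    for batch in fixture.batches:
        if batch.device_id not in mapping:
            record = server.register_device(
                "uploader", batch.device_id, gid
            )
            mapping[batch.device_id] = record.device_id
        batch.device_id = mapping[batch.device_id]
        if apply_uploads:
            server.apply_upload(batch)
    return server
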