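"""Versioned record store: upload semantics, history chains, atomicity,
era finalization, and administrative operations."""

from __future__ import annotations

import random

import pytest

from edcap.store import (
    ERA_NOW,
    DeviceNotRegistered,
    FinalizePolicyViolation,
    PermissionDenied,
    PolicyMismatch,
    Server,
    StoreError,
    UnknownTableError,
    UploadBatch,
    UploadPolicyViolation,
)
from edcap.tasks import UnknownFieldError

from conftest import (
    NHS_VALID,
    T0,
    T1,
    T2,
    clinical_server,
    make_batch,
    patient_row,
    phq9_row,
)


class TestRegistration:
    def test_registration_returns_policy_snapshot(self, server):
        record = server.register_device("clin", "tablet", 1)
        assert record.upload_policy.startswith("forename AND surname")
        assert record.finalize_policy.endswith("idnum1")
        assert "NHS number" in record.iddefs_snapshot
        assert server.audit_events("registration")

    def test_unauthorized_user_refused(self, server):
        server.create_user("nobody", "pw")
        with pytest.raises(PermissionDenied):
            server.register_device("nobody", "tablet", 1)

    def test_device_ids_distinct(self, server):
        a = server.register_device("clin", "t1", 1)
        b = server.register_device("clin", "t2", 1)
        assert a.device_id != b.device_id

    def test_unregistered_device_cannot_upload(self, server):
        patient, idnums = patient_row()
        with pytest.raises(DeviceNotRegistered):
            server.apply_upload(make_batch("bogus", patients=[patient],
                                           idnums=idnums))


class TestUploadVersioning:
    def test_first_upload_inserts_current_now_rows(self, server, device):
        patient, idnums = patient_row()
        report = server.apply_upload(
            make_batch(device.device_id, patients=[patient], idnums=idnums,
                       tasks={"phq9": [phq9_row()]})
        )
        assert report.inserted == 4 and report.superseded == 0
        row = server.conn.execute("SELECT * FROM phq9").fetchone()
        assert row["_era"] == ERA_NOW and row["_current"] == 1
        assert row["_predecessor_pk"] is None

    def test_reupload_changed_row_supersedes(self, server, device):
        patient, idnums = patient_row()
        server.apply_upload(
            make_batch(device.device_id, patients=[patient], idnums=idnums,
                       tasks={"phq9": [phq9_row(when=T0)]})
        )
        server.apply_upload(
            make_batch(device.device_id, patients=[patient], idnums=idnums,
                       tasks={"phq9": [phq9_row(when=T1, q1=3)]})
        )
        rows = server.conn.execute(
            "SELECT * FROM phq9 ORDER BY _pk"
        ).fetchall()
        assert len(rows) == 2
        old, new = rows
        assert old["_current"] == 0 and new["_current"] == 1
        assert old["_successor_pk"] == new["_pk"]
        assert new["_predecessor_pk"] == old["_pk"]
        assert old["_when_removed"] is not None
        assert old["_removing_user"] == "clin"
        assert new["q1"] == 3 and old["q1"] == 1

    def test_unchanged_rows_untouched(self, server, device):
        patient, idnums = patient_row()
        batch = make_batch(device.device_id, patients=[patient],
                           idnums=idnums, tasks={"phq9": [phq9_row()]})
        server.apply_upload(batch)
        before = server.dump_state()
        report = server.apply_upload(batch)
        assert report.unchanged == 4 and report.inserted == 0
        assert server.dump_state() == before

    def test_history_chain_after_three_uploads(self, server, device):
        patient, idnums = patient_row()
        for i, when in enumerate((T0, T1, T2)):
            server.apply_upload(
                make_batch(device.device_id, patients=[patient],
                           idnums=idnums,
                           tasks={"phq9": [phq9_row(when=when, q1=i)]})
            )
        head = server.conn.execute(
            "SELECT _pk FROM phq9 WHERE _current = 1"
        ).fetchone()["_pk"]
        chain = server.history_chain("phq9", head)
        assert len(chain) == 3
        assert [r["q1"] for r in chain] == [0, 1, 2]
        assert sum(r["_current"] for r in chain) == 1
        # the same chain is reachable from its root
        root_chain = server.history_chain("phq9", chain[0]["_pk"])
        assert [r["_pk"] for r in root_chain] == [r["_pk"] for r in chain]

    def test_never_modified_row_chain_length_one(self, server, device):
        patient, idnums = patient_row()
        server.apply_upload(make_batch(device.device_id, patients=[patient],
                                       idnums=idnums))
        pk = server.conn.execute("SELECT _pk FROM patient").fetchone()["_pk"]
        assert len(server.history_chain("patient", pk)) == 1


class TestPolicyGates:
    def test_upload_policy_violation_lists_offenders(self, server, device):
        patient, idnums = patient_row()
        del patient["surname"]
        with pytest.raises(UploadPolicyViolation) as err:
            server.apply_upload(make_batch(device.device_id,
                                           patients=[patient],
                                           idnums=idnums))
        assert err.value.offenders == [1]
        assert server.conn.execute("SELECT COUNT(*) FROM patient"
                                   ).fetchone()[0] == 0

    def test_hospital_b_patient_uploads_but_cannot_move(self, server, device):
        """A patient identified only by the other hospital's number and the
        NHS number uploads under the clinical upload policy, but a move is
        refused until the home institution's idnum1 is added."""
        patient, idnums = patient_row(idnum1=False)
        idnums.append({"client_pk": 99, "patient_client_pk": 1,
                       "which_idnum": 2, "idnum_value": 555,
                       "when_last_modified": T0})
        batch = make_batch(device.device_id, patients=[patient],
                           idnums=idnums, tasks={"phq9": [phq9_row()]})
        server.apply_upload(batch)  # copy: accepted
        move = make_batch(device.device_id, mode="move", patients=[patient],
                          idnums=idnums, tasks={"phq9": [phq9_row()]})
        before = server.dump_state()
        with pytest.raises(FinalizePolicyViolation):
            server.apply_upload(move)
        assert server.dump_state() == before  # whole batch rejected
        # completing the record with idnum1 allows the move
        idnums.append({"client_pk": 100, "patient_client_pk": 1,
                       "which_idnum": 1, "idnum_value": 4242,
                       "when_last_modified": T1})
        server.apply_upload(
            make_batch(device.device_id, mode="move", patients=[patient],
                       idnums=idnums, tasks={"phq9": [phq9_row()]})
        )
        left = server.conn.execute(
            "SELECT COUNT(*) FROM phq9 WHERE _era = ?", (ERA_NOW,)
        ).fetchone()[0]
        assert left == 0

    def test_policy_mismatch_requires_reregistration(self, server, device):
        server.conn.execute(
            "UPDATE groups SET upload_policy = 'sex AND idnum1'"
        )
        patient, idnums = patient_row()
        with pytest.raises(PolicyMismatch):
            server.apply_upload(make_batch(device.device_id,
                                           patients=[patient],
                                           idnums=idnums))

    def test_unknown_table_refused(self, server, device):
        with pytest.raises(UnknownTableError):
            server.apply_upload(
                make_batch(device.device_id, tasks={"made_up": []})
            )

    def test_unknown_field_refused(self, server, device):
        patient, idnums = patient_row()
        row = phq9_row()
        row["bonus_field"] = 1
        with pytest.raises(UnknownFieldError):
            server.apply_upload(
                make_batch(device.device_id, patients=[patient],
                           idnums=idnums, tasks={"phq9": [row]})
            )

    def test_invalid_checksum_idnum_refused(self, server, device):
        patient, idnums = patient_row()
        idnums[0]["idnum_value"] = NHS_VALID - 1  # breaks the check digit
        with pytest.raises(StoreError):
            server.apply_upload(make_batch(device.device_id,
                                           patients=[patient],
                                           idnums=idnums))

    def test_invalid_task_row_refused(self, server, device):
        patient, idnums = patient_row()
        with pytest.raises(StoreError):
            server.apply_upload(
                make_batch(device.device_id, patients=[patient],
                           idnums=idnums,
                           tasks={"phq9": [phq9_row(q3=7)]})
            )


class TestEraSemantics:
    def test_move_finalizes_every_device_row(self, server, device):
        patient, idnums = patient_row()
        server.apply_upload(
            make_batch(device.device_id, mode="move", patients=[patient],
                       idnums=idnums, tasks={"phq9": [phq9_row()]})
        )
        for table in ("patient", "patient_idnum", "phq9"):
            n_now = server.conn.execute(
                f"SELECT COUNT(*) FROM {table} WHERE _era = ?", (ERA_NOW,)
            ).fetchone()[0]
            assert n_now == 0, table
        era = server.conn.execute("SELECT _era FROM phq9").fetchone()["_era"]
        assert era != ERA_NOW  # an ISO timestamp

    def test_move_keeping_patients_recreates_identity_rows(self, server,
                                                           device):
        patient, idnums = patient_row()
        server.apply_upload(
            make_batch(device.device_id, mode="move_keeping_patients",
                       patients=[patient], idnums=idnums,
                       tasks={"phq9": [phq9_row()]})
        )
        assert server.conn.execute(
            "SELECT COUNT(*) FROM phq9 WHERE _era = ?", (ERA_NOW,)
        ).fetchone()[0] == 0
        fresh = server.conn.execute(
            "SELECT * FROM patient WHERE _era = ?", (ERA_NOW,)
        ).fetchall()
        assert len(fresh) == 1
        assert fresh[0]["_predecessor_pk"] is not None
        ancestor = server.get_row("patient", fresh[0]["_predecessor_pk"])
        assert ancestor["_era"] != ERA_NOW
        assert ancestor["surname"] == fresh[0]["surname"]

    def test_copy_finalizes_only_finished_rows(self, server, device):
        p1, id1 = patient_row(cpk=1)
        p2, id2 = patient_row(cpk=2)
        id2[0]["idnum_value"] = 9434765919  # same NHS number ok for test
        server.apply_upload(
            make_batch(device.device_id, mode="copy", patients=[p1, p2],
                       idnums=id1 + id2,
                       tasks={"phq9": [phq9_row(cpk=1, patient_cpk=1),
                                       phq9_row(cpk=2, patient_cpk=2)]},
                       finished_patients=[1])
        )
        eras = {
            r["_client_pk"]: r["_era"]
            for r in server.conn.execute("SELECT _client_pk, _era FROM patient")
        }
        assert eras[1] != ERA_NOW and eras[2] == ERA_NOW
        task_eras = {
            r["patient_client_pk"]: r["_era"]
            for r in server.conn.execute(
                "SELECT patient_client_pk, _era FROM phq9")
        }
        assert task_eras[1] != ERA_NOW and task_eras[2] == ERA_NOW

    def test_finalized_client_pk_cannot_be_reuploaded(self, server, device):
        patient, idnums = patient_row()
        server.apply_upload(
            make_batch(device.device_id, mode="copy", patients=[patient],
                       idnums=idnums, finished_patients=[1])
        )
        with pytest.raises(StoreError):
            server.apply_upload(
                make_batch(device.device_id, patients=[patient],
                           idnums=idnums)
            )

    def test_client_pks_reusable_after_full_move(self, server, device):
        patient, idnums = patient_row()
        server.apply_upload(
            make_batch(device.device_id, mode="move", patients=[patient],
                       idnums=idnums)
        )
        # after a move the device wipes itself; client pk 1 is a new record
        report = server.apply_upload(
            make_batch(device.device_id, patients=[patient], idnums=idnums)
        )
        assert report.inserted == 3


class TestAtomicity:
    def test_fault_at_every_boundary_leaves_store_unchanged(self, server,
                                                            device):
        patient, idnums = patient_row()
        baseline_batch = make_batch(
            device.device_id, patients=[patient], idnums=idnums,
            tasks={"phq9": [phq9_row()]},
        )
        server.apply_upload(baseline_batch)
        before = server.dump_state()
        changed = make_batch(
            device.device_id, mode="move", patients=[patient], idnums=idnums,
            tasks={"phq9": [phq9_row(q1=3, when=T1)],
                   "bmi": [{"client_pk": 1, "patient_client_pk": 1,
                            "height_m": 1.8, "mass_kg": 81.0,
                            "when_created": T1,
                            "when_last_modified": T1}]},
        )
        boundary = 0
        while True:
            calls = {"n": 0}

            def fault_hook():
                calls["n"] += 1
                if calls["n"] > boundary:
                    raise RuntimeError("injected fault")

            try:
                server.apply_upload(changed, fault_hook=fault_hook)
            except RuntimeError:
                assert server.dump_state() == before, (
                    f"store changed after fault at boundary {boundary}"
                )
                boundary += 1
            else:
                break  # batch ran to completion: every boundary was faulted
        assert boundary > 3  # several distinct statement boundaries exercised
        assert server.dump_state() != before  # final clean run applied


class TestRandomizedInvariants:
    def test_invariants_under_random_upload_sequences(self):
        """Exactly-one-current, finalization totality and chain acyclicity
        hold under hundreds of randomized uploads from three devices."""
        rng = random.Random(424242)
        server = clinical_server()
        devices = [server.register_device("clin", f"t{i}", 1)
                   for i in range(3)]
        state = {d.device_id: 0 for d in devices}  # patients per device
        n_ops = 300
        for op in range(n_ops):
            device = rng.choice(devices)
            n = state[device.device_id] = max(
                1, min(state[device.device_id] + rng.choice([0, 0, 1]), 5)
            )
            patients, idnums, tasks = [], [], []
            for cpk in range(1, n + 1):
                p, ids = patient_row(
                    cpk=cpk, surname=rng.choice(["Hollis", "Birch", "Oak"]),
                    when=f"2024-03-01T{9 + op % 12:02d}:00:00.000+00:00",
                )
                patients.append(p)
                idnums.extend(ids)
                tasks.append(phq9_row(cpk=cpk, patient_cpk=cpk,
                                      q1=rng.randrange(4),
                                      when=T0))
            mode = rng.choice(["copy", "copy", "copy", "move",
                               "move_keeping_patients"])
            batch = make_batch(device.device_id, mode=mode,
                               patients=patients, idnums=idnums,
                               tasks={"phq9": tasks})
            server.apply_upload(batch)
            if mode == "move":
                state[device.device_id] = 0
                for table in ("patient", "patient_idnum", "phq9"):
                    left = server.conn.execute(
                        f"SELECT COUNT(*) FROM {table} WHERE _device = ? "
                        "AND _era = ?",
                        (device.device_id, ERA_NOW),
                    ).fetchone()[0]
                    assert left == 0  # finalization totality

        for table in ("patient", "patient_idnum", "phq9"):
            dupes = server.conn.execute(
                f"SELECT _device, _client_pk, COUNT(*) AS n FROM {table} "
                "WHERE _era = ? AND _current = 1 "
                "GROUP BY _device, _client_pk HAVING n > 1",
                (ERA_NOW,),
            ).fetchall()
            assert dupes == []  # exactly one current row per live record
            for row in server.conn.execute(f"SELECT _pk FROM {table}"):
                server.history_chain(table, row["_pk"])  # raises on cycles
        server.close()


class TestAdministrativeOperations:
    def _one_phq9(self, server, device):
        patient, idnums = patient_row()
        server.apply_upload(
            make_batch(device.device_id, patients=[patient], idnums=idnums,
                       tasks={"phq9": [phq9_row()]})
        )
        return server.conn.execute("SELECT _pk FROM phq9").fetchone()["_pk"]

    def test_erase_nulls_content_keeps_envelope(self, server, device):
        pk = self._one_phq9(server, device)
        server.erase_task("phq9", pk, "admin")
        row = server.get_row("phq9", pk)
        assert all(row[f"q{i}"] is None for i in range(1, 11))
        assert row["when_created"] == T0  # instance timestamps intact
        assert row["_when_added"] is not None and row["_current"] == 1
        assert server.audit_events("erase")

    def test_erase_requires_privilege(self, server, device):
        pk = self._one_phq9(server, device)
        with pytest.raises(PermissionDenied):
            server.erase_task("phq9", pk, "clin")

    def test_delete_patient_removes_all_rows_across_eras(self, server,
                                                         device):
        patient, idnums = patient_row()
        # era 1 (finalized via move) ...
        server.apply_upload(
            make_batch(device.device_id, mode="move", patients=[patient],
                       idnums=idnums,
                       tasks={"phq9": [phq9_row()],
                              "bmi": [{"client_pk": 1,
                                       "patient_client_pk": 1,
                                       "height_m": 1.7, "mass_kg": 70.0,
                                       "when_created": T0,
                                       "when_last_modified": T0}]})
        )
        # ... then a second live era with two more tasks
        server.apply_upload(
            make_batch(device.device_id, patients=[patient], idnums=idnums,
                       tasks={"phq9": [phq9_row(when=T1)],
                              "bmi": [{"client_pk": 1,
                                       "patient_client_pk": 1,
                                       "height_m": 1.7, "mass_kg": 71.0,
                                       "when_created": T1,
                                       "when_last_modified": T1}]})
        )
        removed = server.delete_patient(NHS_VALID, 1, "admin")
        assert removed > 0
        for table in ("patient", "patient_idnum", "phq9", "bmi"):
            assert server.conn.execute(
                f"SELECT COUNT(*) FROM {table}"
            ).fetchone()[0] == 0, table
        assert server.audit_events("delete")

    def test_deleted_chain_versions_retained_on_erase_not_delete(
        self, server, device
    ):
        patient, idnums = patient_row()
        for when, q1 in ((T0, 0), (T1, 3)):
            server.apply_upload(
                make_batch(device.device_id, patients=[patient],
                           idnums=idnums,
                           tasks={"phq9": [phq9_row(when=when, q1=q1)]})
            )
        assert server.conn.execute(
            "SELECT COUNT(*) FROM phq9"
        ).fetchone()[0] == 2  # superseded version kept

    def test_annotate_appends_note_without_altering_content(self, server,
                                                            device):
        pk = self._one_phq9(server, device)
        server.add_membership("clin", 1, may_upload=True, may_add_notes=True)
        before = tuple(server.get_row("phq9", pk))
        server.annotate("phq9", pk, "clin", "patient disputes item 3")
        assert tuple(server.get_row("phq9", pk)) == before
        notes = server.annotations_for("phq9", pk)
        assert len(notes) == 1
        assert notes[0]["note"] == "patient disputes item 3"

    def test_annotate_requires_note_permission(self, server, device):
        pk = self._one_phq9(server, device)
        with pytest.raises(PermissionDenied):
            server.annotate("phq9", pk, "clin", "no permission")


class TestPayloadDialects:
    def test_json_round_trip(self, server, device):
        patient, idnums = patient_row()
        batch = make_batch(device.device_id, patients=[patient],
                           idnums=idnums, tasks={"phq9": [phq9_row()]})
        again = UploadBatch.from_json(batch.to_json())
        assert again == batch

    def test_sqlite_payload(self, tmp_path, server, device):
        import json
        import sqlite3 as sq

        patient, idnums = patient_row()
        path = str(tmp_path / "payload.sqlite")
        conn = sq.connect(path)
        conn.execute("CREATE TABLE _upload_meta (key TEXT, value TEXT)")
        meta = {
            "device_id": device.device_id, "username": "clin",
            "group_id": "1", "mode": "copy",
            "task_tables": json.dumps(["phq9"]),
        }
        conn.executemany("INSERT INTO _upload_meta VALUES (?, ?)",
                         meta.items())

        def write(table, rows):
            cols = sorted({k for r in rows for k in r})
            conn.execute(
                f"CREATE TABLE {table} ({', '.join(cols)})"
            )
            for r in rows:
                conn.execute(
                    f"INSERT INTO {table} ({', '.join(r)}) VALUES "
                    f"({', '.join('?' * len(r))})",
                    list(r.values()),
                )

        write("patient", [patient])
        write("patient_idnum", idnums)
        write("phq9", [phq9_row()])
        conn.commit()
        conn.close()

        batch = UploadBatch.from_sqlite(path)
        report = server.apply_upload(batch)
        assert report.inserted == 4


class TestOneWayExchange:
    def test_upload_report_carries_no_content(self, server, device):
        patient, idnums = patient_row()
        report = server.apply_upload(
            make_batch(device.device_id, patients=[patient], idnums=idnums,
                       tasks={"phq9": [phq9_row()]})
        )
        payload = vars(report)
        for leaked in ("Hollis", "Alex", str(NHS_VALID)):
            assert leaked not in str(payload)
        assert set(payload) == {"inserted", "superseded", "unchanged",
                                "finalized", "when"}
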