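from __future__ import annotations

import pytest

from edcap.fixtures import (
    CLINICAL_FINALIZE_POLICY,
    CLINICAL_UPLOAD_POLICY,
    FixtureConfig,
    build_server,
    generate,
)
from edcap.identity import IdNumDefinition, ValidationMethod
from edcap.security import AuthConfig
from edcap.store import Server, ServerConfig, UploadBatch

FAST_AUTH = AuthConfig(hash_cost=500)

T0 = "2024-03-01T09:00:00.000+00:00"
T1 = "2024-03-01T10:00:00.000+00:00"
T2 = "2024-03-01T11:00:00.000+00:00"


def clinical_server(**kwargs) -> Server:
    """A server configured for the identifiable multi-hospital scenario:
    idnum1 = Hospital A (home institution), idnum2 = Hospital B,
    idnum3 = NHS number; linking key is the NHS number."""
    config = ServerConfig(
        idnum_definitions={
            1: IdNumDefinition(1, "Hospital A number", "HospA"),
            2: IdNumDefinition(2, "Hospital B number", "HospB"),
            3: IdNumDefinition(3, "NHS number", "NHS",
                               ValidationMethod.NHS_MODULUS_11),
        },
        linking_idnum=3,
        auth=FAST_AUTH,
    )
    server = Server(":memory:", config)
    server.create_user("admin", "pw-admin", status="superuser")
    server.create_user("clin", "pw-clin")
    gid = server.create_group("clinical", CLINICAL_UPLOAD_POLICY,
                              CLINICAL_FINALIZE_POLICY, **kwargs)
    server.add_membership("clin", gid, may_upload=True,
                          may_register_devices=True)
    return server


# A valid NHS number (check digit 9 over prefix 943476591).
NHS_VALID = 9434765919


def patient_row(cpk=1, surname="Hollis", idnum1=True, when=T0):
    patient = {
        "client_pk": cpk,
        "forename": "Alex",
        "surname": surname,
        "dob": "1980-01-01",
        "sex": "F",
        "when_last_modified": when,
    }
    idnums = [
        {"client_pk": cpk * 10, "patient_client_pk": cpk, "which_idnum": 3,
         "idnum_value": NHS_VALID, "when_last_modified": when},
    ]
    if idnum1:
        idnums.append(
            {"client_pk": cpk * 10 + 1, "patient_client_pk": cpk,
             "which_idnum": 1, "idnum_value": 100 + cpk,
             "when_last_modified": when}
        )
    return patient, idnums


def phq9_row(cpk=1, patient_cpk=1, when=T0, **answers):
    values = {f"q{i}": 1 for i in range(1, 11)}
    values.update(answers)
    return {
        "client_pk": cpk,
        "patient_client_pk": patient_cpk,
        "when_created": when,
        "when_first_exited": when,
        "first_exit_was_finish": True,
        "first_exit_was_abort": False,
        "when_last_modified": when,
        **values,
    }


def make_batch(device_id, mode="copy", patients=(), idnums=(), tasks=None,
               **kwargs):
    return UploadBatch(
        device_id=device_id,
        username="clin",
        group_id=1,
        mode=mode,
        patients=list(patients),
        idnums=list(idnums),
        tasks=tasks or {},
        **kwargs,
    )


@pytest.fixture
def server():
    s = clinical_server()
    yield s
    s.close()


@pytest.fixture
def device(server):
    return server.register_device("clin", "tablet-1", 1)


@pytest.fixture
def research_store():
    """Populated pseudonymised-research store built from the fixture
    generator (seed 7)."""
    fixture = generate(FixtureConfig(seed=7, n_patients=8, n_devices=2,
                                     policy_scenario="research_pseudonym"))
    s = build_server(fixture)
    yield fixture, s
    s.close()
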