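# edcap

Server core for secure electronic data capture in psychiatry, psychology
and the clinical neurosciences. Client devices capture raw assessment
answers (questionnaires such as the PHQ-9, clinical measurements such as
BMI) offline and upload them to an institution-controlled server. This
package implements that server's substance:

- **Subject-identification policies** — boolean expressions over the
  presence of identity attributes (e.g.
  `sex AND idnum1 AND NOT (forename OR surname OR dob)` for a
  pseudonymised study, or
  `forename AND surname AND dob AND sex AND (idnum1 OR idnum2 OR idnum3)`
  for a multi-hospital clinical service), in two flavours: an *upload*
  policy and a stricter *finalizing* policy that gates erasing data from
  the device. ID number types are administrator-defined and can carry
  checksum validation (NHS modulus-11).
- **A versioned, audit-trailed record store** — atomic upload batches
  from registered devices; every row wrapped in an envelope with a
  `current` flag, an `era` (`"NOW"` while live on the device, else the
  finalization instant), addition/removal stamps and
  predecessor/successor links, so every modification leaves an
  inspectable history. Move / move-keeping-patients / copy upload modes;
  content erasure, whole-patient deletion, and annotation.
- **Group-based access control** — groups own data and carry their own
  policies; per-membership permission flags; explicit, one-step,
  directional cross-group visibility; superusers and single-patient
  locked users; deny by default on every read path.
- **Live scoring (DRY)** — only raw answers are stored; summary scores
  (PHQ-9 total 0–27 and severity band, BMI in kg/m²) are computed at
  the moment of request, everywhere they appear.
- **Security machinery** — salted adaptive password hashing, account
  lockout with increasing periods, login-failure mimicry for nonexistent
  usernames, IP-bound sessions with inactivity expiry and token
  regeneration at login, and the mean brute-force key-search time
  0.5·2ⁿ + 0.5 cycles (≈1.83 × 10⁵⁹ years for a 256-bit key at 10 GHz).
- **Research export** — one-row-per-task-instance dumps (TSV, XLSX,
  SQLite, XML) with live summary columns, per-task XML, free-text
  search, clinical text view with identity-conflict warnings, and
  numeric trackers.

A deterministic fixture generator (`edcap.fixtures`) produces complete
synthetic deployments — no external data is needed anywhere.

## Worked example

```python
from edcap import parse_policy, evaluate_policy, PatientRecord
from edcap.fixtures import FixtureConfig, generate, build_server
from edcap.export import DumpSpec, research_dump, tracker
from edcap.security import brute_force_mean_time

# A pseudonymised-research policy: sex and a study ID, nothing else.
policy = parse_policy("sex AND idnum1 AND NOT (forename OR surname OR dob)")
print("policy satisfied:", evaluate_policy(
    policy, PatientRecord(sex="F", idnums={1: 12345})))

# Synthetic study: 4 subjects, 2 tasks each, uploaded from 2 devices.
fixture = generate(FixtureConfig(seed=1, n_patients=4, tasks_per_patient=2))
server = build_server(fixture)
server.add_membership("uploader", 1, may_upload=True, may_dump=True,
                      may_view_all_patients_unfiltered=True)

frames = research_dump(server, DumpSpec(username="uploader", group_ids=(1,)))
print("phq9 dump rows:", len(frames["phq9"]))
print(frames["phq9"][["_client_pk", "q1", "q9", "summary_total",
                      "summary_severity_band"]].to_string(index=False))

key = server.conn.execute(
    "SELECT idnum_value FROM patient_idnum LIMIT 1").fetchone()[0]
print("tracker:", tracker(server, "uploader", key, "phq9", "total").points)

print(f"mean key-search time: {brute_force_mean_time(256, 10e9):.3g} years")
```

prints

```
policy satisfied: True
phq9 dump rows: 6
 _client_pk  q1  q9  summary_total summary_severity_band
          1   3   3             19     moderately severe
          2   2   3              8                  mild
          3   3   1             15     moderately severe
          1   3   0             16     moderately severe
          2   2   3             18     moderately severe
          3   1   1             17     moderately severe
tracker: (('2020-01-06T10:17:00.000+00:00', 19.0), ('2020-01-06T10:34:00.000+00:00', 8.0))
mean key-search time: 1.83e+59 years
```

The `summary_total` column exists only in the dump — the database stores
the ten raw answers and nothing else; the totals and severity bands were
computed as the dump was created. The tracker lists one
(timestamp, total) point per complete PHQ-9 for the chosen subject.

A command-line surface wraps the same library (`edcap --help`):
`init-db`, `create-user`, `create-group`, `grant`, `register-device`,
`upload`, `eval-policy`, `validate-nhs`, `export`, `search`, `tracker`,
`fixtures`, `erase`, `delete-patient`, `annotate`, `report`. Exit codes:
0 success, 1 user error, 2 permission denied, 3 integrity failure.

## Layout

```
src/edcap/
  identity.py   subject model, ID-number checksums, conflict detection
  policy.py     identification-policy language (parse/evaluate/serialize)
  tasks.py      task definitions, validation, live scoring, strings,
                use-context gating, schedules
  store.py      versioned record store, devices, uploads, eras, audit
  access.py     users, groups, memberships, authorization
  security.py   hashing, lockout, sessions, key-search calculator
  export.py     dumps, XML, clinical text view, search, trackers
  fixtures.py   deterministic synthetic-data generator
  cli.py        command-line surface
docs/methods.md   model, parameters, design choices, limitations
```
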