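# Methods

`edcap` re-implements the server core of a secure electronic data-capture
system for psychiatric and cognitive assessment: client devices capture raw
task answers offline and upload them to an institutional server, which
versions every record, enforces subject-identification policies and
group-based authorization, scores questionnaires on demand, and serves
clinical views and research exports. This note records the model, the
parameters that matter, the numerical and design choices made where the
design was genuinely open, and what the synthetic data does and does not
exercise.

## Identification policies

A subject record carries optional direct identifiers (forename, surname,
date of birth, sex/gender coded M/F/X, address, e-mail, GP, other) and any
number of administrator-defined ID number types. Two boolean policies over
attribute *presence* govern each group: the **upload** policy (minimum to
send data at all) and the stricter **finalizing** policy (required before
records are moved permanently to the server and erased from the device).
The two-stage design lets a clinician upload a patient identified only by
another hospital's number, and finalize later once the home institution's
number is known.

The policy grammar is `expr := term (OR term)*`, `term := factor (AND
factor)*`, `factor := NOT factor | "(" expr ")" | ATTR`, i.e. precedence
NOT > AND > OR with left associativity — the standard boolean convention;
all four canonical deployment policies evaluate identically under it.
Tokens are case-insensitive and canonically lower-case. AND/OR are
flattened to n-ary nodes at parse time, making the AST canonical so that
serialize→re-parse is structurally idempotent. "Present" means non-null
and, for text, non-empty after trimming. `idnumN` tokens referencing an
unconfigured type warn by default and can be made hard errors. The
pseudo-attribute `anyidnum` (true when any ID number is present) is an
extension point of this package, not part of the canonical policy set.

Whether a finalizing policy logically implies its upload policy is not
checked; deployments are expected to configure the stricter policy for
finalizing, but nothing enforces the implication.

## ID-number validation

ID number types may declare a validation method. The NHS number scheme is
implemented as the standard modulus-11 algorithm: weights 10…2 over digits
1–9, check = 11 − (weighted sum mod 11), 11 → 0, 10 → unissuable, compared
against digit 10; anything that is not exactly ten digits is invalid.
Uploads reject batches containing ID values that fail their type's check.

## Record versioning and eras

Every uploaded row is wrapped in an envelope: surrogate key, source device
and client key, `era`, `current` flag, addition/removal stamps with the
acting user, and predecessor/successor links. `era` is the literal `"NOW"`
while the source record is still live on its device, or the upload-commit
instant (ISO-8601 UTC) once the device's records have been finalized. A
re-uploaded, changed record closes the old row (current = false, removal
stamped, successor linked) and inserts a new current row linked back — a
complete modification history whose granularity is the upload frequency.
Content erasure nulls answer fields but keeps the envelope; only
whole-patient deletion (a records-management operation) physically removes
rows.

Change detection prefers the client-supplied last-modified timestamp and
falls back to field-by-field comparison, so a client that does not
maintain timestamps still synchronizes correctly.

The three upload modes: **move** finalizes every era-NOW row of the
device (refused wholesale if any patient fails the finalizing policy);
**move-keeping-patients** finalizes everything, then re-creates the
identity rows fresh in era NOW, predecessor-linked to their finalized
ancestors, mirroring the retained copies on the device; **copy** finalizes
only rows the client explicitly marked finished. Client keys finalized by
copy-mode "finished" marks may not be re-uploaded; this memory is cleared
by a full move, after which the device wipes itself and legitimately
reuses its key sequence.

Uploads are validated in full (registration, policy snapshot match,
upload/finalize policy satisfaction, table/field whitelist, value ranges,
checksums) before a single write; the write phase is one SQLite
transaction with an optional per-statement fault hook used by the tests to
verify that a crash at any boundary leaves the store bit-identical to its
prior state. The exchange is one-way: upload reports carry counts only,
never record content.

## Subject identity duplication and conflict detection

Identity records are deliberately duplicated per device-era (repetition is
a safety feature for clinical identification), and copies can disagree.
Records are linked across devices by a server-configured linking ID number
type; when combined views detect two or more distinct non-absent values
for a field, a warning is attached. Name comparison is case-insensitive
and whitespace-normalized; an absent field is compatible with anything.

## Tasks and live scoring

Only raw answers are stored (DRY); summaries are pure functions computed
at request time, so recomputing after deletion reproduces identical
outputs and research dumps can never drift from the raw data. Three
exemplar tasks ship: the PHQ-9 (nine scored items 0–3, total 0–27, plus a
functional-impact tenth item), BMI (height m, mass kg; BMI = mass/height²,
kg/m²), and an anonymous one-question survey exercising the
subject-free pathway and the restricted-strings mechanism.

PHQ-9 choices: q10 is mandatory for completeness but excluded from the
total (it sits outside the scored grid); when any scored item is missing
the total is withheld rather than computed over a subset. Severity bands
0–4 none/minimal, 5–9 mild, 10–14 moderate, 15–19 moderately severe,
20–27 severe come from the instrument's scoring guide. Timestamps keep
their original zone and are compared in UTC; default precision is 1 ms.

Task strings resolve institution-XML → shipped → copyright-free
placeholder ("Question N"), with a missing language falling back to the
configured default; the chain is total. Use-context gating takes the four
declared flags (clinical/research/educational/commercial, each
yes/no/unknown) and refuses a task prohibited in a context declared "yes";
"unknown" is treated conservatively as blocking. Refusal carries the
blocking context as a reason code rather than hiding the task (hiding is a
UI decision).

Schedules ("a weekly PHQ-9 for 6 weeks") define ⌈total/interval⌉
half-open slots `[anchor + k·interval, anchor + (k+1)·interval)`; a slot
is due when now is within or past it and no completion of that task falls
inside it.

## Access control

Groups own data and carry their own policies; memberships carry
per-(user, group) flags (upload, register devices, web login, unfiltered
multi-subject view, bulk dump, reports, notes, group admin). Group
visibility is an explicit directional list and deliberately one-step:
A seeing B and B seeing C does not give A sight of C. Group admins manage
users of their own group only; superusers bypass everything;
patient-locked users reach only records of the one subject they belong
to. All checks are deny-by-default pure functions, re-checked per record
on every read path (dump, XML, search, tracker, clinical view).

## Authentication

Passwords are stored only as salted PBKDF2-SHA256 hashes in a
self-describing `$pbkdf2-sha256$cost$salt$digest` format (default cost
50 000 iterations, configurable; old hashes remain verifiable after a cost
change). Login failures for nonexistent usernames run exactly one
verification against a fixed dummy hash and return the same failure shape
as a wrong password, so username discovery gains nothing; the mimicry is
asserted by call counting, which is robust where wall-clock comparison is
not. Accounts lock after 7 consecutive failures for 1 minute, doubling
per further failure and capped at 24 h — an explicit default schedule,
all configurable, chosen to satisfy "increasing periods" with bounded
denial-of-service surface. Sessions are IP-bound, expire after 30 min
inactivity (default), and get a fresh token at every login (session
fixation). A maximum password lifetime is disabled unless configured.

The brute-force calculator uses exact integer arithmetic for the mean
cycle count (0.5·2ⁿ + 0.5) and converts to years with a Julian year
(365.25 × 86 400 s); at 256 bits and 10 GHz this gives 1.83 × 10⁵⁹ years.

## Synthetic data

The fixture generator emulates the two canonical deployments. The
research scenario emits subjects carrying exactly a sex code and a
research ID, satisfying `sex AND idnum1` and the prohibition on direct
identifiers. The clinical scenario emits named subjects with DOB, a valid
NHS number (check digit computed, unissuable prefixes re-drawn), and a
configurable fraction carrying only the other hospital's number so they
upload but cannot finalize. PHQ-9 answers are uniform on 0–3 from a
single seeded stream; a configurable fraction of instances are left
incomplete; a configurable fraction of patients receive a duplicate
device record with a one-character surname slip to trigger conflict
warnings. Names combine small neutral word lists to avoid real-person
likeness. The same seed yields byte-identical payloads.

The generator does not attempt statistically realistic symptom
distributions, longitudinal plausibility, or adversarial payloads beyond
the malformed cases the tests construct directly — passing tests show the
mechanics (policies, versioning, scoring, authorization) are correct, not
that the system has been exercised against realistic clinical traffic.

## Problem sizes and numerical choices

The randomized versioning check runs 1 000 upload operations across 3
devices; live scoring is checked on 10 000 generated task instances; the
NHS checksum on 10⁵ random 10-digit values plus all generated-valid
numbers; access-control soundness on randomized stores of 8 groups with
random one-step visibility graphs and 6 random users. These sizes keep
the whole suite and the acceptance script in the tens of seconds while
the invariants they check are size-independent. BMI equality is checked
to 10⁻⁹ (pure float arithmetic both sides); all integer comparisons are
exact. Low PBKDF2 costs are used for synthetic users so hashing does not
dominate test time; the format is cost-agnostic.

## Known limitations

- ODS export is not available in this build; TSV, XLSX, XML and SQLite
  are. PDF/HTML rendering, HL7/FHIR/REDCap transports and multi-factor
  authentication are out of scope (the export hook and config stubs mark
  the seams).
- TLS and at-rest encryption are deployment concerns; the package
  implements password hashing and session discipline only.
- No fuzzy record linkage: subjects are linked by the configured ID
  number type exactly, and no external registry is consulted.
- The client is out of scope; the `UploadBatch` JSON/SQLite dialects
  stand in for the device side, and fixtures generate them.
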