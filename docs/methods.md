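# Methods

This note records the model implemented by `healthledger`, the
parameters that matter, the numerical and design choices made where the
design was genuinely open, and what the synthetic workloads do and do
not establish.

## Trust model and cryptography

All trust reduces to detached signatures over canonical bytes.
Canonical form is JSON with lexicographically sorted keys, no
insignificant whitespace, UTF-8 — chosen because the wire objects are
JSON documents and hashing/signing needs byte-stable serialization of
semantically equal values.

Signatures are ECDSA over NIST P-256 with SHA-256 digests. Nonces are
deterministic (RFC 6979), so signing is a pure function of (key,
message); combined with seed-derived keys (HMAC-SHA256 of a network
seed and the subject id) this makes an entire consortium — CAs, peers,
orderer, clients — bit-reproducible from one integer seed, which the
tests and the acceptance script rely on. The implementation is
in-package (Jacobian coordinates, a fixed-base window table for
signing, memoized verification keyed on key/digest/signature, since
replicated validation re-verifies identical triples on every peer).
Conformance is pinned to the published RFC 6979 P-256/SHA-256 test
vector. Side-channel hardening and real X.509/DER interop are
non-goals: certificates are canonical-JSON bodies carrying exactly the
fields the access logic consumes. "Deleting" a certificate is modeled
as adding its serial to the MSP revocation set, since an in-process
system has no certificate file to delete.

## Topology and roles

The default profile is two hospitals, two insurers and two governmental
agencies, one peer each (A–F), one orderer, and one CA per organization
kind. CAs for all three kinds are provisioned even in reduced test
profiles, because enrollment rights are keyed to the issuing CA's kind:
hospitals enroll doctors, nurses and lab technicians; insurers enroll
auditors; governmental agencies enroll patients, family members,
regulators, researchers and emergency staff. The orderer is enrolled
under the government CA — the governance text places the ordering node
with the governmental agencies, which is the least-speculative reading.
Emergency staff share the clinical permission row; no break-glass
override is modeled because none is specified.

## Access control

The decision procedure applies exactly three checks in order, and every
failure is a decision value, never an exception: membership (MSP +
request signature), role→API matrix (shipped as
`data/permissions.json` so a deployment can tighten it), and subject
authorization. The subject check is skipped when the requester *is* the
data subject, for anonymized queries (no subject is identifiable in the
output), and for auditors and regulators, who are oversight roles
entitled to read for payment/operations purposes; they are never exempt
from checks 1–2. Family members hold write/read APIs but still need the
patient's grant, honoring grants literally.

Delegation semantics: a grantee holds permission *p* on patient *P* iff
some grant edge to the grantee carries *p* and its grantor is a
*delegator* for *P* — where the delegator set is the least fixpoint of
"the patient, plus anyone granted `authorize` by a delegator". This
reads the "every intermediate grantor holds authorize" rule as a
property of grantors rather than of simple paths, which keeps the check
well-defined when grant records form cycles (the on-ledger records are
append-only and unordered, so cycles can be written even though the
intended shape is a tree). Grant revocation is not modeled; it is
nowhere specified, and grants are ordinary ledger records, hence
append-only.

## Ledger mechanics

`current_hash = SHA-256(canonical({number, previous_hash,
transactions}))`. The hash deliberately covers the transaction bytes —
covering only header fields would make transaction tampering invisible
to chain verification. The orderer's signature covers header,
transactions *and* the metadata timestamp; leaving the timestamp
outside the signature would make it the single silently mutable byte
range in the ledger. Genesis is block 0 with an all-zero previous hash
and an empty transaction list (the only block allowed to be empty).

Batch cutting: a block is cut when the pending count reaches
`batch_size`, or when `batch_timeout` has elapsed since the arrival of
the *first transaction of the current batch* (the timer starts at first
enqueue and restarts after each cut; it does not run on an empty
queue). Ties at equal arrival time break by transaction id. The timeout
comparison uses the same float expression that the deadline query
returns, so a driver advancing a simulated clock exactly to the
deadline always triggers the cut — an early version computed the two
sides differently and float rounding could leave the deadline
unreachable.

MVCC: at endorsement the chaincode records each consulted key with its
current version `(block, tx-index)` (or `None` for absent keys); at
commit, transactions are validated in block order against an
incrementally updated version map, so the second of two same-snapshot
writes to one key is flagged stale. Invalid transactions remain in the
block with a validity flag and are simply not applied — removing them
would break the append-only hash chain. The world state is therefore a
pure function of the block stream; replica consistency and
replay-reconstruction are property-tested, and the per-key history
index (maintained at commit time) serves history queries without a
chain scan.

Keys follow `patientID~type~seq` with a monotone 4-digit sequence per
(patient, type); updates reuse the key, which is what makes history
meaningful. Availability is a peer flag: a down peer refuses
endorsement and queries, misses deliveries, and catches up by replaying
the orderer's chain on recovery; failover is the caller's explicit
retry against another peer, not automatic load balancing.

## Anonymization

Researcher results replace identity-bearing fields (patient, clinician,
technician, grantor/grantee ids and the patient name, plus the record
key and author) with `SHA-256(value ‖ query-timestamp)` hex digests.
One timestamp is shared across a query — required to preserve
within-query linkage between a patient's records — and differs between
queries, so digests do not form a stable pseudonym over time. This is
pseudonymization by salted hashing only; k-anonymity or differential
privacy are out of scope, and free-text clinical fields are returned
verbatim.

## Benchmark harness

The four metrics are: read latency (steps 1–2, no ledger change), read
throughput in RPS (network figure = sum over peers, reads being
peer-local), transaction latency (request to the *last* peer's
commitment, all five lifecycle steps), and transaction throughput in
TPS. Concurrency is modeled as interleaved events on a shared simulated
clock; each stage is a single-server FIFO queue with constant service
times (defaults: read 0.1 s, response 0.005 s, endorse 0.1 s, block
assembly 0.05 s, per-block commit 0.2 s). The transactions themselves
are real — real signatures, the real orderer's cutting rules, real
commitment on every peer — only their timestamps come from the event
model. OS threads are deliberately not used; they would add
nondeterminism without changing the modeled quantities.

Absolute timings are properties of the configured service times, not
reproducible hardware measurements; the harness is built to expose
structure: read metrics are independent of the batching parameters (no
block is generated), a lone transaction's latency is
`endorse + order + commit` plus a timeout wait of 0 (batch size 1) or
the full `batch_timeout` (large batch size), and for a fixed workload
TPS falls as the number of blocks cut rises, because block assembly and
per-block commit are per-block costs. The `bench` CLI averages over a
`--repeats` flag (default 3).

## Synthetic data

`generate_population` emulates the *shape* of clinical traffic: each
patient files demographics and grants read/write/authorize to one
assigned doctor; the doctor writes the encounters; for roughly a third
of patients the doctor orders a lab test by granting a technician
read/write, and the technician files an analyte-list result. Free text
comes from small template pools, and the delegation structure is
consistent by construction. It does not emulate clinical realism —
longitudinal visit timing, coded terminologies, realistic lab
distributions, or adversarial clients — so passing tests demonstrate
protocol properties (ordering, validation, access control,
reproducibility), not fitness of the schemas for real clinical data.
The worked-scenario record bodies (Steve Apple / Carl Savem / John Doe,
lipid profile) are synthetic reconstructions.

## Problem sizes

The test suite and acceptance script run the worked scenario plus 200
random transactions for chain/tamper checks (500 single-byte
mutations), the full 135-case policy table, 200 random delegation
graphs (≤ 20 actors), 100 randomized MVCC workloads (≤ 20 keys, up to
100–200 transactions each), and 1000-transaction write workloads for
the throughput comparison — sizes chosen so the full suite completes in
a few minutes on one CPU while every law is exercised at meaningful
scale.

## Known limitations

Single orderer (a deliberate single point of failure, as in the
prototype being modeled); no network transport, TLS, or gossip — nodes
are in-process objects; no Byzantine orderer behavior beyond signature
and allow-list checks; no consent expiry or grant revocation; history
is index-backed but the ledger file is a flat JSON-lines scan on load;
certificates have no expiry and no CRL/OCSP semantics beyond the serial
revocation set.
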