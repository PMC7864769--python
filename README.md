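# healthledger

A self-contained, permissioned blockchain for electronic health records
(EHRs), built as a library plus CLI. It models a healthcare consortium —
hospitals, insurance providers and governmental agencies — that jointly
operates a replicated, hash-chained, append-only ledger of clinical
records under an agreed governance model: certificate-based identity,
role- and delegation-based fine-grained access control enforced by
chaincode, proof-of-authority (PoA) block ordering under batch-timeout /
batch-size rules, MVCC read/write-set validation on every committing
peer, pseudonymized reads for researchers, and a benchmark harness for
the four standard ledger metrics.

It is aimed at health-informatics researchers and engineers who want an
executable, fully inspectable model of a consortium EHR ledger — every
byte of every block can be re-verified from the chain alone — without
standing up a container orchestration stack.

## The model

**Identity.** Each organization kind runs a certificate authority; the
set of trusted CA roots, the orderer allow-list and the revocation set
form the membership service provider (MSP). Certificates are
canonical-JSON bodies signed with ECDSA P-256/SHA-256 (deterministic
RFC 6979 nonces, implemented in-package), carrying subject, role,
organization and public key.

**Access control** is a three-check decision evaluated by the chaincode
on every request, in order:

1. membership — the client certificate chains to a trusted CA, is not
   revoked, and the request signature verifies;
2. role — a permission matrix maps each of the nine user roles to its
   API set (clinical roles and patients write and grant; auditors and
   regulators read; researchers read anonymized only);
3. subject authorization — access to a patient's data requires a
   delegation chain of on-ledger authorization records rooted at that
   patient, where every intermediate grantor holds the `authorize`
   permission and the final grant carries the needed permission
   (`write` for submissions, `read` for queries, `authorize` for
   onward grants).

**The ledger.** Transactions carry the signed request, the endorsing
peer's signed response (returned value, read set, write set), and both
signatures. A single PoA orderer queues them first-come-first-serve and
cuts a block when either the pending count reaches `batch_size` or
`batch_timeout` seconds have passed since the first pending arrival —
whichever comes first. Block `n+1` stores the hash of block `n`;
`current_hash = SHA-256(number ‖ previous_hash ‖ transactions)`; there
is no nonce and no proof-of-work pattern — validity is the verified
identity of the block's signer. Committing peers re-check everything and
apply a write set only if its read-set versions are still current
(MVCC); stale transactions stay in the block, flagged invalid.

**Anonymization.** Researcher reads replace every identity field with
`SHA-256(value ‖ query-timestamp)`, one shared timestamp per query — so
patient–provider linkage survives within a query but not across queries.

## Worked example

```python
import healthledger as hl

net = hl.build_network(hl.NetworkConfig.default(seed=1))
transcript = net.run_worked_example()
print(transcript["committed_records"], transcript["chain_length"],
      transcript["chain_valid"])
# 5 6 True
```

The transcript walks the five-stage clinical scenario: patient Steve
Apple (P01) files demographics; lab technician John Doe is *refused*
(`not_authorized_by_subject`) before any grant exists; Steve authorizes
doctor Carl Savem (read, write, authorize); Carl writes an encounter
note and orders a lipid panel by granting John read/write; John files
the result; finally a researcher reads the chart anonymized. Five
records end up committed in five blocks after the genesis block, and
`verify_chain` confirms the hash chain and every PoA signature.

The same flow from the shell:

```bash
healthledger init --home ./net --batch-size 10
healthledger demo --home ./net
healthledger verify --home ./net
# {"valid": true, "blocks": 6, "violation": null}
healthledger query --home ./net --as ./net/identities/P01.json --patient P01
healthledger history --home ./net --as ./net/identities/D01.json \
    --key 'P01~encounter_note~0001'
healthledger bench --scenario write-concurrent --n 200 --batch-size 10
```

A single write with `--batch-size 1` commits on all six peers at 0.35 s
simulated (endorse 0.1 s + order 0.05 s + commit 0.2 s, no timeout
wait); the same write under `--batch-timeout 20 --batch-size 1000`
takes 20.35 s, because the lone transaction waits out the full batch
timeout before its block is cut.

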