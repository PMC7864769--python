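"""Endorsement-time ledger logic ("chaincode").

This is the program every endorsing peer runs in simulation: it exposes
the five chaincode APIs, enforces the consortium's fine-grained access
policy, produces the read set / write set that the committing peers will
later validate, and pseudonymizes results served to researchers.

Access control is a three-check decision, applied in order:

1. *Membership* — only consortium members may touch the ledger: the
   client certificate must chain to a trusted CA, be unrevoked, and the
   request signature must verify under it.
2. *Role* — each role is entitled to a fixed set of APIs (the permission
   matrix): clinical roles and patients may write and grant, auditors
   and regulators may only read, researchers may only read anonymized.
3. *Subject authorization* — a user may touch a patient's data only if
   a chain of authorization records rooted at that patient delegates the
   needed permission to them.  The patient themself, anonymized reads,
   and the oversight roles (auditor, regulator — entitled by law to read
   for payment/operations purposes) skip this check.

Delegation forms a tree rooted at the patient: every grantor on the path
must themselves hold the ``authorize`` permission for that patient, and
the final grant must include the permission the API needs.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Sequence, Set, Tuple

from . import crypto, records
from .identity import Certificate, Identity, MSPConfig, sign as id_sign, verify_certificate, verify_signature
from .records import RecordEnvelope

APIS = (
    "submit_record",
    "query_records",
    "query_history",
    "grant_authorization",
    "query_anonymized",
)

#: Permission (in the delegation sense) each API needs on the data subject.
NEEDED_PERMISSION = {
    "submit_record": "write",
    "query_records": "read",
    "query_history": "read",
    "grant_authorization": "authorize",
    "query_anonymized": None,
}

#: Oversight roles that may read any patient's data without a grant
#: (checks 1 and 2 still apply).
SUBJECT_CHECK_EXEMPT_ROLES = {"auditor", "regulator"}

#: Identity-bearing payload fields replaced by digests for researchers.
IDENTITY_FIELDS = (
    "patientID",
    "patientName",
    "doctorID",
    "technicianID",
    "orderingDoctorID",
    "grantorID",
    "granteeID",
)

CHAINCODE_NAME = "ehrcc"


def default_permission_matrix() -> Dict[str, Set[str]]:
    """Role → allowed APIs, loaded from the packaged policy file."""
    text = importlib.resources.files("healthledger").joinpath("data/permissions.json").read_text()
    return {role: set(apis) for role, apis in json.loads(text).items()}


_DEFAULT_MATRIX: Optional[Dict[str, Set[str]]] = None


def _matrix() -> Dict[str, Set[str]]:
    global _DEFAULT_MATRIX
    if _DEFAULT_MATRIX is None:
        _DEFAULT_MATRIX = default_permission_matrix()
    return _DEFAULT_MATRIX


# --- request / response / decision ---------------------------------------


@dataclass
class EHRRequest:
    api: str
    args: Dict[str, Any]
    client_cert: Certificate
    nonce: str
    sent_at: str  # RFC 3339
    client_signature: str = ""  # hex, over canonical body

    def body(self) -> dict:
        return {
            "api": self.api,
            "args": self.args,
            "client_cert": self.client_cert.to_dict(),
            "nonce": self.nonce,
            "sent_at": self.sent_at,
        }

    def body_bytes(self) -> bytes:
        return crypto.canonical_json(self.body())

    def digest(self) -> str:
        return crypto.sha256_hex(self.body_bytes())

    def to_dict(self) -> dict:
        d = self.body()
        d["client_signature"] = self.client_signature
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EHRRequest":
        return cls(
            api=d["api"],
            args=d["args"],
            client_cert=Certificate.from_dict(d["client_cert"]),
            nonce=d["nonce"],
            sent_at=d["sent_at"],
            client_signature=d["client_signature"],
        )


def make_request(
    identity: Identity,
    api: str,
    args: Dict[str, Any],
    nonce: str,
    sent_at: str,
) -> EHRRequest:
    """Build and sign a chaincode request on behalf of a client."""
    req = EHRRequest(
        api=api, args=args, client_cert=identity.certificate, nonce=nonce, sent_at=sent_at
    )
    req.client_signature = id_sign(identity, req.body_bytes()).hex()
    return req


@dataclass
class EHRResponse:
    """The endorsement: returned value plus read set and write set, signed."""

    request_digest: str
    returned_value: Any
    read_set: List[Tuple[str, Optional[Tuple[int, int]]]]
    write_set: List[Tuple[str, dict]]
    endorsing_peer_cert: Certificate
    peer_signature: str = ""
    error: Optional[dict] = None

    def body(self) -> dict:
        return {
            "request_digest": self.request_digest,
            "returned_value": self.returned_value,
            "read_set": [[k, list(v) if v is not None else None] for k, v in self.read_set],
            "write_set": [[k, v] for k, v in self.write_set],
            "endorsing_peer_cert": self.endorsing_peer_cert.to_dict(),
            "error": self.error,
        }

    def body_bytes(self) -> bytes:
        return crypto.canonical_json(self.body())

    def to_dict(self) -> dict:
        d = self.body()
        d["peer_signature"] = self.peer_signature
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EHRResponse":
        return cls(
            request_digest=d["request_digest"],
            returned_value=d["returned_value"],
            read_set=[(k, tuple(v) if v is not None else None) for k, v in d["read_set"]],
            write_set=[(k, v) for k, v in d["write_set"]],
            endorsing_peer_cert=Certificate.from_dict(d["endorsing_peer_cert"]),
            peer_signature=d["peer_signature"],
            error=d.get("error"),
        )


@dataclass
class AccessDecision:
    allowed: bool
    failed_check: Optional[str] = None  # not_consortium_member | api_not_permitted_for_role | not_authorized_by_subject
    detail: str = ""

    def to_dict(self) -> dict:
        return {"allowed": self.allowed, "failed_check": self.failed_check, "detail": self.detail}


ALLOW = AccessDecision(True)


# --- delegation ----------------------------------------------------------


def _grant_edges(world_state, patient: str) -> List[dict]:
    """All authorization payloads on the ledger scoped to this patient."""
    edges = []
    for key in world_state.keys_for(patient_id=patient, record_type="authorization"):
        value = world_state.get(key)
        if value is not None:
            edges.append(value["payload"])
    return edges


def is_authorized(world_state, grantee: str, patient: str, needed: str) -> bool:
    """Does a valid delegation chain give ``grantee`` ``needed`` on ``patient``?

    The patient is the root of the delegation tree and trivially holds
    every permission on their own data.  A grant edge counts only if its
    grantor can themselves delegate: either the patient, or someone who
    (transitively) received ``authorize``.  Computed as a fixpoint over
    the grant records in world state.
    """
    if grantee == patient:
        return True
    edges = _grant_edges(world_state, patient)
    can_delegate = {patient}
    perms: Dict[str, Set[str]] = {}
    changed = True
    while changed:
        changed = False
        for e in edges:
            if e["grantorID"] not in can_delegate:
                continue
            target = e["granteeID"]
            got = perms.setdefault(target, set())
            new = set(e["permissions"]) - got
            if new:
                got |= new
                changed = True
            if "authorize" in e["permissions"] and target not in can_delegate:
                can_delegate.add(target)
                changed = True
    return needed in perms.get(grantee, ())


def _data_subject(api: str, args: Dict[str, Any]) -> Optional[str]:
    """The patient whose data the request touches, if determinable."""
    if api == "submit_record":
        payload = args.get("payload", {})
        pid = payload.get("patientID")
        if not pid and args.get("key"):
            pid = records.patient_of_key(args["key"])
        return pid
    if api in ("query_records", "query_anonymized"):
        return args.get("patient")
    if api == "query_history":
        key = args.get("key")
        return records.patient_of_key(key) if key else None
    if api == "grant_authorization":
        return args.get("patient")
    return None


def check_access(
    request: EHRRequest,
    world_state,
    msp: MSPConfig,
    matrix: Optional[Dict[str, Set[str]]] = None,
) -> AccessDecision:
    """The three-check access decision (membership, role, subject grant)."""
    matrix = matrix if matrix is not None else _matrix()
    cert = request.client_cert
    # (1) only consortium members can access the ledger
    if not verify_certificate(cert, msp):
        return AccessDecision(False, "not_consortium_member", "certificate not trusted by MSP")
    try:
        sig = bytes.fromhex(request.client_signature)
    except ValueError:
        sig = b""
    if not verify_signature(cert, request.body_bytes(), sig):
        return AccessDecision(False, "not_consortium_member", "request signature invalid")
    # (2) different roles hold different chaincode APIs
    if request.api not in APIS:
        return AccessDecision(False, "api_not_permitted_for_role", f"unknown API {request.api!r}")
    if request.api not in matrix.get(cert.role, set()):
        return AccessDecision(
            False,
            "api_not_permitted_for_role",
            f"role {cert.role!r} may not call {request.api!r}",
        )
    # (3) no access to another's data without that subject's authorization
    needed = NEEDED_PERMISSION[request.api]
    if needed is None:
        return ALLOW
    subject = _data_subject(request.api, request.args)
    if subject is None:
        return AccessDecision(False, "not_authorized_by_subject", "data subject indeterminable")
    if cert.subject_id == subject:
        return ALLOW
    if cert.role in SUBJECT_CHECK_EXEMPT_ROLES:
        return ALLOW
    if is_authorized(world_state, cert.subject_id, subject, needed):
        return ALLOW
    return AccessDecision(
        False,
        "not_authorized_by_subject",
        f"{cert.subject_id} holds no {needed!r} grant from {subject}",
    )


# --- anonymization -------------------------------------------------------


def anonymize_result(record_list: Sequence[RecordEnvelope], query_time: str) -> List[RecordEnvelope]:
    """Pseudonymize identity fields for researcher reads.

    Each identity field value is replaced by the SHA-256 hex digest of
    the value concatenated with the query timestamp.  One timestamp is
    shared by the whole query, so equal identities map to equal digests
    within a query (patient–provider relationships stay visible) but to
    different digests across queries (no stable linkage over time).
    """
    out = []
    for rec in record_list:
        payload = dict(rec.payload)
        for f in IDENTITY_FIELDS:
            if f in payload and isinstance(payload[f], str) and payload[f]:
                payload[f] = crypto.sha256_hex((payload[f] + query_time).encode("utf-8"))
        anon = RecordEnvelope(
            record_type=rec.record_type,
            key=crypto.sha256_hex((rec.key + query_time).encode("utf-8")),
            payload=payload,
            created_by=crypto.sha256_hex((rec.created_by + query_time).encode("utf-8")),
            created_at=rec.created_at,
        )
        out.append(anon)
    return out


# --- execution -----------------------------------------------------------


def execute(
    request: EHRRequest,
    world_state,
    peer_identity: Identity,
    msp: MSPConfig,
    matrix: Optional[Dict[str, Set[str]]] = None,
) -> EHRResponse:
    """Run a request against a peer's world state, producing the endorsement.

    Access is (re-)checked here — the certificate is extracted from the
    request itself, never taken on faith from the transport layer.
    Writes do not touch the state: they only enter the write set, to be
    applied if and when the transaction survives ordering and validation.
    """
    decision = check_access(request, world_state, msp, matrix)
    reads: List[Tuple[str, Optional[Tuple[int, int]]]] = []
    writes: List[Tuple[str, dict]] = []
    value: Any = None
    error: Optional[dict] = None

    if not decision.allowed:
        error = decision.to_dict()
    else:
        try:
            value, reads, writes = _dispatch(request, world_state)
        except ValueError as exc:
            error = {"allowed": False, "failed_check": None, "detail": str(exc)}

    resp = EHRResponse(
        request_digest=request.digest(),
        returned_value=value,
        read_set=reads,
        write_set=writes,
        endorsing_peer_cert=peer_identity.certificate,
        error=error,
    )
    resp.peer_signature = id_sign(peer_identity, resp.body_bytes()).hex()
    return resp


def _dispatch(request: EHRRequest, state):
    api, args = request.api, request.args
    subject = request.client_cert.subject_id
    if api == "submit_record":
        return _submit_record(args, state, subject, request.sent_at)
    if api == "grant_authorization":
        return _grant_authorization(args, state, subject, request.sent_at)
    if api == "query_records":
        return _query_records(args, state)
    if api == "query_history":
        return _query_history(args, state)
    if api == "query_anonymized":
        value, reads, _ = _query_records(args, state)
        env_list = [RecordEnvelope.from_dict(v) for v in value]
        anon = anonymize_result(env_list, request.sent_at)
        return [e.to_dict() for e in anon], reads, []
    raise ValueError(f"unknown API {api!r}")


def _submit_record(args, state, subject: str, sent_at: str):
    rtype = args.get("record_type")
    payload = args.get("payload")
    if rtype not in records.RECORD_TYPES:
        raise ValueError(f"unknown record_type {rtype!r}")
    if not isinstance(payload, dict):
        raise ValueError("payload must be an object")
    key = args.get("key")
    if key:
        if state.get(key) is None:
            raise ValueError(f"update targets unknown key {key!r}")
    else:
        key = records.next_key(state.keys(), payload.get("patientID", ""), rtype)
    env = records.envelope(rtype, payload, key, created_by=subject, created_at=sent_at)
    reads = [(key, state.version(key))]
    writes = [(key, env.to_dict())]
    return key, reads, writes


def _grant_authorization(args, state, subject: str, sent_at: str):
    payload = {
        "grantorID": subject,
        "granteeID": args.get("grantee", ""),
        "patientID": args.get("patient", ""),
        "permissions": sorted(args.get("permissions", [])),
        "granted_at": sent_at,
    }
    key = records.next_key(state.keys(), payload["patientID"], "authorization")
    env = records.envelope("authorization", payload, key, created_by=subject, created_at=sent_at)
    reads = [(key, state.version(key))]
    writes = [(key, env.to_dict())]
    return key, reads, writes


def _query_records(args, state):
    patient = args.get("patient")
    if not patient:
        raise ValueError("query requires a patient id")
    rtype = args.get("record_type")
    if rtype is not None and rtype not in records.RECORD_TYPES:
        raise ValueError(f"unknown record_type {rtype!r}")
    reads = []
    values = []
    for key in state.keys_for(patient_id=patient, record_type=rtype):
        reads.append((key, state.version(key)))
        values.append(state.get(key))
    return values, reads, []


def _query_history(args, state):
    key = args.get("key")
    if not key:
        raise ValueError("query_history requires a key")
    entries = state.history_of(key)
    value = [
        {"value": v, "version": list(ver), "tx_id": txid} for v, ver, txid in entries
    ]
    return value, [(key, state.version(key))], []
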