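"""EHR document types, validation, canonical serialization and keying.

Four record types circulate on the ledger:

* ``demographics`` — patient-reported personal information (the PHR side),
* ``encounter_note`` — a clinician's visit note (chief complaint, physical
  examination, assessment, plan),
* ``test_result`` — a laboratory report as a list of analytes,
* ``authorization`` — a grant of permissions (read / write / authorize)
  from one subject to another, scoped to one patient's data.

Every record travels in a :class:`RecordEnvelope` carrying its ledger
key, author and timestamp.  Envelopes are hashed and signed, so their
serialization must be canonical: JSON with lexicographically sorted
keys, no insignificant whitespace, UTF-8.

Ledger keys follow ``<patientID>~<record_type>~<seq>`` with a 4-digit
monotone sequence per (patient, type).  An update to an existing
clinical record reuses its key, which is what makes per-key history
queries meaningful.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from typing import Any, Dict, Iterable, List, Optional

from . import crypto

RECORD_TYPES = ("demographics", "encounter_note", "test_result", "authorization")

PERMISSIONS = ("read", "write", "authorize")

KEY_SEP = "~"

#: Required fields per payload type; values must be non-empty strings
#: where marked.  Schemas are additive-extensible: unknown extra fields
#: are preserved, never rejected.
_REQUIRED: Dict[str, List[str]] = {
    "demographics": ["patientID", "patientName"],
    "encounter_note": [
        "patientID",
        "patientName",
        "doctorID",
        "chiefComplaint",
        "physicalExamination",
        "assessment",
        "plan",
    ],
    "test_result": ["patientID", "technicianID", "orderingDoctorID", "testName", "resultItems"],
    "authorization": ["grantorID", "granteeID", "patientID", "permissions", "granted_at"],
}

_NON_EMPTY: Dict[str, List[str]] = {
    "demographics": ["patientID"],
    "encounter_note": ["patientID", "doctorID"],
    "test_result": ["patientID", "technicianID"],
    "authorization": ["grantorID", "granteeID", "patientID"],
}


@dataclass
class Demographics:
    patientID: str
    patientName: str
    birthDate: str = ""
    sex: str = ""
    contact: str = ""
    allergies: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EncounterNote:
    patientID: str
    patientName: str
    doctorID: str
    chiefComplaint: str
    physicalExamination: str
    assessment: str
    plan: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TestResult:
    patientID: str
    technicianID: str
    orderingDoctorID: str
    testName: str
    #: each item: {"analyte", "value", "unit", "referenceRange"}
    resultItems: List[Dict[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AuthorizationRecord:
    grantorID: str
    granteeID: str
    patientID: str
    permissions: List[str]
    granted_at: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RecordEnvelope:
    """A typed EHR document plus the metadata the ledger needs."""

    record_type: str
    key: str
    payload: Dict[str, Any]
    created_by: str
    created_at: str  # RFC 3339 UTC

    def to_dict(self) -> dict:
        return {
            "record_type": self.record_type,
            "key": self.key,
            "payload": copy.deepcopy(self.payload),
            "created_by": self.created_by,
            "created_at": self.created_at,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RecordEnvelope":
        return cls(
            record_type=d["record_type"],
            key=d["key"],
            payload=copy.deepcopy(d["payload"]),
            created_by=d["created_by"],
            created_at=d["created_at"],
        )


def canonical_serialize(record: RecordEnvelope) -> bytes:
    """Canonical bytes of an envelope (stable across construction order)."""
    violations = validate_record(record)
    if violations:
        raise ValueError("cannot serialize invalid record: " + "; ".join(violations))
    return crypto.canonical_json(record.to_dict())


def parse_record(data: bytes) -> RecordEnvelope:
    return RecordEnvelope.from_dict(json.loads(data.decode("utf-8")))


def validate_record(record: RecordEnvelope) -> List[str]:
    """Schema check; returns human-readable violations (empty = valid)."""
    out: List[str] = []
    rt = record.record_type
    if rt not in RECORD_TYPES:
        return [f"unknown record_type {rt!r}"]
    payload = record.payload
    if not isinstance(payload, dict):
        return [f"{rt}: payload must be an object"]
    for f in _REQUIRED[rt]:
        if f not in payload:
            out.append(f"{rt}: missing field {f!r}")
    for f in _NON_EMPTY[rt]:
        if f in payload and not payload[f]:
            out.append(f"{rt}: field {f!r} must be non-empty")
    if rt == "authorization":
        perms = payload.get("permissions")
        if perms is not None:
            if not perms:
                out.append("authorization: permissions must be non-empty")
            else:
                bad = [p for p in perms if p not in PERMISSIONS]
                if bad:
                    out.append(f"authorization: unknown permissions {bad}")
        if (
            payload.get("grantorID")
            and payload.get("granteeID")
            and payload["grantorID"] == payload["granteeID"]
        ):
            out.append("authorization: grantor and grantee must differ")
    if rt == "test_result":
        items = payload.get("resultItems")
        if items is not None and not isinstance(items, list):
            out.append("test_result: resultItems must be a list")
    if record.key:
        parts = record.key.split(KEY_SEP)
        if len(parts) != 3 or parts[1] != rt:
            out.append(f"key {record.key!r} does not follow patient~type~seq")
        elif payload.get("patientID") and parts[0] != payload["patientID"]:
            out.append("key patient segment does not match payload patientID")
    return out


def make_key(patient_id: str, record_type: str, seq: int) -> str:
    return f"{patient_id}{KEY_SEP}{record_type}{KEY_SEP}{seq:04d}"


def parse_key(key: str) -> tuple:
    """(patientID, record_type, seq) of a ledger key."""
    pid, rt, seq = key.split(KEY_SEP)
    return pid, rt, int(seq)


def next_key(existing_keys: Iterable[str], patient_id: str, record_type: str) -> str:
    """The next free key for (patient, type) given the keys already in state.

    Sequence numbers are monotone per (patient, type) starting at 1;
    updates reuse an existing key rather than taking a new one.
    """
    top = 0
    prefix = f"{patient_id}{KEY_SEP}{record_type}{KEY_SEP}"
    for k in existing_keys:
        if k.startswith(prefix):
            try:
                top = max(top, int(k[len(prefix):]))
            except ValueError:
                continue
    return make_key(patient_id, record_type, top + 1)


def patient_of_key(key: str) -> str:
    return key.split(KEY_SEP, 1)[0]


def envelope(
    record_type: str,
    payload: Dict[str, Any],
    key: str,
    created_by: str,
    created_at: str,
) -> RecordEnvelope:
    """Build and validate an envelope; raises on schema violations."""
    env = RecordEnvelope(
        record_type=record_type,
        key=key,
        payload=copy.deepcopy(payload),
        created_by=created_by,
        created_at=created_at,
    )
    violations = validate_record(env)
    if violations:
        raise ValueError("; ".join(violations))
    return env
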