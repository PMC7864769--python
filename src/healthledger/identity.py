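"""Certificate authorities, enrollment and the membership service provider.

The consortium has three kinds of organizations — hospitals, insurance
providers and governmental agencies — and each kind runs a certificate
authority.  A CA issues simplified certificates (a canonical-JSON body
carrying subject, role, organization and public key, signed by the CA)
to every actor: clinical staff, patients and their families, auditors,
regulators, researchers, and the infrastructure nodes (peers, the
orderer).  The set of trusted CA roots plus the orderer allow-list and
the revocation set form the membership service provider (MSP): an
identity is a consortium member iff its certificate chains to a trusted
CA and has not been revoked.

Certificates here are deliberately not ASN.1/DER X.509 — real PKI
interoperability is a non-goal; the structure mirrors the fields the
access-control logic actually consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, Optional, Set

from . import crypto
from .errors import EnrollmentError

ROLES = (
    "doctor",
    "nurse",
    "lab_technician",
    "emergency_staff",
    "patient",
    "family_member",
    "auditor",
    "regulator",
    "researcher",
    "peer",
    "orderer",
    "ca",
)

#: The nine end-user roles that hold client certificates (not nodes).
CLIENT_ROLES = ROLES[:9]

ORG_TYPES = ("hospital", "insurer", "government")

#: Which org type's CA may enroll which roles.  Hospitals enroll their
#: clinical staff; insurers enroll auditors; governmental agencies enroll
#: the public-facing roles and, because they also contribute the ordering
#: node, the orderer.  Every org type enrolls its own peers.
ROLES_BY_ORG_TYPE: Dict[str, Set[str]] = {
    "hospital": {"doctor", "nurse", "lab_technician", "peer"},
    "insurer": {"auditor", "peer"},
    "government": {
        "patient",
        "family_member",
        "regulator",
        "researcher",
        "emergency_staff",
        "peer",
        "orderer",
    },
}


@dataclass(frozen=True)
class Certificate:
    """A simplified identity certificate (canonical-JSON body + CA signature)."""

    serial: str
    subject_id: str
    common_name: str
    role: str
    org: str
    org_type: str
    public_key: str  # hex, uncompressed SEC1
    issuer_org: str
    issuer_signature: str  # hex, over canonical body

    def body(self) -> dict:
        d = asdict(self)
        d.pop("issuer_signature")
        return d

    def body_bytes(self) -> bytes:
        return crypto.canonical_json(self.body())

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Certificate":
        return cls(**d)


@dataclass
class Identity:
    """A certificate together with its private signing key (held by the owner)."""

    certificate: Certificate
    private_key: int = field(repr=False)

    @property
    def subject_id(self) -> str:
        return self.certificate.subject_id

    def to_dict(self) -> dict:
        return {
            "certificate": self.certificate.to_dict(),
            "private_key": format(self.private_key, "064x"),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Identity":
        return cls(
            certificate=Certificate.from_dict(d["certificate"]),
            private_key=int(d["private_key"], 16),
        )


@dataclass
class MSPConfig:
    """Membership service provider: trusted roots, orderer allow-list, revocations."""

    trusted_ca_certs: Dict[str, Certificate] = field(default_factory=dict)
    orderer_subjects: Set[str] = field(default_factory=set)
    revoked_serials: Set[str] = field(default_factory=set)

    def add_ca(self, cert: Certificate) -> None:
        if cert.role != "ca":
            raise EnrollmentError("only CA certificates may be trusted roots")
        self.trusted_ca_certs[cert.org] = cert

    def revoke(self, serial: str) -> None:
        """Withdraw trust in a certificate (models deleting it)."""
        self.revoked_serials.add(serial)

    def to_dict(self) -> dict:
        return {
            "trusted_ca_certs": {o: c.to_dict() for o, c in self.trusted_ca_certs.items()},
            "orderer_subjects": sorted(self.orderer_subjects),
            "revoked_serials": sorted(self.revoked_serials),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MSPConfig":
        return cls(
            trusted_ca_certs={
                o: Certificate.from_dict(c) for o, c in d["trusted_ca_certs"].items()
            },
            orderer_subjects=set(d["orderer_subjects"]),
            revoked_serials=set(d["revoked_serials"]),
        )


def _serial_for(org: str, subject_id: str, role: str) -> str:
    digest = crypto.sha256_hex(f"{org}|{subject_id}|{role}".encode())
    return f"{org}:{digest[:16]}"


def create_ca(org: str, org_type: str, seed: bytes, *, existing: Optional[Iterable[str]] = None) -> Identity:
    """Create a self-signed certificate authority for one organization.

    ``seed`` is the deterministic key-derivation seed; rebuilding a
    network from the same seed reproduces the same CA key material.
    """
    if not org:
        raise EnrollmentError("CA organization name must be non-empty")
    if org_type not in ORG_TYPES:
        raise EnrollmentError(f"unknown org type {org_type!r}")
    if existing is not None and org in set(existing):
        raise EnrollmentError(f"duplicate CA organization {org!r}")
    d, pub = crypto.derive_keypair(seed + b"|ca|" + org.encode())
    unsigned = Certificate(
        serial=_serial_for(org, org, "ca"),
        subject_id=f"ca:{org}",
        common_name=f"{org} CA",
        role="ca",
        org=org,
        org_type=org_type,
        public_key=pub.hex(),
        issuer_org=org,
        issuer_signature="",
    )
    sig = crypto.sign(d, unsigned.body_bytes())
    cert = Certificate(**{**unsigned.to_dict(), "issuer_signature": sig.hex()})
    return Identity(certificate=cert, private_key=d)


def enroll(
    ca: Identity,
    subject_id: str,
    common_name: str,
    role: str,
    *,
    key_seed: Optional[bytes] = None,
) -> Identity:
    """Enroll an actor under a CA, returning their identity bundle.

    The CA checks that the requested role is one its kind of organization
    is entitled to enroll (a hospital CA cannot mint auditors, an insurer
    CA cannot mint doctors, and so on).
    """
    cacert = ca.certificate
    if cacert.role != "ca":
        raise EnrollmentError("enrolling identity is not a CA")
    if role not in ROLES:
        raise EnrollmentError(f"unknown role {role!r}")
    if not subject_id:
        raise EnrollmentError("subject_id must be non-empty")
    if role not in ROLES_BY_ORG_TYPE[cacert.org_type]:
        raise EnrollmentError(
            f"a {cacert.org_type} CA may not enroll role {role!r}"
        )
    if key_seed is None:
        key_seed = (cacert.org + "|" + subject_id + "|" + role).encode()
    d, pub = crypto.derive_keypair(b"enroll|" + key_seed)
    unsigned = Certificate(
        serial=_serial_for(cacert.org, subject_id, role),
        subject_id=subject_id,
        common_name=common_name,
        role=role,
        org=cacert.org,
        org_type=cacert.org_type,
        public_key=pub.hex(),
        issuer_org=cacert.org,
        issuer_signature="",
    )
    sig = crypto.sign(ca.private_key, unsigned.body_bytes())
    cert = Certificate(**{**unsigned.to_dict(), "issuer_signature": sig.hex()})
    return Identity(certificate=cert, private_key=d)


def sign(identity: Identity, message: bytes) -> bytes:
    """Detached signature by the identity's private key."""
    return crypto.sign(identity.private_key, message)


def verify_signature(cert: Certificate, message: bytes, signature: bytes) -> bool:
    """True iff ``signature`` over ``message`` verifies under the cert's key."""
    try:
        pub = bytes.fromhex(cert.public_key)
    except ValueError:
        return False
    return crypto.verify(pub, message, signature)


def verify_certificate(cert, msp: MSPConfig) -> bool:
    """Is this certificate a live credential of a consortium member?

    True iff the issuer is a trusted CA, the issuer signature over the
    canonical body verifies, and the serial has not been revoked.
    Malformed input returns False rather than raising: the caller is
    deciding whether to trust a wire object.
    """
    if not isinstance(cert, Certificate):
        return False
    issuer = msp.trusted_ca_certs.get(cert.issuer_org)
    if issuer is None:
        return False
    if cert.serial in msp.revoked_serials:
        return False
    try:
        pub = bytes.fromhex(issuer.public_key)
        sig = bytes.fromhex(cert.issuer_signature)
        body = cert.body_bytes()
    except (ValueError, TypeError):
        return False
    return crypto.verify(pub, body, sig)
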