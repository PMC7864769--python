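"""Consortium topology and the five-step EHR transaction lifecycle.

The default profile mirrors the reference deployment: two hospitals, two
insurance providers and two governmental agencies, each contributing one
peer (named A–F), plus one orderer and one certificate authority per
organization kind — all in-process objects communicating by direct call
(network transport and TLS are deployment concerns, out of scope here).

A write travels the full lifecycle:

1. the client signs an EHR request and sends it to an endorsing peer;
2. the peer runs the chaincode and returns a signed response with read
   set and write set;
3. the client verifies the peer's signature and assembles request +
   response into an EHR transaction;
4. the orderer queues transactions FCFS and cuts blocks under the batch
   timeout / batch size rules;
5. every available peer validates and commits the block.

Reads stop after step 2 and never touch the chain.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Tuple

from . import chaincode, fixtures
from .chaincode import make_request
from .clock import SimulatedClock, WallClock, rfc3339
from .errors import ConfigError, EndorsementError, PeerUnavailableError
from .identity import (
    CLIENT_ROLES,
    Identity,
    MSPConfig,
    ROLES_BY_ORG_TYPE,
    create_ca,
    enroll,
    verify_certificate,
    verify_signature,
)
from .ordering import Block, Orderer, OrdererConfig, assemble_transaction
from .peer import Peer

PEER_NAMES = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

#: Small time step charged to each client interaction on the simulated
#: clock, so that successive requests carry distinct timestamps.
TICK = 0.001


@dataclass
class OrgSpec:
    name: str
    org_type: str
    n_peers: int = 1


@dataclass
class NetworkConfig:
    orgs: List[OrgSpec]
    batching: OrdererConfig = field(default_factory=OrdererConfig)
    clock_mode: str = "simulated"  # or "wall"
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0, batching: Optional[OrdererConfig] = None) -> "NetworkConfig":
        return cls(
            orgs=[
                OrgSpec("hospital1", "hospital"),
                OrgSpec("hospital2", "hospital"),
                OrgSpec("insurer1", "insurer"),
                OrgSpec("insurer2", "insurer"),
                OrgSpec("gov1", "government"),
                OrgSpec("gov2", "government"),
            ],
            batching=batching or OrdererConfig(),
            seed=seed,
        )

    def validate(self) -> None:
        if not self.orgs:
            raise ConfigError("at least one organization is required")
        names = [o.name for o in self.orgs]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate organization names")
        for o in self.orgs:
            if o.n_peers < 1:
                raise ConfigError(f"org {o.name!r} must contribute at least one peer")
            if o.org_type not in ROLES_BY_ORG_TYPE:
                raise ConfigError(f"unknown org type {o.org_type!r}")
        if "government" not in {o.org_type for o in self.orgs}:
            raise ConfigError("a governmental org is required (it hosts the orderer)")
        self.batching.validate()

    def to_dict(self) -> dict:
        return {
            "orgs": [{"name": o.name, "org_type": o.org_type, "n_peers": o.n_peers} for o in self.orgs],
            "batching": {
                "batch_timeout": self.batching.batch_timeout,
                "batch_size": self.batching.batch_size,
            },
            "clock_mode": self.clock_mode,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(
            orgs=[OrgSpec(**o) for o in d["orgs"]],
            batching=OrdererConfig(**d.get("batching", {})),
            clock_mode=d.get("clock_mode", "simulated"),
            seed=d.get("seed", 0),
        )


@dataclass
class Client:
    identity: Identity
    target_peer: str

    @property
    def subject_id(self) -> str:
        return self.identity.subject_id


@dataclass
class SubmitOutcome:
    status: str  # committed | denied
    tx_id: Optional[str] = None
    returned_value: Any = None
    decision: Optional[dict] = None
    block_number: Optional[int] = None
    tx_valid: Optional[bool] = None
    peer_status: Dict[str, str] = field(default_factory=dict)
    commit_time: Optional[float] = None


@dataclass
class QueryOutcome:
    status: str  # ok | denied
    records: List[Any] = field(default_factory=list)
    decision: Optional[dict] = None


class Network:
    """The running consortium: CAs, peers, orderer, shared MSP, one clock."""

    def __init__(self, config: NetworkConfig):
        config.validate()
        self.config = config
        self.clock = SimulatedClock() if config.clock_mode == "simulated" else WallClock()
        self.rng = random.Random(config.seed)
        self._key_root = b"net-seed:%d" % config.seed

        # one CA per organization kind, whether or not that kind
        # contributes peers in this profile
        self.msp = MSPConfig()
        self.cas: Dict[str, Identity] = {}  # org_type -> CA identity
        for org_type in ("hospital", "insurer", "government"):
            ca = create_ca(f"{org_type}-ca", org_type, self._key_root, existing=self.cas)
            self.cas[org_type] = ca
            self.msp.add_ca(ca.certificate)

        self.peers: Dict[str, Peer] = {}
        names = iter(PEER_NAMES)
        for org in config.orgs:
            for _ in range(org.n_peers):
                name = next(names)
                ident = enroll(
                    self.cas[org.org_type],
                    f"peer-{name}",
                    f"Peer {name} ({org.name})",
                    "peer",
                    key_seed=self._key_root + b"|peer|" + name.encode(),
                )
                self.peers[name] = Peer(ident, org.name, self.msp)

        gov_ca = self.cas["government"]
        self.orderer_identity = enroll(
            gov_ca,
            "orderer-1",
            "Consortium Orderer",
            "orderer",
            key_seed=self._key_root + b"|orderer",
        )
        self.msp.orderer_subjects.add("orderer-1")
        self.orderer = Orderer(
            self.orderer_identity, config.batching, self.msp, genesis_time=self.clock.now()
        )
        for peer in self.peers.values():
            peer.commit_block(self.orderer.chain[0])
        self.clients: Dict[str, Client] = {}

    # --- enrollment ------------------------------------------------------

    def enroll_user(self, role: str, subject_id: str, common_name: str, target_peer: Optional[str] = None) -> Client:
        """Enroll a client under the CA entitled to issue its role."""
        if role not in CLIENT_ROLES:
            raise ConfigError(f"{role!r} is not a client role")
        if subject_id in self.clients:
            return self.clients[subject_id]
        org_type = next(t for t, roles in ROLES_BY_ORG_TYPE.items() if role in roles)
        ident = enroll(
            self.cas[org_type],
            subject_id,
            common_name,
            role,
            key_seed=self._key_root + b"|client|" + subject_id.encode(),
        )
        client = Client(ident, target_peer or next(iter(self.peers)))
        self.clients[subject_id] = client
        return client

    # --- clock and plumbing ----------------------------------------------

    def _tick(self) -> float:
        self.clock.advance(TICK)
        return self.clock.now()

    def _nonce(self) -> str:
        return format(self.rng.getrandbits(96), "024x")

    def build_request(self, client: Client, api: str, args: Dict[str, Any]) -> chaincode.EHRRequest:
        now = self._tick()
        return make_request(client.identity, api, args, nonce=self._nonce(), sent_at=rfc3339(now))

    def deliver(self, block: Block) -> Tuple[Dict[str, str], Dict[str, Any]]:
        """Lifecycle step 5: hand a block to every available peer."""
        status: Dict[str, str] = {}
        reports: Dict[str, Any] = {}
        for name, peer in self.peers.items():
            if peer.available:
                report = peer.commit_block(block)
                reports[name] = report
                status[name] = "committed"
            else:
                status[name] = "unavailable"
        return status, reports

    def set_peer_available(self, name: str, available: bool) -> None:
        """Toggle a peer; on recovery it catches up by replaying the chain."""
        peer = self.peers[name]
        peer.set_available(available)
        if available:
            for block in self.orderer.chain[len(peer.chain):]:
                peer.commit_block(block)

    # --- client operations ------------------------------------------------

    def client_submit(
        self,
        client: Client,
        api: str,
        args: Dict[str, Any],
        target: Optional[str] = None,
    ) -> SubmitOutcome:
        """Drive one write through all five lifecycle steps.

        Returns a denial outcome if endorsement fails the access checks;
        raises :class:`PeerUnavailableError` if the target peer is down
        (the caller may retry against another peer, which is the
        documented failover behaviour).
        """
        if api not in ("submit_record", "grant_authorization"):
            raise ValueError(f"{api!r} is not a write API")
        request = self.build_request(client, api, args)
        peer = self.peers[target or client.target_peer]
        response = peer.endorse(request)  # raises if unavailable
        if response.error is not None:
            return SubmitOutcome(status="denied", decision=response.error, tx_id=request.digest())
        self._client_check_endorsement(response)
        tx = assemble_transaction(request, response)
        self.orderer.submit(tx, self.clock.now())
        blocks = self.orderer.cut_all(self.clock.now())
        if not any(tx.tx_id == t.tx_id for b in blocks for t in b.transactions):
            deadline = self.orderer.batch_deadline()
            assert deadline is not None
            self.clock.advance_to(max(deadline, self.clock.now()))
            blocks += self.orderer.cut_all(self.clock.now())
        outcome = SubmitOutcome(status="committed", tx_id=tx.tx_id, returned_value=response.returned_value)
        for block in blocks:
            status, reports = self.deliver(block)
            for idx, t in enumerate(block.transactions):
                if t.tx_id == tx.tx_id:
                    outcome.block_number = block.header.number
                    outcome.peer_status = status
                    outcome.commit_time = self.clock.now()
                    if reports:
                        outcome.tx_valid = next(iter(reports.values())).tx_valid[idx]
        return outcome

    def _client_check_endorsement(self, response: chaincode.EHRResponse) -> None:
        """Lifecycle step 3: the client trusts no unsigned endorsement."""
        cert = response.endorsing_peer_cert
        if not verify_certificate(cert, self.msp):
            raise EndorsementError("endorsing peer certificate not trusted")
        try:
            sig = bytes.fromhex(response.peer_signature)
        except ValueError:
            raise EndorsementError("malformed peer signature")
        if not verify_signature(cert, response.body_bytes(), sig):
            raise EndorsementError("peer signature invalid")

    def client_query(
        self,
        client: Client,
        api: str,
        args: Dict[str, Any],
        target: Optional[str] = None,
    ) -> QueryOutcome:
        """A read: endorsement only, nothing ordered, ledger untouched."""
        if api not in ("query_records", "query_history", "query_anonymized"):
            raise ValueError(f"{api!r} is not a read API")
        request = self.build_request(client, api, args)
        peer = self.peers[target or client.target_peer]
        response = peer.endorse(request)
        if response.error is not None:
            return QueryOutcome(status="denied", decision=response.error)
        self._client_check_endorsement(response)
        return QueryOutcome(status="ok", records=response.returned_value)

    # --- reference scenario ----------------------------------------------

    def run_worked_example(self) -> dict:
        """The five-stage clinical scenario, end to end.

        Patient Steve Apple (P01) registers demographics, authorizes
        doctor Carl Savem, who writes an encounter note and orders a
        lipid panel from technician John Doe, who files the result; a
        researcher then reads the chart anonymized.  The transcript also
        records that John is refused before Carl's order grant exists.
        """
        fx = fixtures.demo_payloads()
        steve = self.enroll_user("patient", fx.patient_id, "Steve Apple")
        carl = self.enroll_user("doctor", fx.doctor_id, "Carl Savem")
        john = self.enroll_user("lab_technician", fx.technician_id, "John Doe")
        researcher = self.enroll_user("researcher", "R01", "Rita Cohort")

        steps: List[dict] = []

        def log(stage: str, outcome) -> None:
            entry = {"stage": stage, "status": outcome.status}
            if isinstance(outcome, SubmitOutcome):
                entry["key"] = outcome.returned_value
                entry["block"] = outcome.block_number
                if outcome.decision:
                    entry["failed_check"] = outcome.decision.get("failed_check")
            steps.append(entry)

        log("demographics", self.client_submit(steve, "submit_record", {
            "record_type": "demographics", "payload": fx.demographics}))

        premature = self.client_submit(john, "submit_record", {
            "record_type": "test_result", "payload": fx.test_result})
        log("premature_test_result", premature)

        log("authorize_doctor", self.client_submit(steve, "grant_authorization", {
            "grantee": fx.doctor_id, "patient": fx.patient_id,
            "permissions": ["read", "write", "authorize"]}))

        log("encounter_note", self.client_submit(carl, "submit_record", {
            "record_type": "encounter_note", "payload": fx.encounter_note}))

        log("order_test", self.client_submit(carl, "grant_authorization", {
            "grantee": fx.technician_id, "patient": fx.patient_id,
            "permissions": ["read", "write"]}))

        log("test_result", self.client_submit(john, "submit_record", {
            "record_type": "test_result", "payload": fx.test_result}))

        anon = self.client_query(researcher, "query_anonymized", {
            "patient": fx.patient_id, "record_type": "encounter_note"})
        steps.append({"stage": "research_read", "status": anon.status,
                      "n_records": len(anon.records)})

        committed = [s for s in steps if s.get("status") == "committed"]
        some_peer = next(p for p in self.peers.values() if p.available)
        return {
            "steps": steps,
            "committed_records": len(committed),
            "chain_length": len(some_peer.chain),
            "state_fingerprint": some_peer.state.fingerprint(),
            "anonymized_sample": anon.records[0] if anon.records else None,
            "chain_valid": some_peer.verify_chain()[0],
        }


def build_network(config: NetworkConfig) -> Network:
    """Stand up CAs, peers and orderer with genesis committed everywhere."""
    return Network(config)
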