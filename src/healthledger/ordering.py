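"""The ordering service: FCFS queueing, block cutting, PoA block signing.

A single designated orderer receives endorsed transactions from clients,
queues them first-come-first-serve, and cuts a block when either of two
conditions is met — whichever comes first:

* *batch size* — the pending queue reaches ``batch_size`` transactions;
* *batch timeout* — ``batch_timeout`` seconds have elapsed since the
  first transaction of the current batch arrived (the timer starts at
  first enqueue and restarts with each cut).

Blocks carry no nonce and need no hash pattern: validity is proof of
authority — the block is signed by the orderer, whose subject must be on
the MSP allow-list.  The header's current hash covers the block number,
the previous hash and the canonical bytes of the transaction list, so
the chain is tamper-evident end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

from . import crypto
from .chaincode import CHAINCODE_NAME, EHRRequest, EHRResponse
from .identity import Identity, Certificate, MSPConfig, sign as id_sign, verify_certificate, verify_signature
from .errors import OrderingError
from .clock import rfc3339

GENESIS_PREV_HASH = "00" * 32


@dataclass
class OrdererConfig:
    """The two performance-critical batching parameters."""

    batch_timeout: float = 2.0  # seconds
    batch_size: int = 10  # transactions per block, max

    def validate(self) -> None:
        if self.batch_timeout <= 0:
            raise OrderingError("batch_timeout must be positive")
        if self.batch_size < 1:
            raise OrderingError("batch_size must be >= 1")


@dataclass
class EHRTransaction:
    """One EHR lifecycle unit: signed request + signed endorsement."""

    tx_id: str
    chaincode_name: str
    request: EHRRequest
    response: EHRResponse
    user_signature: str
    peer_signature: str
    arrival_time: float = 0.0  # stamped by the orderer

    def to_dict(self) -> dict:
        return {
            "tx_id": self.tx_id,
            "chaincode_name": self.chaincode_name,
            "request": self.request.to_dict(),
            "response": self.response.to_dict(),
            "user_signature": self.user_signature,
            "peer_signature": self.peer_signature,
            "arrival_time": self.arrival_time,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EHRTransaction":
        return cls(
            tx_id=d["tx_id"],
            chaincode_name=d["chaincode_name"],
            request=EHRRequest.from_dict(d["request"]),
            response=EHRResponse.from_dict(d["response"]),
            user_signature=d["user_signature"],
            peer_signature=d["peer_signature"],
            arrival_time=d["arrival_time"],
        )


def assemble_transaction(request: EHRRequest, response: EHRResponse) -> EHRTransaction:
    """Client step 3: bind the endorsement to the request as a transaction."""
    return EHRTransaction(
        tx_id=request.digest(),
        chaincode_name=CHAINCODE_NAME,
        request=request,
        response=response,
        user_signature=request.client_signature,
        peer_signature=response.peer_signature,
    )


@dataclass
class BlockHeader:
    number: int
    previous_hash: str  # hex of 32 bytes
    current_hash: str

    def to_dict(self) -> dict:
        return {
            "number": self.number,
            "previous_hash": self.previous_hash,
            "current_hash": self.current_hash,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BlockHeader":
        return cls(number=d["number"], previous_hash=d["previous_hash"], current_hash=d["current_hash"])


@dataclass
class BlockMetadata:
    timestamp: str  # RFC 3339
    orderer_cert: Certificate
    orderer_signature: str

    def to_dict(self) -> dict:
        return {
            "timestamp": self.timestamp,
            "orderer_cert": self.orderer_cert.to_dict(),
            "orderer_signature": self.orderer_signature,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BlockMetadata":
        return cls(
            timestamp=d["timestamp"],
            orderer_cert=Certificate.from_dict(d["orderer_cert"]),
            orderer_signature=d["orderer_signature"],
        )


def compute_block_hash(number: int, previous_hash: str, tx_dicts: List[dict]) -> str:
    """SHA-256 over (number ‖ previous hash ‖ canonical transaction bytes)."""
    return crypto.sha256_hex(
        crypto.canonical_json(
            {"number": number, "previous_hash": previous_hash, "transactions": tx_dicts}
        )
    )


@dataclass
class Block:
    header: BlockHeader
    transactions: List[EHRTransaction]
    metadata: BlockMetadata

    def signed_bytes(self) -> bytes:
        """Bytes the orderer signs: header, timestamp and transactions."""
        return crypto.canonical_json(
            {
                "header": self.header.to_dict(),
                "timestamp": self.metadata.timestamp,
                "transactions": [t.to_dict() for t in self.transactions],
            }
        )

    def to_dict(self) -> dict:
        return {
            "header": self.header.to_dict(),
            "transactions": [t.to_dict() for t in self.transactions],
            "metadata": self.metadata.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Block":
        return cls(
            header=BlockHeader.from_dict(d["header"]),
            transactions=[EHRTransaction.from_dict(t) for t in d["transactions"]],
            metadata=BlockMetadata.from_dict(d["metadata"]),
        )


def _signed_block(number: int, previous_hash: str, txs: List[EHRTransaction], orderer: Identity, now: float) -> Block:
    tx_dicts = [t.to_dict() for t in txs]
    header = BlockHeader(
        number=number,
        previous_hash=previous_hash,
        current_hash=compute_block_hash(number, previous_hash, tx_dicts),
    )
    block = Block(header=header, transactions=txs, metadata=BlockMetadata(rfc3339(now), orderer.certificate, ""))
    block.metadata.orderer_signature = id_sign(orderer, block.signed_bytes()).hex()
    return block


def make_genesis(orderer: Identity, now: float = 0.0) -> Block:
    """Block 0: empty transaction list, all-zero previous hash."""
    return _signed_block(0, GENESIS_PREV_HASH, [], orderer, now)


def create_block(
    pending: List[EHRTransaction],
    prev: Block,
    orderer: Identity,
    now: float,
) -> Block:
    """Cut a block extending ``prev`` with the given transactions."""
    if not pending:
        raise OrderingError("cannot cut an empty block")
    return _signed_block(
        prev.header.number + 1, prev.header.current_hash, list(pending), orderer, now
    )


class Orderer:
    """Single PoA orderer: verify, enqueue FCFS, cut under timeout/size rules."""

    def __init__(self, identity: Identity, config: OrdererConfig, msp: MSPConfig, genesis_time: float = 0.0):
        config.validate()
        self.identity = identity
        self.config = config
        self.msp = msp
        self.pending: List[EHRTransaction] = []
        self.chain: List[Block] = [make_genesis(identity, genesis_time)]

    @property
    def tip(self) -> Block:
        return self.chain[-1]

    def submit(self, tx: EHRTransaction, now: float) -> dict:
        """Accept a transaction into the pending queue (arrival-stamped).

        Both signatures must verify against the certificates they
        accompany, and both certificates must be live consortium
        credentials — the orderer never queues garbage that committing
        peers would unanimously reject.
        """
        req, resp = tx.request, tx.response
        if not verify_certificate(req.client_cert, self.msp):
            raise OrderingError("client certificate not trusted")
        if not verify_certificate(resp.endorsing_peer_cert, self.msp):
            raise OrderingError("endorsing peer certificate not trusted")
        try:
            usig = bytes.fromhex(tx.user_signature)
            psig = bytes.fromhex(tx.peer_signature)
        except ValueError:
            raise OrderingError("malformed signature encoding")
        if not verify_signature(req.client_cert, req.body_bytes(), usig):
            raise OrderingError("user signature invalid")
        if not verify_signature(resp.endorsing_peer_cert, resp.body_bytes(), psig):
            raise OrderingError("peer signature invalid")
        tx.arrival_time = now
        self.pending.append(tx)
        return {"tx_id": tx.tx_id, "queued": len(self.pending), "arrival_time": now}

    def batch_deadline(self) -> Optional[float]:
        """When the current batch times out, or None if the queue is empty."""
        if not self.pending:
            return None
        return self.pending[0].arrival_time + self.config.batch_timeout

    def maybe_cut(self, now: float) -> Optional[Block]:
        """Cut one block if the size or timeout condition is met.

        Callers loop while blocks keep coming (a burst larger than
        ``batch_size`` yields several size-triggered blocks).
        """
        if not self.pending:
            return None
        size_hit = len(self.pending) >= self.config.batch_size
        # compare against the same float expression batch_deadline() uses,
        # so a caller advancing exactly to the deadline always triggers it
        timeout_hit = now >= self.pending[0].arrival_time + self.config.batch_timeout
        if not (size_hit or timeout_hit):
            return None
        self.pending.sort(key=lambda t: (t.arrival_time, t.tx_id))
        batch = self.pending[: self.config.batch_size]
        self.pending = self.pending[self.config.batch_size:]
        block = create_block(batch, self.tip, self.identity, now)
        self.chain.append(block)
        return block

    def cut_all(self, now: float) -> List[Block]:
        """Cut every block currently due (drains size-triggered backlog)."""
        out = []
        while True:
            blk = self.maybe_cut(now)
            if blk is None:
                return out
            out.append(blk)
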