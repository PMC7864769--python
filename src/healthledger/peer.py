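"""Committing peers: block validation, world state, history, chain audit.

Each peer holds a full copy of the chain plus the *world state* — the
latest versioned value per ledger key, deterministically derived from
the chain.  On delivery of a block the peer:

1. checks block-level validity: hash linkage and recomputation, and the
   proof-of-authority condition (the block is signed by an orderer whose
   certificate chains to a trusted CA and whose subject is on the MSP
   allow-list);
2. checks each transaction: user and peer signatures, endorsement
   success, and the MVCC condition — every (key, version) the endorsing
   peer read must still be current.  A stale read flags that one
   transaction invalid; the block itself is still committed, keeping the
   ledger append-only;
3. applies the write sets of valid transactions, versioning each write
   as (block number, transaction index), and extends the per-key history
   index.

Because every step is deterministic, all peers fed the same block stream
converge to byte-identical ledgers and equal world states, and the
state can always be rebuilt from scratch by replay.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from . import chaincode, records
from .errors import CommitError, PeerUnavailableError
from .identity import Identity, MSPConfig, verify_certificate, verify_signature
from .ordering import Block, GENESIS_PREV_HASH, compute_block_hash

Version = Tuple[int, int]  # (block number, tx index)


class WorldState:
    """Latest versioned value per key, plus a per-key history index."""

    def __init__(self):
        self._data: Dict[str, Tuple[dict, Version]] = {}
        self._history: Dict[str, List[Tuple[dict, Version, str]]] = {}

    def get(self, key: str) -> Optional[dict]:
        entry = self._data.get(key)
        return copy.deepcopy(entry[0]) if entry else None

    def version(self, key: str) -> Optional[Version]:
        entry = self._data.get(key)
        return entry[1] if entry else None

    def keys(self) -> Iterable[str]:
        return self._data.keys()

    def keys_for(self, patient_id: Optional[str] = None, record_type: Optional[str] = None) -> List[str]:
        out = []
        for key in self._data:
            pid, rt, _ = records.parse_key(key)
            if patient_id is not None and pid != patient_id:
                continue
            if record_type is not None and rt != record_type:
                continue
            out.append(key)
        return sorted(out)

    def apply(self, key: str, value: dict, version: Version, tx_id: str) -> None:
        value = copy.deepcopy(value)
        self._data[key] = (value, version)
        self._history.setdefault(key, []).append((value, version, tx_id))

    def history_of(self, key: str) -> List[Tuple[dict, Version, str]]:
        return [(copy.deepcopy(v), ver, txid) for v, ver, txid in self._history.get(key, [])]

    def versions_snapshot(self) -> Dict[str, Version]:
        return {k: v[1] for k, v in self._data.items()}

    def items(self) -> List[Tuple[str, dict, Version]]:
        return sorted((k, copy.deepcopy(v), ver) for k, (v, ver) in self._data.items())

    def fingerprint(self) -> str:
        from . import crypto

        return crypto.sha256_hex(
            crypto.canonical_json([[k, v, list(ver)] for k, v, ver in self.items()])
        )


@dataclass
class BlockValidation:
    block_valid: bool
    reason: Optional[str] = None
    tx_valid: List[bool] = field(default_factory=list)
    tx_reasons: List[Optional[str]] = field(default_factory=list)


@dataclass
class CommitReport:
    block_number: int
    n_valid: int
    n_invalid: int
    tx_valid: List[bool]


def _check_block_authority(block: Block, msp: MSPConfig) -> Optional[str]:
    """PoA + integrity checks that do not depend on peer state."""
    cert = block.metadata.orderer_cert
    if not verify_certificate(cert, msp):
        return "orderer certificate not trusted"
    if cert.subject_id not in msp.orderer_subjects:
        return "block signer is not an authorized orderer"
    recomputed = compute_block_hash(
        block.header.number,
        block.header.previous_hash,
        [t.to_dict() for t in block.transactions],
    )
    if recomputed != block.header.current_hash:
        return "current_hash does not match block contents"
    try:
        sig = bytes.fromhex(block.metadata.orderer_signature)
    except ValueError:
        return "malformed orderer signature"
    if not verify_signature(cert, block.signed_bytes(), sig):
        return "orderer signature invalid"
    if block.header.number == 0:
        if block.header.previous_hash != GENESIS_PREV_HASH:
            return "genesis previous_hash must be all zeroes"
    elif not block.transactions:
        return "non-genesis block must contain transactions"
    return None


def _check_transaction(tx, msp: MSPConfig, current: Dict[str, Version]) -> Optional[str]:
    """Per-transaction validity; None means valid."""
    req, resp = tx.request, tx.response
    if not verify_certificate(req.client_cert, msp):
        return "client certificate not trusted"
    if not verify_certificate(resp.endorsing_peer_cert, msp):
        return "endorsing peer certificate not trusted"
    try:
        usig = bytes.fromhex(tx.user_signature)
        psig = bytes.fromhex(tx.peer_signature)
    except ValueError:
        return "malformed signature"
    if not verify_signature(req.client_cert, req.body_bytes(), usig):
        return "user signature invalid"
    if not verify_signature(resp.endorsing_peer_cert, resp.body_bytes(), psig):
        return "peer signature invalid"
    if resp.error is not None:
        return "endorsement carried an error"
    for key, ver in resp.read_set:
        if current.get(key) != ver:
            return f"stale read of {key!r} (MVCC)"
    return None


class Peer:
    """A committing (and endorsing) peer node."""

    def __init__(self, identity: Identity, org: str, msp: MSPConfig):
        self.identity = identity
        self.org = org
        self.msp = msp
        self.chain: List[Block] = []
        self.state = WorldState()
        self.available = True

    @property
    def name(self) -> str:
        return self.identity.subject_id

    def set_available(self, available: bool) -> None:
        """Toggle availability; a down peer refuses endorsement and queries."""
        self.available = bool(available)

    def _require_available(self) -> None:
        if not self.available:
            raise PeerUnavailableError(f"peer {self.name} is unavailable")

    # --- endorsement ----------------------------------------------------

    def endorse(self, request: chaincode.EHRRequest) -> chaincode.EHRResponse:
        """Lifecycle step 2: simulate the chaincode and sign the response."""
        self._require_available()
        return chaincode.execute(request, self.state, self.identity, self.msp)

    # --- validation and commitment --------------------------------------

    def validate_block(self, block: Block) -> BlockValidation:
        reason = _check_block_authority(block, self.msp)
        if reason is None:
            tip_number = self.chain[-1].header.number if self.chain else -1
            tip_hash = self.chain[-1].header.current_hash if self.chain else GENESIS_PREV_HASH
            if block.header.number == tip_number + 1 and block.header.previous_hash != tip_hash:
                reason = "previous_hash does not match chain tip"
        if reason is not None:
            return BlockValidation(False, reason)
        current = self.state.versions_snapshot()
        flags: List[bool] = []
        reasons: List[Optional[str]] = []
        for idx, tx in enumerate(block.transactions):
            why = _check_transaction(tx, self.msp, current)
            flags.append(why is None)
            reasons.append(why)
            if why is None:
                for key, _value in tx.response.write_set:
                    current[key] = (block.header.number, idx)
        return BlockValidation(True, None, flags, reasons)

    def commit_block(self, block: Block) -> CommitReport:
        """Lifecycle step 5: validate, append, apply valid write sets."""
        expected = self.chain[-1].header.number + 1 if self.chain else 0
        if block.header.number != expected:
            raise CommitError(
                f"block number gap: expected {expected}, got {block.header.number}"
            )
        result = self.validate_block(block)
        if not result.block_valid:
            raise CommitError(f"block rejected: {result.reason}")
        self.chain.append(block)
        n_valid = 0
        for idx, (tx, ok) in enumerate(zip(block.transactions, result.tx_valid)):
            if not ok:
                continue
            n_valid += 1
            for key, value in tx.response.write_set:
                self.state.apply(key, value, (block.header.number, idx), tx.tx_id)
        return CommitReport(
            block_number=block.header.number,
            n_valid=n_valid,
            n_invalid=len(block.transactions) - n_valid,
            tx_valid=result.tx_valid,
        )

    # --- queries ---------------------------------------------------------

    def get_history(self, key: str) -> List[Tuple[dict, Version, str]]:
        """All committed versions of a key in chain order (oldest first)."""
        self._require_available()
        return self.state.history_of(key)

    def verify_chain(self) -> Tuple[bool, Optional[str]]:
        return verify_chain_blocks(self.chain, self.msp)

    def ledger_bytes(self) -> bytes:
        return serialize_chain(self.chain)


# --- whole-chain audit and replay ----------------------------------------


def verify_chain_blocks(blocks: List[Block], msp: MSPConfig) -> Tuple[bool, Optional[str]]:
    """Audit a chain from genesis: linkage, hashes, orderer authority.

    Returns (ok, first violation).  Any in-place edit of a committed
    record, any re-signed or unsigned block, and any dropped or reordered
    block makes this false.
    """
    if not blocks:
        return False, "empty chain (no genesis)"
    prev_hash = GENESIS_PREV_HASH
    for i, block in enumerate(blocks):
        if block.header.number != i:
            return False, f"block {i}: wrong number {block.header.number}"
        if block.header.previous_hash != prev_hash:
            return False, f"block {i}: broken hash link"
        reason = _check_block_authority(block, msp)
        if reason is not None:
            return False, f"block {i}: {reason}"
        prev_hash = block.header.current_hash
    return True, None


def replay_chain(blocks: List[Block], msp: MSPConfig) -> WorldState:
    """Rebuild a world state from scratch by re-committing every block."""
    shadow = Peer.__new__(Peer)
    shadow.msp = msp
    shadow.chain = []
    shadow.state = WorldState()
    shadow.available = True
    for block in blocks:
        shadow.commit_block(block)
    return shadow.state


def serialize_chain(blocks: List[Block]) -> bytes:
    """JSON-lines encoding of a chain (one canonical block per line)."""
    from . import crypto

    return b"\n".join(crypto.canonical_json(b.to_dict()) for b in blocks) + b"\n"


def parse_chain(data: bytes) -> List[Block]:
    import json

    out = []
    for line in data.splitlines():
        if line.strip():
            out.append(Block.from_dict(json.loads(line.decode("utf-8"))))
    return out
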