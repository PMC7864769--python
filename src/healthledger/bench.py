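"""Performance harness: the four ledger metrics under concurrent load.

The metrics:

* **read latency** — time from submitting a read request to receiving
  the response (lifecycle steps 1–2; the chain is untouched);
* **read throughput (RPS)** — completed reads per second on a peer;
  the network-level figure is the sum over peers, since reads on one
  peer are independent of reads on another;
* **transaction latency** — time from submitting a write request until
  the transaction is available on *every* peer (all five lifecycle
  steps, measured to the last peer's commitment);
* **transaction throughput (TPS)** — committed transactions per second.

Concurrency is modeled as interleaved events on the simulated clock:
each stage (endorse, order, commit, read) is a single-server FIFO queue
with a configurable constant service time, while the transactions
themselves run through the real pipeline — real signatures, the real
orderer's batching rules, real block commitment on every peer.  Under a
fixed seed a run is bit-reproducible.  Absolute timings are properties
of the configured service times, not of any particular hardware; what
the harness exposes is the *structure* — how batch timeout and batch
size shape latency and throughput via the number of blocks cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional

from .clock import rfc3339
from .chaincode import make_request
from .errors import OrderingError, PeerUnavailableError
from .network import Network
from .ordering import Block, OrdererConfig, assemble_transaction


@dataclass
class ServiceTimes:
    """Per-stage service times (seconds) for the simulated-clock model.

    Defaults are on the scale a small containerized deployment shows:
    ~0.1 s to serve a read (hence ~10 RPS per peer), ~0.1 s to endorse,
    0.05 s for the orderer to assemble and sign a block, 0.2 s for a
    peer to validate and commit one block.
    """

    read: float = 0.1
    respond: float = 0.005
    endorse: float = 0.1
    order: float = 0.05
    commit: float = 0.2


@dataclass
class MetricReport:
    batch_timeout: float
    batch_size: int
    clock_mode: str
    n_concurrent: int
    read_latency: Optional[float] = None
    read_throughput: Optional[float] = None  # RPS on the measured peer
    network_read_throughput: Optional[float] = None  # sum over peers
    transaction_latency: Optional[float] = None
    transaction_throughput: Optional[float] = None  # TPS
    n_blocks_cut: Optional[int] = None
    first_block_cut_delay: Optional[float] = None  # cut time - first tx arrival

    def to_dict(self) -> dict:
        return asdict(self)


def measure_read(
    network: Network,
    n_concurrent: int,
    peer_name: str = "A",
    times: ServiceTimes = ServiceTimes(),
) -> MetricReport:
    """Read latency/throughput for ``n_concurrent`` simultaneous reads.

    One representative read is executed for real (so access control,
    availability and result correctness are exercised); the n-fold
    concurrent completion times follow the single-server queue model.
    Batching parameters are irrelevant here — no block is generated by
    a read.
    """
    if n_concurrent < 1:
        raise ValueError("n_concurrent must be >= 1")
    peer = network.peers[peer_name]
    if not peer.available:
        raise PeerUnavailableError(f"peer {peer_name} is unavailable")
    keys = list(peer.state.keys())
    auditor = network.enroll_user("auditor", "bench-auditor", "Bench Auditor")
    if not keys:
        raise ValueError("ledger is empty; commit records before measuring reads")
    patient = sorted(keys)[0].split("~")[0]
    out = network.client_query(
        auditor, "query_records", {"patient": patient}, target=peer_name
    )
    assert out.status == "ok"

    last_response = n_concurrent * times.read + times.respond
    per_peer_rps = n_concurrent / last_response
    n_up = sum(1 for p in network.peers.values() if p.available)
    return MetricReport(
        batch_timeout=network.orderer.config.batch_timeout,
        batch_size=network.orderer.config.batch_size,
        clock_mode=network.config.clock_mode,
        n_concurrent=n_concurrent,
        read_latency=times.read + times.respond,
        read_throughput=per_peer_rps,
        network_read_throughput=per_peer_rps * n_up,
    )


def measure_write(
    network: Network,
    n_concurrent: int,
    cfg: Optional[OrdererConfig] = None,
    times: ServiceTimes = ServiceTimes(),
    peer_name: str = "A",
) -> MetricReport:
    """Transaction latency/throughput for ``n_concurrent`` simultaneous writes.

    All requests are submitted at the same instant; the endorsing peer
    serves them FIFO, the real orderer cuts blocks under its timeout and
    size rules as transactions arrive, and every block is committed on
    every available peer (block validation is a per-block cost, which is
    why throughput falls as more blocks are cut for the same workload).
    """
    if n_concurrent < 1:
        raise ValueError("n_concurrent must be >= 1")
    if cfg is not None:
        cfg.validate()
        network.orderer.config = cfg
    orderer = network.orderer
    t0 = network.clock.now()

    # each writer is a distinct patient filing their own demographics —
    # self-access, so the workload isolates pipeline cost from policy cost
    txs = []
    for i in range(n_concurrent):
        pid = f"BW{i:05d}"
        client = network.enroll_user("patient", pid, f"Bench Writer {i}")
        payload = {"patientID": pid, "patientName": f"Bench Writer {i}"}
        req = make_request(
            client.identity,
            "submit_record",
            {"record_type": "demographics", "payload": payload},
            nonce=network._nonce(),
            sent_at=rfc3339(t0),
        )
        resp = network.peers[peer_name].endorse(req)
        if resp.error is not None:
            raise OrderingError(f"endorsement failed: {resp.error}")
        txs.append(assemble_transaction(req, resp))

    # event loop: arrivals are the sequential endorsement completions;
    # between arrivals the batch timeout may fire
    blocks: List[Block] = []
    cut_times: List[float] = []
    first_arrival: Optional[float] = None

    def drain_due(until: float) -> None:
        while True:
            deadline = orderer.batch_deadline()
            if deadline is None or deadline > until:
                return
            for blk in orderer.cut_all(deadline):
                blocks.append(blk)
                cut_times.append(deadline)

    for k, tx in enumerate(txs, start=1):
        arrival = t0 + k * times.endorse
        drain_due(arrival)
        orderer.submit(tx, arrival)
        for blk in orderer.cut_all(arrival):
            blocks.append(blk)
            cut_times.append(arrival)
    while orderer.pending:
        deadline = orderer.batch_deadline()
        assert deadline is not None
        drain_due(deadline)

    # pipeline timing: orderer assembles blocks FIFO, then each peer
    # validates/commits them FIFO
    orderer_free = t0
    peer_free: Dict[str, float] = {n: t0 for n in network.peers}
    latest_commit = t0
    for blk, t_cut in zip(blocks, cut_times):
        created = max(t_cut, orderer_free) + times.order
        orderer_free = created
        for name, peer in network.peers.items():
            if not peer.available:
                continue
            done = max(peer_free[name], created) + times.commit
            peer_free[name] = done
            latest_commit = max(latest_commit, done)
            peer.commit_block(blk)

    if network.config.clock_mode == "simulated":
        network.clock.advance_to(max(latest_commit, network.clock.now()))

    elapsed = latest_commit - t0
    return MetricReport(
        batch_timeout=orderer.config.batch_timeout,
        batch_size=orderer.config.batch_size,
        clock_mode=network.config.clock_mode,
        n_concurrent=n_concurrent,
        transaction_latency=elapsed,
        transaction_throughput=n_concurrent / elapsed if elapsed > 0 else float("inf"),
        n_blocks_cut=len(blocks),
        first_block_cut_delay=(cut_times[0] - blocks[0].transactions[0].arrival_time) if blocks else None,
    )
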