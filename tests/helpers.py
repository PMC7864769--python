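"""Shared test utilities and independent oracles.

The oracles here deliberately take different computational routes from
the library: delegation is checked by graph reachability (networkx),
MVCC by sequential re-execution over a plain dict, anonymization by a
direct hashlib call.
"""

from __future__ import annotations

import hashlib
import random
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx

from healthledger import (
    Network,
    NetworkConfig,
    OrdererConfig,
    OrgSpec,
    assemble_transaction,
    build_network,
    make_request,
)
from healthledger.clock import rfc3339

PERMS = ("read", "write", "authorize")


def tiny_network(seed: int = 0, batching: Optional[OrdererConfig] = None) -> Network:
    """One government org, one peer — the cheapest viable consortium."""
    cfg = NetworkConfig(
        orgs=[OrgSpec("gov1", "government")],
        batching=batching or OrdererConfig(2.0, 10),
        seed=seed,
    )
    return build_network(cfg)


def endorsed_tx(net: Network, client, api: str, args: dict, peer_name: str = "A"):
    """Build a signed, endorsed transaction without ordering it."""
    req = make_request(
        client.identity, api, args, nonce=net._nonce(), sent_at=rfc3339(net.clock.now())
    )
    resp = net.peers[peer_name].endorse(req)
    assert resp.error is None, resp.error
    return assemble_transaction(req, resp)


# --- delegation oracle ----------------------------------------------------


GrantEdge = Tuple[str, str, Tuple[str, ...]]  # (grantor, grantee, permissions)


def random_grant_edges(rng: random.Random, actors: Sequence[str], patient: str) -> List[GrantEdge]:
    nodes = [patient, *actors]
    edges = []
    for _ in range(rng.randint(0, 3 * len(actors))):
        g, t = rng.sample(nodes, 2)
        perms = tuple(sorted(rng.sample(PERMS, rng.randint(1, 3))))
        edges.append((g, t, perms))
    return edges


def oracle_is_authorized(edges: Sequence[GrantEdge], patient: str, grantee: str, needed: str) -> bool:
    """Reachability oracle: delegators are the nodes reachable from the
    patient along authorize-carrying edges; the grantee is authorized iff
    some delegator granted them the needed permission."""
    if grantee == patient:
        return True
    g = nx.DiGraph()
    g.add_node(patient)
    for grantor, target, perms in edges:
        if "authorize" in perms:
            g.add_edge(grantor, target)
    delegators = {patient} | nx.descendants(g, patient)
    return any(
        grantor in delegators and target == grantee and needed in perms
        for grantor, target, perms in edges
    )


def grants_to_state(edges: Sequence[GrantEdge], patient: str):
    """Materialize grant edges as authorization records in a world state."""
    from healthledger.peer import WorldState

    state = WorldState()
    for i, (grantor, target, perms) in enumerate(edges):
        key = f"{patient}~authorization~{i + 1:04d}"
        state.apply(
            key,
            {
                "record_type": "authorization",
                "key": key,
                "payload": {
                    "grantorID": grantor,
                    "granteeID": target,
                    "patientID": patient,
                    "permissions": list(perms),
                    "granted_at": "2021-01-22T00:00:00.000000Z",
                },
                "created_by": grantor,
                "created_at": "2021-01-22T00:00:00.000000Z",
            },
            (1, i),
            f"tx{i}",
        )
    return state


# --- MVCC oracle ----------------------------------------------------------


def oracle_valid_set(blocks) -> Tuple[List[str], Dict[str, Tuple[int, int]]]:
    """Sequential re-execution over a plain dict: a transaction is valid
    iff every read-set version still matches; valid writes bump versions."""
    versions: Dict[str, Tuple[int, int]] = {}
    valid: List[str] = []
    for block in blocks:
        for idx, tx in enumerate(block.transactions):
            ok = tx.response.error is None and all(
                versions.get(k) == v for k, v in tx.response.read_set
            )
            if ok:
                valid.append(tx.tx_id)
                for k, _v in tx.response.write_set:
                    versions[k] = (block.header.number, idx)
    return valid, versions


def sha256_oracle(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def applied_tx_ids(peer) -> List[str]:
    """Tx ids whose write set was actually applied to the peer's state."""
    out = []
    for block in peer.chain:
        for idx, tx in enumerate(block.transactions):
            ws = tx.response.write_set
            if ws and any(
                h[1] == (block.header.number, idx)
                for h in peer.state.history_of(ws[0][0])
            ):
                out.append(tx.tx_id)
    return out


def random_update_workload(seed: int, max_patients: int = 20, max_txs: int = 200):
    """A random endorse/order/commit workload on a one-peer network.

    Transactions arrive in generations endorsed against the same state
    snapshot, so write-write conflicts (stale reads) occur naturally;
    the batch size is drawn per workload, randomizing block partitions.
    Returns the committing peer and its network.
    """
    rng = random.Random(seed)
    batch = OrdererConfig(batch_timeout=1e6, batch_size=rng.randint(1, 8))
    net = tiny_network(seed=seed, batching=batch)
    n_patients = rng.randint(3, max_patients)
    clients = {}
    for i in range(n_patients):
        pid = f"W{i:02d}"
        clients[pid] = net.enroll_user("patient", pid, f"W {i}")
    peer = net.peers["A"]
    n_txs = rng.randint(10, max_txs)
    done = 0
    t = 0.0
    while done < n_txs:
        gen = min(rng.randint(1, 8), n_txs - done)
        group = []
        for _ in range(gen):
            pid = rng.choice(list(clients))
            args = {
                "record_type": "demographics",
                "payload": {"patientID": pid, "patientName": f"v{rng.random():.6f}"},
            }
            existing = peer.state.keys_for(patient_id=pid, record_type="demographics")
            if existing and rng.random() < 0.8:
                args["key"] = rng.choice(existing)
            group.append(endorsed_tx(net, clients[pid], "submit_record", args))
        for tx in group:
            t += 1.0
            net.orderer.submit(tx, t)
        for block in net.orderer.cut_all(t + 1e7):
            peer.commit_block(block)
        done += gen
    return net, peer


# --- access-control truth table ------------------------------------------

#: Transcription of the role-entitlement figure: which APIs each of the
#: nine user roles holds.  (Kept literal on purpose — this is the oracle.)
ROLE_APIS = {
    "doctor": {"submit_record", "query_records", "query_history", "grant_authorization"},
    "nurse": {"submit_record", "query_records", "query_history", "grant_authorization"},
    "lab_technician": {"submit_record", "query_records", "query_history", "grant_authorization"},
    "emergency_staff": {"submit_record", "query_records", "query_history", "grant_authorization"},
    "patient": {"submit_record", "query_records", "query_history", "grant_authorization"},
    "family_member": {"submit_record", "query_records", "query_history"},
    "auditor": {"query_records", "query_history"},
    "regulator": {"query_records", "query_history"},
    "researcher": {"query_anonymized"},
}

ALL_APIS = ("submit_record", "query_records", "query_history", "grant_authorization", "query_anonymized")
RELATIONS = ("self", "authorized", "unauthorized")


def expected_decision(role: str, api: str, relation: str):
    """(allowed, failed_check) per the three-check algorithm, transcribed
    by hand from the access-rights and decision figures."""
    if api not in ROLE_APIS[role]:
        return False, "api_not_permitted_for_role"
    if api == "query_anonymized":
        return True, None
    if relation == "self":
        return True, None
    if role in ("auditor", "regulator"):
        return True, None
    if relation == "authorized":
        return True, None
    return False, "not_authorized_by_subject"


def truth_table_cases():
    for role in ROLE_APIS:
        for api in ALL_APIS:
            for relation in RELATIONS:
                yield role, api, relation
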