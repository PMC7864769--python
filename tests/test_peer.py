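"""Block validation, MVCC, commitment, history, tamper evidence, replay."""

import random

import pytest

from healthledger import (
    CommitError,
    OrdererConfig,
    PeerUnavailableError,
    create_block,
)
from healthledger.peer import parse_chain, replay_chain, serialize_chain, verify_chain_blocks

from helpers import endorsed_tx, oracle_valid_set, tiny_network


def _submit_demo(net, pid):
    client = net.enroll_user("patient", pid, f"Name {pid}")
    return client, net.client_submit(client, "submit_record", {
        "record_type": "demographics",
        "payload": {"patientID": pid, "patientName": f"Name {pid}"}})


def test_wellformed_block_all_valid():
    net = tiny_network(seed=21)
    _, out = _submit_demo(net, "P20")
    assert out.status == "committed" and out.tx_valid is True
    peer = net.peers["A"]
    assert peer.verify_chain() == (True, None)


def test_block_signed_by_non_orderer_is_rejected():
    net = tiny_network(seed=22)
    client = net.enroll_user("patient", "P21", "N")
    tx = endorsed_tx(net, client, "submit_record", {
        "record_type": "demographics", "payload": {"patientID": "P21", "patientName": "N"}})
    rogue = create_block([tx], net.orderer.tip, client.identity, now=1.0)
    result = net.peers["A"].validate_block(rogue)
    assert not result.block_valid
    assert "orderer" in result.reason
    with pytest.raises(CommitError):
        net.peers["A"].commit_block(rogue)


def test_mvcc_conflicting_writes_in_one_block_second_flagged_invalid():
    """Two transactions endorsed against the same version of one key:
    the first commits, the second is flagged stale (matches sequential
    re-execution of the requests)."""
    net = tiny_network(seed=23, batching=OrdererConfig(10.0, 2))
    pat, _ = _submit_demo(net, "P22")
    key = "P22~demographics~0001"
    tx1 = endorsed_tx(net, pat, "submit_record", {
        "record_type": "demographics", "key": key,
        "payload": {"patientID": "P22", "patientName": "First Update"}})
    tx2 = endorsed_tx(net, pat, "submit_record", {
        "record_type": "demographics", "key": key,
        "payload": {"patientID": "P22", "patientName": "Second Update"}})
    net.orderer.submit(tx1, now=1.0)
    net.orderer.submit(tx2, now=2.0)
    [block] = net.orderer.cut_all(now=2.0)
    peer = net.peers["A"]
    report = peer.commit_block(block)
    assert report.tx_valid == [True, False]
    assert peer.state.get(key)["payload"]["patientName"] == "First Update"
    # the invalid transaction stays in the committed block, only unapplied
    assert len(peer.chain[-1].transactions) == 2
    oracle_valid, _ = oracle_valid_set(peer.chain)
    assert tx1.tx_id in oracle_valid and tx2.tx_id not in oracle_valid


def test_mvcc_matches_sequential_oracle_on_random_workload():
    rng = random.Random(5)
    net = tiny_network(seed=24, batching=OrdererConfig(30.0, rng.randint(1, 8)))
    clients = {}
    for i in range(6):
        pid = f"R{i:02d}"
        clients[pid], _ = _submit_demo(net, pid)
    peer = net.peers["A"]
    for _round in range(8):
        group = []
        for _ in range(rng.randint(1, 6)):
            pid = rng.choice(list(clients))
            args = {"record_type": "demographics",
                    "payload": {"patientID": pid, "patientName": f"v{rng.random():.6f}"}}
            if rng.random() < 0.7:
                args["key"] = f"{pid}~demographics~0001"
            group.append(endorsed_tx(net, clients[pid], "submit_record", args))
        for tx in group:
            net.orderer.submit(tx, net.clock.now())
        for block in net.orderer.cut_all(net.clock.now() + 100.0):
            peer.commit_block(block)
    committed_valid = [
        tx.tx_id
        for block in peer.chain
        for idx, tx in enumerate(block.transactions)
        if peer.state.version(tx.response.write_set[0][0]) is not None
        and any(h[1] == (block.header.number, idx)
                for h in peer.state.history_of(tx.response.write_set[0][0]))
    ]
    oracle_valid, oracle_versions = oracle_valid_set(peer.chain)
    assert sorted(committed_valid) == sorted(oracle_valid)
    assert oracle_versions == peer.state.versions_snapshot()
    # replayed world state equals the incrementally maintained one
    assert replay_chain(peer.chain, net.msp).fingerprint() == peer.state.fingerprint()


def test_commit_rejects_block_number_gap():
    net = tiny_network(seed=25)
    _submit_demo(net, "P23")
    _, out = _submit_demo(net, "P24")
    peer = net.peers["A"]
    future = net.orderer.chain[out.block_number]
    fresh = tiny_network(seed=25)  # same identities, only genesis committed
    with pytest.raises(CommitError, match="gap"):
        fresh.peers["A"].commit_block(future)


def test_history_records_all_versions_in_order():
    net = tiny_network(seed=26)
    pat, _ = _submit_demo(net, "P25")
    key = "P25~demographics~0001"
    net.client_submit(pat, "submit_record", {
        "record_type": "demographics", "key": key,
        "payload": {"patientID": "P25", "patientName": "Renamed"}})
    hist = net.peers["A"].get_history(key)
    assert [h[0]["payload"]["patientName"] for h in hist] == ["Name P25", "Renamed"]
    assert hist[0][1] < hist[1][1]
    assert net.peers["A"].get_history("nope~demographics~0001") == []


def test_unavailable_peer_refuses_then_catches_up():
    net = tiny_network(seed=27)
    pat, _ = _submit_demo(net, "P26")
    net.set_peer_available("A", False)
    with pytest.raises(PeerUnavailableError):
        net.client_query(pat, "query_records", {"patient": "P26"}, target="A")
    with pytest.raises(PeerUnavailableError):
        net.peers["A"].get_history("P26~demographics~0001")
    net.set_peer_available("A", True)
    assert net.client_query(pat, "query_records", {"patient": "P26"}, target="A").status == "ok"


def test_replica_consistency_across_six_peers(demo_net):
    net, _ = demo_net
    ledgers = {name: p.ledger_bytes() for name, p in net.peers.items()}
    assert len(set(ledgers.values())) == 1
    states = {name: p.state.fingerprint() for name, p in net.peers.items()}
    assert len(set(states.values())) == 1


def test_tamper_with_committed_record_breaks_verification(demo_net):
    net, _ = demo_net
    blocks = parse_chain(net.peers["A"].ledger_bytes())  # deep copy via serialization
    target = blocks[3].transactions[0]
    target.response.write_set[0][1]["payload"]["physicalExamination"] = "acute distress"
    ok, violation = verify_chain_blocks(blocks, net.msp)
    assert not ok and "block 3" in violation


def test_deleting_middle_block_breaks_linkage(demo_net):
    net, _ = demo_net
    blocks = parse_chain(net.peers["A"].ledger_bytes())
    del blocks[2]
    ok, _ = verify_chain_blocks(blocks, net.msp)
    assert not ok


def test_random_single_byte_mutations_always_detected(demo_net):
    """Flipping any single byte of the serialized ledger breaks either
    JSON parsing or chain verification."""
    net, _ = demo_net
    raw = bytearray(net.peers["A"].ledger_bytes())
    rng = random.Random(99)
    for _ in range(40):
        pos = rng.randrange(len(raw))
        old = raw[pos]
        new = rng.randrange(256)
        while new == old:
            new = rng.randrange(256)
        mutated = bytes(raw[:pos]) + bytes([new]) + bytes(raw[pos + 1:])
        try:
            blocks = parse_chain(mutated)
        except Exception:
            continue  # undecodable ledger counts as detected
        ok, _ = verify_chain_blocks(blocks, net.msp)
        assert not ok, f"mutation at byte {pos} went undetected"


def test_state_reconstruction_by_replay(demo_net):
    net, _ = demo_net
    peer = net.peers["B"]
    rebuilt = replay_chain(peer.chain, net.msp)
    assert rebuilt.fingerprint() == peer.state.fingerprint()
    assert serialize_chain(peer.chain) == peer.ledger_bytes()
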