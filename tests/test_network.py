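"""Topology construction, lifecycle end-to-end, worked scenario, drills."""

import pytest

import healthledger as hl
from healthledger import ConfigError, NetworkConfig, OrgSpec, PeerUnavailableError, build_network
from healthledger import fixtures
from healthledger.identity import verify_certificate, verify_signature


def test_default_profile_topology(demo_net):
    net, _ = demo_net
    assert list(net.peers) == ["A", "B", "C", "D", "E", "F"]
    assert len(net.cas) == 3
    assert net.orderer_identity.certificate.role == "orderer"
    assert net.orderer_identity.certificate.org_type == "government"
    genesis = [p.chain[0].to_dict() for p in net.peers.values()]
    assert all(g == genesis[0] for g in genesis)


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        build_network(NetworkConfig(orgs=[]))
    with pytest.raises(ConfigError):
        build_network(NetworkConfig(orgs=[OrgSpec("g", "government", n_peers=0)]))
    with pytest.raises(ConfigError):
        build_network(NetworkConfig(orgs=[OrgSpec("h", "hospital")]))  # no government org


def test_worked_example_transcript(demo_net):
    _, transcript = demo_net
    assert transcript["committed_records"] == 5
    assert transcript["chain_valid"] is True
    stages = {s["stage"]: s for s in transcript["steps"]}
    assert stages["premature_test_result"]["status"] == "denied"
    assert stages["premature_test_result"]["failed_check"] == "not_authorized_by_subject"
    assert stages["test_result"]["status"] == "committed"
    assert stages["research_read"]["status"] == "ok"
    anon = transcript["anonymized_sample"]
    assert anon and "P01" not in str(anon)


def test_worked_example_is_deterministic_under_seed():
    t1 = build_network(NetworkConfig.default(seed=77)).run_worked_example()
    t2 = build_network(NetworkConfig.default(seed=77)).run_worked_example()
    assert t1 == t2


def test_record_retrievable_from_every_peer(demo_net):
    net, _ = demo_net
    steve = net.clients["P01"]
    for name in net.peers:
        out = net.client_query(steve, "query_records",
                               {"patient": "P01", "record_type": "demographics"},
                               target=name)
        assert out.status == "ok"
        assert out.records[0]["payload"]["patientName"] == "Steve Apple"


def test_read_path_never_mutates_chain(demo_net):
    net, _ = demo_net
    before = net.peers["A"].ledger_bytes()
    steve = net.clients["P01"]
    for _ in range(5):
        net.client_query(steve, "query_records", {"patient": "P01"})
    assert net.peers["A"].ledger_bytes() == before


def test_submission_failover_mirrors_availability_drill():
    net = build_network(NetworkConfig.default(seed=31))
    net.run_worked_example()
    steve = net.clients["P01"]
    net.set_peer_available("E", False)
    with pytest.raises(PeerUnavailableError):
        net.client_submit(steve, "submit_record", {
            "record_type": "demographics",
            "payload": {"patientID": "P01", "patientName": "Steve Apple"},
            "key": "P01~demographics~0001"}, target="E")
    retry = net.client_submit(steve, "submit_record", {
        "record_type": "demographics",
        "payload": {"patientID": "P01", "patientName": "Steve Apple"},
        "key": "P01~demographics~0001"}, target="A")
    assert retry.status == "committed"
    assert retry.peer_status["E"] == "unavailable"
    net.set_peer_available("E", True)
    assert net.peers["E"].ledger_bytes() == net.peers["A"].ledger_bytes()


def test_committed_signature_chain_verifies_from_ledger_alone(demo_net):
    """Every committed transaction carries enough to re-verify the whole
    client -> peer -> orderer signature chain with no side state."""
    net, _ = demo_net
    for block in net.peers["A"].chain:
        meta = block.metadata
        assert verify_certificate(meta.orderer_cert, net.msp)
        assert verify_signature(meta.orderer_cert, block.signed_bytes(),
                                bytes.fromhex(meta.orderer_signature))
        for tx in block.transactions:
            assert verify_certificate(tx.request.client_cert, net.msp)
            assert verify_signature(tx.request.client_cert, tx.request.body_bytes(),
                                    bytes.fromhex(tx.user_signature))
            assert verify_certificate(tx.response.endorsing_peer_cert, net.msp)
            assert verify_signature(tx.response.endorsing_peer_cert,
                                    tx.response.body_bytes(),
                                    bytes.fromhex(tx.peer_signature))


def test_security_drills_behave_as_documented():
    net = build_network(NetworkConfig.default(seed=33))
    net.run_worked_example()
    avail = fixtures.availability_drill(net)
    assert avail == {"unavailable_peer_failed": True, "retry_on_A_succeeded": True,
                     "peer_E_caught_up": True}
    hist = fixtures.history_drill(net)
    assert hist["shows_change"] is True
    assert hist["history_values"] == ["no acute distress", "acute distress"]
    revoked = fixtures.revoked_identity_drill(net)
    assert revoked == {"denied": True, "failed_check": "not_consortium_member"}
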