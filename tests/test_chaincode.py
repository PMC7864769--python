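"""Access control, delegation, execution semantics, anonymization."""

import random

import pytest

from healthledger import (
    MSPConfig,
    RecordEnvelope,
    anonymize_result,
    check_access,
    create_ca,
    enroll,
    is_authorized,
    make_request,
)
from healthledger.chaincode import NEEDED_PERMISSION
from healthledger.identity import ROLES_BY_ORG_TYPE
from healthledger.peer import WorldState

from helpers import (
    ALL_APIS,
    ROLE_APIS,
    RELATIONS,
    expected_decision,
    grants_to_state,
    oracle_is_authorized,
    random_grant_edges,
    sha256_oracle,
    tiny_network,
    truth_table_cases,
)

TS = "2021-01-22T00:00:10.000000Z"
PATIENT = "PX"


@pytest.fixture(scope="module")
def actors():
    msp = MSPConfig(orderer_subjects={"orderer-1"})
    cas = {}
    for org, org_type in [("h", "hospital"), ("i", "insurer"), ("g", "government")]:
        ca = create_ca(org, org_type, b"tt", existing=cas)
        cas[org_type] = ca
        msp.add_ca(ca.certificate)
    by_role = {}
    for role in ROLE_APIS:
        org_type = next(t for t in cas if role in ROLES_BY_ORG_TYPE[t])
        by_role[role] = enroll(cas[org_type], f"U-{role}", role.title(), role)
    patient_root = enroll(cas["government"], PATIENT, "Subject", "patient")
    return msp, by_role, patient_root


def _args_for(api, subject):
    if api == "submit_record":
        return {"record_type": "demographics",
                "payload": {"patientID": subject, "patientName": "N"}}
    if api == "grant_authorization":
        return {"grantee": "ZZ", "patient": subject, "permissions": ["read"]}
    if api == "query_history":
        return {"key": f"{subject}~encounter_note~0001"}
    return {"patient": subject}


def test_access_decision_truth_table(actors):
    """All 9 roles x 5 APIs x {self, authorized, unauthorized} against the
    hand-transcribed policy table: 135 cases, exact match."""
    msp, by_role, _ = actors
    authorized_state = grants_to_state(
        [(PATIENT, f"U-{r}", ("read", "write", "authorize")) for r in ROLE_APIS], PATIENT
    )
    empty_state = WorldState()
    mismatches = []
    for role, api, relation in truth_table_cases():
        ident = by_role[role]
        subject = ident.subject_id if relation == "self" else PATIENT
        state = authorized_state if relation == "authorized" else empty_state
        req = make_request(ident, api, _args_for(api, subject), nonce="n", sent_at=TS)
        got = check_access(req, state, msp)
        want_allowed, want_check = expected_decision(role, api, relation)
        if (got.allowed, got.failed_check) != (want_allowed, want_check):
            mismatches.append((role, api, relation, got))
    assert mismatches == []


def test_membership_check_precedes_everything(actors):
    msp, by_role, _ = actors
    doctor = by_role["doctor"]
    req = make_request(doctor, "query_records", {"patient": PATIENT}, nonce="n", sent_at=TS)

    revoking = MSPConfig(
        trusted_ca_certs=dict(msp.trusted_ca_certs),
        orderer_subjects=set(msp.orderer_subjects),
        revoked_serials={doctor.certificate.serial},
    )
    got = check_access(req, WorldState(), revoking)
    assert (got.allowed, got.failed_check) == (False, "not_consortium_member")

    # a tampered request body also fails authentication, not authorization
    req2 = make_request(doctor, "query_records", {"patient": PATIENT}, nonce="n", sent_at=TS)
    req2.args = {"patient": "someone-else"}
    got2 = check_access(req2, WorldState(), msp)
    assert (got2.allowed, got2.failed_check) == (False, "not_consortium_member")


def test_delegation_chain_example(actors):
    """patient -> Alice (r,w,a) -> Betty (r,w,a): Betty may write; a
    read-only grantee's onward grants confer nothing."""
    state = grants_to_state(
        [(PATIENT, "Alice", ("read", "write", "authorize")),
         ("Alice", "Betty", ("read", "write", "authorize")),
         (PATIENT, "ReadOnly", ("read",)),
         ("ReadOnly", "Eve", ("read", "write", "authorize"))],
        PATIENT,
    )
    assert is_authorized(state, "Betty", PATIENT, "write")
    assert is_authorized(state, "Alice", PATIENT, "authorize")
    assert not is_authorized(state, "Eve", PATIENT, "read")
    assert is_authorized(state, PATIENT, PATIENT, "write")  # root self-access


def test_delegation_matches_reachability_oracle():
    rng = random.Random(42)
    for _ in range(40):
        n = rng.randint(2, 20)
        actors_ = [f"A{i}" for i in range(n)]
        edges = random_grant_edges(rng, actors_, PATIENT)
        state = grants_to_state(edges, PATIENT)
        for _ in range(15):
            grantee = rng.choice(actors_ + [PATIENT])
            needed = rng.choice(["read", "write", "authorize"])
            assert is_authorized(state, grantee, PATIENT, needed) == oracle_is_authorized(
                edges, PATIENT, grantee, needed
            ), (edges, grantee, needed)


def test_execute_write_produces_read_write_sets():
    net = tiny_network(seed=3)
    pat = net.enroll_user("patient", "P10", "Pat Ten")
    req = net.build_request(pat, "submit_record", {
        "record_type": "demographics",
        "payload": {"patientID": "P10", "patientName": "Pat Ten"}})
    resp = net.peers["A"].endorse(req)
    assert resp.error is None
    assert resp.returned_value == "P10~demographics~0001"
    assert resp.write_set[0][0] == "P10~demographics~0001"
    assert resp.read_set == [("P10~demographics~0001", None)]
    # endorsement simulates: nothing applied yet
    assert net.peers["A"].state.get("P10~demographics~0001") is None


def test_grant_then_query_flow_end_to_end():
    net = tiny_network(seed=4)
    pat = net.enroll_user("patient", "P11", "Pat Eleven")
    doc = net.enroll_user("doctor", "D11", "Doc Eleven")
    net.client_submit(pat, "submit_record", {
        "record_type": "demographics",
        "payload": {"patientID": "P11", "patientName": "Pat Eleven"}})
    denied = net.client_query(doc, "query_records", {"patient": "P11"})
    assert denied.status == "denied"
    assert denied.decision["failed_check"] == "not_authorized_by_subject"
    net.client_submit(pat, "grant_authorization", {
        "grantee": "D11", "patient": "P11", "permissions": ["read", "write", "authorize"]})
    allowed = net.client_query(doc, "query_records", {"patient": "P11"})
    assert allowed.status == "ok"
    assert len(allowed.records) == 2  # demographics + authorization record
    assert is_authorized(net.peers["A"].state, "D11", "P11", "write")


def test_read_only_apis_produce_empty_write_sets():
    net = tiny_network(seed=5)
    pat = net.enroll_user("patient", "P12", "Pat Twelve")
    net.client_submit(pat, "submit_record", {
        "record_type": "demographics",
        "payload": {"patientID": "P12", "patientName": "Pat Twelve"}})
    researcher = net.enroll_user("researcher", "R12", "Res Twelve")
    for client, api in [(pat, "query_records"), (pat, "query_history"),
                        (researcher, "query_anonymized")]:
        args = {"key": "P12~demographics~0001"} if api == "query_history" else {"patient": "P12"}
        req = net.build_request(client, api, args)
        resp = net.peers["A"].endorse(req)
        assert resp.error is None
        assert resp.write_set == []


# --- anonymization --------------------------------------------------------


def _note(pid="P01", doc="D01"):
    return RecordEnvelope(
        "encounter_note", f"{pid}~encounter_note~0001",
        {"patientID": pid, "patientName": "Steve Apple", "doctorID": doc,
         "chiefComplaint": "c", "physicalExamination": "no acute distress",
         "assessment": "a", "plan": "p"},
        doc, TS)


def test_anonymized_digest_matches_independent_sha256():
    t = "2021-01-22T01:00:00.000000Z"
    [anon] = anonymize_result([_note()], t)
    assert anon.payload["patientID"] == sha256_oracle("P01" + t)
    assert anon.payload["doctorID"] == sha256_oracle("D01" + t)
    # clinical content untouched
    assert anon.payload["physicalExamination"] == "no acute distress"


def test_anonymization_preserves_within_query_linkage():
    t = "2021-01-22T01:00:00.000000Z"
    a, b = anonymize_result([_note(), _note(doc="D02")], t)
    assert a.payload["patientID"] == b.payload["patientID"]
    assert a.payload["doctorID"] != b.payload["doctorID"]


def test_anonymization_differs_across_queries():
    r1 = anonymize_result([_note()], "2021-01-22T01:00:00.000000Z")[0]
    r2 = anonymize_result([_note()], "2021-01-22T02:00:00.000000Z")[0]
    assert r1.payload["patientID"] != r2.payload["patientID"]


def test_anonymization_never_leaks_raw_ids():
    from healthledger import crypto

    t = "2021-01-22T01:00:00.000000Z"
    for rec in anonymize_result([_note()], t):
        blob = crypto.canonical_json(rec.to_dict()).decode()
        assert "P01" not in blob
        assert "D01" not in blob
        assert "Steve Apple" not in blob


def test_needed_permission_map_is_total():
    assert set(NEEDED_PERMISSION) == set(ALL_APIS)
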