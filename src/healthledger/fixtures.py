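"""Reference scenario data and synthetic EHR populations.

``demo_payloads`` carries the worked clinical scenario — patient Steve
Apple (P01), doctor Carl Savem, lab technician John Doe, a lipid-panel
order — used by the end-to-end demo and the security drills.  The
clinical bodies are plausible reconstructions (synthetic, not real
patient data).

``generate_population`` produces seeded synthetic populations of
schema-valid demographics, grants, encounters and lab results with a
consistent delegation structure, for tests and benchmarks.  It emulates
the *shape* of clinical traffic (who writes what about whom, under which
grants), not clinical realism: free-text fields are template strings and
visit timing is uniform.

The three security drills mirror the standard operational checks:
peer failover, a revoked identity being turned away at authentication,
and per-key history across a legitimate correction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional

from .errors import PeerUnavailableError

PATIENT_ID = "P01"
DOCTOR_ID = "D01"
TECHNICIAN_ID = "T01"


@dataclass
class DemoPayloads:
    patient_id: str
    doctor_id: str
    technician_id: str
    demographics: Dict[str, Any]
    encounter_note: Dict[str, Any]
    encounter_note_update: Dict[str, Any]
    test_result: Dict[str, Any]


def demo_payloads() -> DemoPayloads:
    """The worked scenario's record bodies (synthetic reconstruction)."""
    demographics = {
        "patientID": PATIENT_ID,
        "patientName": "Steve Apple",
        "birthDate": "1957-05-08",
        "sex": "M",
        "contact": "13 Pine Ave, Anytown",
        "allergies": ["penicillin"],
    }
    encounter_note = {
        "patientID": PATIENT_ID,
        "patientName": "Steve Apple",
        "doctorID": DOCTOR_ID,
        "chiefComplaint": "Follow-up of hyperlipidemia; intermittent chest tightness.",
        "physicalExamination": "no acute distress",
        "assessment": "Hyperlipidemia, suboptimally controlled.",
        "plan": "Repeat lipid profile; continue statin; review in 3 months.",
    }
    encounter_note_update = dict(encounter_note, physicalExamination="acute distress")
    test_result = {
        "patientID": PATIENT_ID,
        "technicianID": TECHNICIAN_ID,
        "orderingDoctorID": DOCTOR_ID,
        "testName": "Lipid profile",
        "resultItems": [
            {"analyte": "Total cholesterol", "value": "242", "unit": "mg/dL", "referenceRange": "<200"},
            {"analyte": "LDL cholesterol", "value": "165", "unit": "mg/dL", "referenceRange": "<130"},
            {"analyte": "HDL cholesterol", "value": "38", "unit": "mg/dL", "referenceRange": ">40"},
            {"analyte": "Triglycerides", "value": "195", "unit": "mg/dL", "referenceRange": "<150"},
        ],
    }
    return DemoPayloads(
        patient_id=PATIENT_ID,
        doctor_id=DOCTOR_ID,
        technician_id=TECHNICIAN_ID,
        demographics=demographics,
        encounter_note=encounter_note,
        encounter_note_update=encounter_note_update,
        test_result=test_result,
    )


# --- synthetic populations ------------------------------------------------

_FIRST = ["Ada", "Ben", "Cara", "Dev", "Elif", "Femi", "Gwen", "Hugo", "Ines", "Jon",
          "Kira", "Liam", "Mona", "Nils", "Omar", "Pia", "Quinn", "Rosa", "Sam", "Tova"]
_LAST = ["Adler", "Brook", "Chen", "Diaz", "Evers", "Fox", "Grant", "Hale", "Iqbal",
         "Jones", "Kline", "Lowe", "Moss", "Ngata", "Oster", "Park", "Reyes", "Stone"]
_COMPLAINTS = ["fatigue", "chest pain", "persistent cough", "joint pain", "headache",
               "shortness of breath", "abdominal pain", "dizziness"]


@dataclass
class GrantStep:
    grantor: str
    grantee: str
    patient: str
    permissions: List[str]


@dataclass
class Population:
    """A synthetic cohort plus the grant plan that makes it writable."""

    patients: List[Dict[str, Any]]  # demographics payloads
    doctors: List[Dict[str, str]]  # {"id", "name"}
    technicians: List[Dict[str, str]]
    grants: List[GrantStep]  # ordered: every writer is authorized first
    encounters: List[Dict[str, Any]]  # encounter_note payloads
    test_results: List[Dict[str, Any]]
    doctor_of: Dict[str, str] = field(default_factory=dict)  # patient -> doctor


def generate_population(
    n_patients: int,
    n_doctors: int,
    encounters_per_patient: int,
    seed: int,
) -> Population:
    """Deterministically generate a consistent synthetic cohort.

    Every patient grants read/write/authorize to one assigned doctor;
    that doctor writes the patient's encounters, and for roughly a third
    of patients orders a lab test (granting read/write to a technician,
    who then files the result).  Rerunning with the same arguments
    yields identical output.
    """
    if min(n_patients, n_doctors, encounters_per_patient) < 1:
        raise ValueError("all counts must be >= 1")
    rng = random.Random(seed)
    patients, doctors, technicians = [], [], []
    for i in range(n_patients):
        pid = f"SP{i:03d}"
        patients.append({
            "patientID": pid,
            "patientName": f"{rng.choice(_FIRST)} {rng.choice(_LAST)}",
            "birthDate": f"{rng.randint(1935, 2005)}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}",
            "sex": rng.choice(["F", "M"]),
            "contact": f"{rng.randint(1, 99)} Elm St",
            "allergies": rng.sample(["penicillin", "latex", "sulfa", "aspirin"], rng.randint(0, 2)),
        })
    for i in range(n_doctors):
        doctors.append({"id": f"SD{i:03d}", "name": f"Dr {rng.choice(_FIRST)} {rng.choice(_LAST)}"})
    n_tech = max(1, n_doctors // 3)
    for i in range(n_tech):
        technicians.append({"id": f"ST{i:03d}", "name": f"{rng.choice(_FIRST)} {rng.choice(_LAST)}"})

    grants: List[GrantStep] = []
    encounters: List[Dict[str, Any]] = []
    test_results: List[Dict[str, Any]] = []
    doctor_of: Dict[str, str] = {}
    for pat in patients:
        pid = pat["patientID"]
        doc = rng.choice(doctors)
        doctor_of[pid] = doc["id"]
        grants.append(GrantStep(pid, doc["id"], pid, ["read", "write", "authorize"]))
        for _ in range(encounters_per_patient):
            encounters.append({
                "patientID": pid,
                "patientName": pat["patientName"],
                "doctorID": doc["id"],
                "chiefComplaint": rng.choice(_COMPLAINTS).capitalize() + ".",
                "physicalExamination": "no acute distress",
                "assessment": "Stable; differential under review.",
                "plan": "Symptomatic management; follow-up as needed.",
            })
        if rng.random() < 1 / 3:
            tech = rng.choice(technicians)
            grants.append(GrantStep(doc["id"], tech["id"], pid, ["read", "write"]))
            test_results.append({
                "patientID": pid,
                "technicianID": tech["id"],
                "orderingDoctorID": doc["id"],
                "testName": "Basic metabolic panel",
                "resultItems": [
                    {"analyte": "Sodium", "value": str(rng.randint(132, 146)), "unit": "mmol/L",
                     "referenceRange": "135-145"},
                    {"analyte": "Creatinine", "value": f"{rng.uniform(0.6, 1.6):.2f}", "unit": "mg/dL",
                     "referenceRange": "0.6-1.2"},
                ],
            })
    return Population(
        patients=patients,
        doctors=doctors,
        technicians=technicians,
        grants=grants,
        encounters=encounters,
        test_results=test_results,
        doctor_of=doctor_of,
    )


def seed_network(network, population: Population) -> Dict[str, int]:
    """Enroll a population's actors and commit its records to a network.

    Submission order respects the delegation structure (grants precede
    the writes they authorize).  Returns counts of committed records.
    """
    clients: Dict[str, Any] = {}
    for pat in population.patients:
        clients[pat["patientID"]] = network.enroll_user("patient", pat["patientID"], pat["patientName"])
    for doc in population.doctors:
        clients[doc["id"]] = network.enroll_user("doctor", doc["id"], doc["name"])
    for tech in population.technicians:
        clients[tech["id"]] = network.enroll_user("lab_technician", tech["id"], tech["name"])

    counts = {"demographics": 0, "authorization": 0, "encounter_note": 0, "test_result": 0}
    for pat in population.patients:
        out = network.client_submit(clients[pat["patientID"]], "submit_record",
                                    {"record_type": "demographics", "payload": pat})
        assert out.status == "committed", out
        counts["demographics"] += 1
    for grant in population.grants:
        out = network.client_submit(clients[grant.grantor], "grant_authorization",
                                    {"grantee": grant.grantee, "patient": grant.patient,
                                     "permissions": grant.permissions})
        assert out.status == "committed", out
        counts["authorization"] += 1
    for enc in population.encounters:
        out = network.client_submit(clients[enc["doctorID"]], "submit_record",
                                    {"record_type": "encounter_note", "payload": enc})
        assert out.status == "committed", out
        counts["encounter_note"] += 1
    for tr in population.test_results:
        out = network.client_submit(clients[tr["technicianID"]], "submit_record",
                                    {"record_type": "test_result", "payload": tr})
        assert out.status == "committed", out
        counts["test_result"] += 1
    return counts


def commit_random_traffic(network, n_txs: int, seed: int) -> int:
    """Commit exactly ``n_txs`` further random transactions to a network.

    A synthetic population is committed first (demographics, grants,
    encounters, lab results); the remainder are random demographic
    updates by the population's own patients.  Returns the number of
    transactions committed (== ``n_txs``).
    """
    rng = random.Random(seed)
    pop = generate_population(max(2, n_txs // 5), max(1, n_txs // 25), 1, seed)
    counts = seed_network(network, pop)
    done = sum(counts.values())
    if done > n_txs:
        raise ValueError(f"population produced {done} > {n_txs} transactions")
    pids = [p["patientID"] for p in pop.patients]
    while done < n_txs:
        pid = rng.choice(pids)
        out = network.client_submit(network.clients[pid], "submit_record", {
            "record_type": "demographics",
            "key": f"{pid}~demographics~0001",
            "payload": {"patientID": pid, "patientName": f"Update {rng.random():.6f}"},
        })
        assert out.status == "committed"
        done += 1
    return done


# --- security drills ------------------------------------------------------


def availability_drill(network) -> dict:
    """Query a downed peer, then fail over to peer A.

    Requires the worked scenario (or equivalent P01 data) on the ledger.
    Peer E is taken down; the patient's encounter-note query against it
    fails with an availability error, while the same query against peer
    A succeeds.  Peer E is then restored and catches up.
    """
    fx = demo_payloads()
    steve = network.enroll_user("patient", fx.patient_id, "Steve Apple")
    network.set_peer_available("E", False)
    failed = False
    try:
        network.client_query(steve, "query_records",
                             {"patient": fx.patient_id, "record_type": "encounter_note"},
                             target="E")
    except PeerUnavailableError:
        failed = True
    retry = network.client_query(steve, "query_records",
                                 {"patient": fx.patient_id, "record_type": "encounter_note"},
                                 target="A")
    network.set_peer_available("E", True)
    caught_up = network.peers["E"].ledger_bytes() == network.peers["A"].ledger_bytes()
    return {
        "unavailable_peer_failed": failed,
        "retry_on_A_succeeded": retry.status == "ok" and len(retry.records) >= 1,
        "peer_E_caught_up": caught_up,
    }


def revoked_identity_drill(network) -> dict:
    """Delete (revoke) Steve Apple's certificate and watch him be refused."""
    fx = demo_payloads()
    steve = network.enroll_user("patient", fx.patient_id, "Steve Apple")
    network.msp.revoke(steve.identity.certificate.serial)
    out = network.client_query(steve, "query_records",
                               {"patient": fx.patient_id, "record_type": "encounter_note"},
                               target="A")
    return {
        "denied": out.status == "denied",
        "failed_check": out.decision.get("failed_check") if out.decision else None,
    }


def history_drill(network) -> dict:
    """A legitimate correction leaves both versions in the key's history.

    The doctor re-submits the P01 encounter note under its existing key
    with the physical examination changed from "no acute distress" to
    "acute distress"; the per-key history query returns both versions in
    chain order.
    """
    fx = demo_payloads()
    carl = network.enroll_user("doctor", fx.doctor_id, "Carl Savem")
    key = f"{fx.patient_id}~encounter_note~0001"
    out = network.client_submit(carl, "submit_record", {
        "record_type": "encounter_note",
        "payload": fx.encounter_note_update,
        "key": key,
    })
    hist = network.client_query(carl, "query_history", {"key": key})
    values = [h["value"]["payload"]["physicalExamination"] for h in hist.records]
    return {
        "update_committed": out.status == "committed",
        "history_values": values,
        "shows_change": values == ["no acute distress", "acute distress"],
    }
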