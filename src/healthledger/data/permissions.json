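{
  "doctor": ["submit_record", "query_records", "query_history", "grant_authorization"],
  "nurse": ["submit_record", "query_records", "query_history", "grant_authorization"],
  "lab_technician": ["submit_record", "query_records", "query_history", "grant_authorization"],
  "emergency_staff": ["submit_record", "query_records", "query_history", "grant_authorization"],
  "patient": ["submit_record", "query_records", "query_history", "grant_authorization"],
  "family_member": ["submit_record", "query_records", "query_history"],
  "auditor": ["query_records", "query_history"],
  "regulator": ["query_records", "query_history"],
  "researcher": ["query_anonymized"]
}
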