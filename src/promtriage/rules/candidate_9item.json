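{
  "name": "candidate_9item",
  "policy": "ANY_CROSSED",
  "unallocatable_default": "HOSPITAL",
  "criteria": [
    {"instrument": "NRS_REST", "item": 0, "comparator": ">=", "cutoff": 4, "group": "PAIN"},
    {"instrument": "NRS_ACTIVITY", "item": 0, "comparator": ">=", "cutoff": 4, "group": "PAIN"},
    {"instrument": "EQ5D3L", "item": 4, "comparator": ">=", "cutoff": 3, "group": "PAIN"},
    {"instrument": "OHS", "item": 1, "comparator": "<=", "cutoff": 1, "group": "PAIN"},
    {"instrument": "OHS", "item": 8, "comparator": "<=", "cutoff": 2, "group": "PAIN"},
    {"instrument": "OHS", "item": 10, "comparator": "<=", "cutoff": 1, "group": "PAIN"},
    {"instrument": "OHS", "item": 12, "comparator": "<=", "cutoff": 2, "group": "PAIN"},
    {"instrument": "EQ5D3L", "item": 1, "comparator": ">=", "cutoff": 3, "group": "CRUTCHES"},
    {"instrument": "OHS", "item": 6, "comparator": "<=", "cutoff": 2, "group": "CRUTCHES"}
  ]
}
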