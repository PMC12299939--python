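{"name": "hbv_conditions", "domain": "condition", "concept_ids": [1101, 1102]}
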