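{"name": "hiv_conditions", "domain": "condition", "concept_ids": [1001, 1002, 1003]}
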