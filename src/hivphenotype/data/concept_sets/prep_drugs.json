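{"name": "prep_drugs", "domain": "drug", "concept_ids": [3001, 3002]}
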