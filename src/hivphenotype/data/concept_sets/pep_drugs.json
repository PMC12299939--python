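{"name": "pep_drugs", "domain": "drug", "concept_ids": [3101, 3102]}
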