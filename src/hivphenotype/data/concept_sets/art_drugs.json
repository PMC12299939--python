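{"name": "art_drugs", "domain": "drug", "concept_ids": [3101, 3102, 3201, 3202, 3203]}
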