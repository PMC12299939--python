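{"name": "hiv_qualitative_tests", "domain": "measurement", "concept_ids": [2001, 2002]}
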