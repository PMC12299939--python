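{"name": "hiv_viral_load", "domain": "measurement", "concept_ids": [2101, 2102]}
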