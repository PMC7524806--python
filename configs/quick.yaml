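# Desk-scale tier: sizes used by the test suite and acceptance script.
tier: quick
overrides: {}
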