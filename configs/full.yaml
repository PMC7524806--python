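# Full-scale tier: population sizes and averaging windows for a complete
# reproduction (cluster-comfortable; not needed for the tests).
tier: full
overrides:
  db_count: 635
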