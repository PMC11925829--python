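# Condition CP111 (experiment 2): red = VI 10 s on the left, blue = VI 60 s on the right.
# All other parameters take their defaults; see docs/config_schema.md.
condition: CP111
experiment: 2
seed: 0
agent:
  type: rate_learning
  params: {}
  seed: 1
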