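# Condition GP402 (experiment 1): blue = VI 10 s on the right, red = VI 60 s on the left.
# All other parameters take their defaults; see docs/config_schema.md.
condition: GP402
experiment: 1
seed: 0
agent:
  type: rule_following
  params:
    compliance: 1.0
  seed: 1
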