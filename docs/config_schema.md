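# Session configuration schema

A session configuration is a YAML mapping validated against
`rulechoice.SessionConfig`. Unknown or out-of-range keys raise a schema
error that lists the offending keys. One example file per counterbalancing
row ships in `examples/`.

```yaml
# examples/gp101.yaml
condition: GP101          # counterbalancing row id (required)
experiment: 1             # 1 = with rules + rule test; 2 = no rules
seed: 0                   # engine seed (schedules, orders, placements)
agent:
  type: rule_following    # rule_following | rate_learning | always_respond
  params: {compliance: 1.0}
  seed: 1                 # agent seed (response times, choices)
```

## Keys

| key | type / default | meaning |
|---|---|---|
| `condition` | str, required | One of the 16 condition ids (`GP101`..`GP402`, `CP111`..`CP412`); fixes stimulus colors, VI sides and VI means. |
| `participant_id` | str, default = `condition` | Label used in output paths. |
| `experiment` | 1 or 2, default 1 | 2 removes the rules and the rule-test phase and lowers the training criterion. |
| `n_blocks` | int, 3 | Training blocks. |
| `cycles_per_block` | int, 6 | Cycles per block; each cycle presents both components once in random order. |
| `component_duration_s` | float, 60 | Observation-period length. |
| `ici_s` | float, 10 | Inter-component interval. |
| `rest_s` | float, 30 | Rest between blocks. |
| `cod_s` | float, 3 | Changeover delay. |
| `criterion_pct` | float or null | Training advancement criterion on the pooled last six observation periods of each component; null selects 95 (experiment 1) or 80 (experiment 2). |
| `n_forced_ext_lean` | int, 6 | Lean components run as concurrent EXT-EXT, placed uniformly at random among the 18 Lean presentations. |
| `choice_test_cycles` | int, 2 | Cycles of the four-component choice test. |
| `vi_list_length` | int, 20 | Intervals per Fleshler-Hoffman list. |
| `bs_alternation_ms` | int, 400 | Color alternation period in the both-stimuli component. |
| `reinforce_post_cod_unconditionally` | bool, false | Literal post-changeover reading: first response to the switched-to VI side after the COD is reinforced even if unarmed. |
| `point_value` | float, 0.7 | Currency units credited per reinforcer (logged in the manifest). |
| `seed` | int, 0 | Engine RNG seed; recorded in the event-log header. |
| `agent.type` | str, required | `rule_following`, `rate_learning` or `always_respond`. |
| `agent.params` | mapping, `{}` | Keyword arguments of the agent class (see `rulechoice.agents`). The engine injects `rule_map`/`rich_color` for rule agents from the condition row unless overridden. |
| `agent.seed` | int or null | Agent RNG seed; null derives `seed + 1`. |

## Event-log format

`events.csv` starts with `#`-prefixed `key = JSON` header lines (full config
echo, seeds, instructed-side mapping), then CSV columns
`t_s,phase,block,cycle,component_index,component_label,event,payload`.
Timestamps have 3 decimal places (lossless at the engine's 10 ms grid);
`payload` is a JSON object. Event types: `component_on/off`,
`response_left/right` (payload `outcome`: `recorded`, `reinforced`, or
`cod_triggered`), `reinforcer_left/right` (payload `armed_at_s`),
`cod_on/off`, `rest_on/off` (payload `kind`: `ici` or `block_rest`),
`sentence_shown`, `sentence_answered`.
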