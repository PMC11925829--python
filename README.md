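# rulechoice

A programmable operant-conditioning task engine for studying **rule-governed
choice** on concurrent schedules, with simulated agents in place of human
participants.

The procedure it implements is a free-operant choice task from the
experimental analysis of human behaviour: two response alternatives
(left/right buttons) are governed by concurrent **variable-interval (VI) /
extinction (EXT)** schedules inside a two-component multiple schedule. Each
component is signalled by a discriminative stimulus (red or blue circle)
and pairs a rich (VI 10 s) or lean (VI 60 s) alternative with extinction; a
3 s **changeover delay (COD)** discourages rapid alternation. After
training — with explicit performance rules ("when the circle is red, press
the left chest", experiment 1) or without them (experiment 2) — choice is
probed by presenting **both** stimuli at once (BS, alternating every
400 ms) or **no** stimulus (NS), under extinction. The question: when two
trained (or instructed) relations conflict, does the one associated with
the higher reinforcer rate win?

The package provides:

* `rulechoice.schedules` — Fleshler-Hoffman constant-probability VI interval
  lists, VI/EXT state machines, and the concurrent-pair-with-COD contract
  (10 ms discrete-time engine);
* `rulechoice.session` — the full session: training (3 blocks × 6 cycles,
  140 s cycles, 6 of 18 lean components non-reinforced, last-six-period
  stability criterion), the rule test (exact-match fill-in sentences), and
  the four-component choice test;
* `rulechoice.agents` — synthetic participants: a rule-following agent, a
  rate-learning agent (softmax over exponentially weighted
  reinforcers-per-response estimates), and an always-respond calibration
  probe;
* `rulechoice.analysis` — per-period response-allocation percentages,
  stability checks, pooled choice-test percentages, and the two-tailed
  **Fisher-Pitman exact permutation test for related samples**
  (statistic T = Σdᵢ = n·M_dif; exact p by full enumeration of the 2ⁿ sign
  assignments up to n = 20, Monte-Carlo above);
* `rulechoice.io` / a `rulechoice` CLI — YAML configs (schema in
  `docs/config_schema.md`, one example per counterbalancing row in
  `examples/`), self-describing CSV event logs, SHA-256 run manifests.

See `docs/methods.md` for the model, parameters, and design choices.

## Worked example

Run one experiment-1 session (condition GP101: red = VI 10 s on the left,
blue = VI 60 s on the right) with a fully compliant rule-following agent:

```
$ rulechoice run examples/gp101.yaml -o out/gp101
manifest: out/gp101/manifest.json
```

The event log, per-period percentages, choice-test report and manifest land
in `out/gp101/`. In Python:

```python
>>> from rulechoice import io, analysis
>>> log = io.read_event_log("out/gp101/events.csv")
>>> analysis.percent_instructed_series(log, "Lean").tail(6)
observation_period
13    100.0
...
18    100.0
>>> print(analysis.choice_test_report(log).to_string(index=False))
component alternative_1      pct_1 alternative_2     pct_2  n_responses
     Rich    instructed 100.000000  uninstructed  0.000000          125
     Lean    instructed 100.000000  uninstructed  0.000000          118
       BS          rich  64.444444          lean 35.555556           45
       NS          rich  50.000000          lean 50.000000           48
```

Reading: the agent allocated 100% of its training-phase responses to the
instructed alternative in the last six observation periods of both
components (so it passed the 95% criterion), kept exclusive instructed
responding in the signalled test components, favoured the richer rule's
side under both stimuli (64%), and sat at indifference with no stimulus.

Calibrate the programmed reinforcer rates with a dense probe:

```
$ rulechoice calibrate --vi-mean 10 --duration 10000 --response-rate 5 --seed 1
VI 10 s: 979 reinforcers in 10000 s = 5.874/min (95% CI 5.506-6.242); 48946 responses
```

— about six reinforcers per minute on the rich schedule versus one on
VI 60 s, the programmed 6:1 ratio.

Group analysis across the eight counterbalanced conditions
(`rulechoice batch examples-dir -o out/`) pools each participant's
choice-test percentages and runs the paired permutation test per
component; with perfect rule followers the Rich-component comparison gives
T = 800, M_dif = 100, exact p = 2/256 ≈ 0.0078 (all eight pairs 100% vs
0%).

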