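# Methods

`rulechoice` simulates a rule-governed-choice procedure: a free-operant task
in which a participant responds on two alternatives (left/right) under a
multiple schedule whose components are concurrent variable-interval (VI) /
extinction (EXT) pairs, signalled by discriminative stimuli (a red or blue
circle). Training establishes stimulus control (with or without verbal
rules); probe components then present both stimuli at once (BS) or none
(NS), under extinction, to ask which trained relation controls choice.
Human participants are replaced by simulated agents, so the entire
procedure, its event logs, and its statistics run end to end with no human
data.

## Schedule model

**Interval generation.** Each VI schedule uses a 20-interval
constant-probability list computed from the Fleshler-Hoffman progression

t_k = T·[1 + ln n + (n−k)·ln(n−k) − (n−k+1)·ln(n−k+1)],  k = 1..n, 0·ln 0 ≡ 0,

with T the programmed mean and n the list length. These t_k are the
conditional means of Exp(T) within n equal-probability slices, so the list
sum telescopes to n·T exactly (the arithmetic-mean invariant is checked to
1e-9 relative tolerance) and uniform draws approximate an exponential
inter-setup distribution: a VI built this way has an approximately constant
reinforcer-setup hazard. Draws are uniform without replacement; a fresh
list is generated at every component onset, and a free-running schedule
regenerates on exhaustion. An armed but uncollected reinforcer is discarded
at component end; nothing carries over.

**Arming and collection.** A VI counts down its current interval in real
time, arms when it elapses, and stays armed until a response to that side
collects the reinforcer, which draws the next interval. EXT never arms and
never delivers.

**Changeover delay (COD).** Switching sides starts a 3 s COD during which
the operanda are withdrawn: responses are blocked entirely (dropped, not
queued). The changeover press itself counts toward neither schedule, and
the first press of a component can never trigger a COD. After a COD, a
press on the pre-changeover side is a changeover again. Reinforcement of
the first post-COD press on the switched-to side follows standard COD
semantics — delivered only if that VI is armed; unconditional delivery
would contradict the programmed VI rates. A configuration flag
(`reinforce_post_cod_unconditionally`) exposes the literal
always-reinforce reading for sensitivity analyses; it never applies to an
EXT side. A structural consequence, audited on every log: no reinforcer is
ever delivered within 3 s of a changeover.

**Time model.** Fixed-grid discrete time at 10 ms resolution. Every
duration in the procedure (60 s components, 10 s inter-component
intervals, 30 s block rests, 3 s COD, 400 ms BS alternation, 235 ms flash)
is an integer number of steps, so event times are exact and logs replay
bit-for-bit from the two seeds (engine and agent). The simulation itself is
event-driven between agent decision opportunities, which is equivalent to
stepping because arming depends only on elapsed time.

## Session structure

Training: 3 blocks × 6 cycles; each cycle presents the Rich (conc VI 10 s
EXT) and Lean (conc VI 60 s EXT) components once, in random order, each
60 s and followed by a 10 s inter-component interval — 140 s per cycle —
with 30 s rests between blocks. Exactly 6 of the 18 Lean presentations run
as concurrent EXT-EXT. The source procedure frames these as emergent
(a sampled interval exceeding the 60 s component) while stating a fixed
count; the engine enforces the printed count deterministically by drawing
6 of the 18 Lean indices uniformly without replacement. Advancement
requires the pooled percentage of responses to the instructed/VI
alternative over the last six observation periods of each component to
reach the criterion (95% with rules, 80% without). The criterion is pooled
over responses, not averaged over period percentages, so sparse periods are
weighted by their behaviour; `stability_check` therefore operates on
per-period counts (a percentage series is accepted as a convenience with
unweighted averaging).

Rule test (experiment 1 only): four fill-in sentences — two asking for the
color given a side, two for the side given a color — in random order.
Scoring is an exact match against the lowercase, space-free token; answers
are immutable once validated; 4/4 on the first cycle is required, otherwise
the session terminates.

Choice test: two cycles of {Rich, Lean, BS, NS} in a uniformly random
permutation per cycle. Rich and Lean keep their trained schedules; BS shows
the two colors alternating every 400 ms (initial color random per onset)
and NS shows no stimulus, both under EXT-EXT. The same 10 s
inter-component interval separates components. Per-component percentages
pool the two presentations; for BS/NS the sides are labelled by the rule
that applies to the Rich vs the Lean component in that participant's
condition row.

Counterbalancing: 8 rows per experiment — 4 combinations of (color of the
VI-10 component) × (side of its VI), each assigned to two participants.
The experiment-2 ids reuse the same four combinations in participant order
(the original assignment is not recorded anywhere recoverable).

## Agents

Agents are explicit stand-ins, not models of participants. All emit
decision opportunities at exponential inter-response times (default mean
1 s, snapped up to the grid), giving a few dozen responses per 60 s
component, the order of magnitude seen in free-operant button pressing.

**Rule-following agent** (experiment-1 pattern): responds to the side its
rule map assigns to the current stimulus with probability `compliance`
(default 1 — immediate, exclusive rule following). Under BS it follows the
richer rule with probability `bs_rich_weight`; because whether instructed
humans follow the richer rule exclusively or probabilistically is exactly
the open question the probe addresses, this weight is a free parameter:
1.0 encodes exclusive richer-rule control, 0.5 indifference, and the
default 0.7 a majority preference. Under NS it responds left with
probability `bias` (default 0.5). Its rule-test answers derive from its own
rule map with probability `rule_recall` (default 1); lower values exercise
the failure path.

**Rate-learning agent** (experiment-2 pattern): keeps an exponentially
weighted average Q(stimulus, side) of reinforcers obtained per response
(update Q ← Q + α(r − Q) on every emitted response, r ∈ {0, 1}) and
chooses by a logistic softmax on [Q(ctx, left) − Q(ctx, right)] / τ.
Defaults α = 0.01 and τ = 0.005 were fixed by a pre-release simulation
study over seeds: with them the asymptotic Lean-side estimate
(≈ 1 reinforcer per ≈ 50 responses ⇒ Q ≈ 0.02) clears the 80% criterion
(needs Q/τ ≥ ln 4), while α is small enough that a forced-EXT Lean
component does not collapse the estimate. Under BS the agent evaluates
each side by its best estimate under either color (rapid 400 ms
alternation is treated as seeing both stimuli); under NS it uses a separate
no-stimulus context with no training history, so NS choice sits at chance.
The learning rule is deliberately pluggable — any mechanism with these
hooks (`choose`, `observe`) can be swapped in.

**Always-respond probe**: presses one side at every opportunity; it is the
calibration instrument for programmed reinforcer rates. Obtained rate is
60/(T + d) per minute where d is the mean collection delay (≈ half an
inter-response time), so calibration runs use a dense 5 Hz probe to make
d negligible (≈ 0.1 s).

## Analysis

The primary dependent variable is the percentage of responses to the
instructed/VI alternative per observation period (100 = instructed
exclusive, 50 = indifference). A period with zero responses is *undefined*
(NaN, flagged with a warning), never 0%: a silent period carries no
allocation information, and 0% would masquerade as exclusive preference
for the other side. (This also resolves the reporting oddity that a probe
component can otherwise show 0% on both alternatives.) Changeover presses
count as emitted responses to the pressed side, although they never count
toward a schedule.

**Fisher-Pitman paired permutation test.** For paired samples with
differences d_i, the statistic is the sum T = Σd_i (reported with the mean
M_dif = T/n, so T = n·M_dif). Under the null of zero mean difference each
|d_i| carries either sign with probability ½; the two-tailed exact p is the
fraction of all 2^n sign assignments with |Σ s_i d_i| ≥ |T|, ties counted
(inclusive, conservative). Exact enumeration is used through n = 20
(2^20 assignments, vectorised); above that a Monte-Carlo estimate with the
observed assignment included in the count, p = (1 + hits)/(1 + B). All-zero
differences give p = 1 degenerately. Undefined percentages propagate as
missing pairs and reduce n with a warning. No multiple-testing correction
is applied; raw p values are reported per comparison. The reference
behaviour is pinned against an independent full-enumeration oracle and
scipy's paired permutation test in the test suite.

## Problem sizes and numerical choices

Default sessions are the study's own sizes (36 training + 8 test
components, ≈ 46 min of simulated time, ≈ 3,000 events) and run in tens of
milliseconds, so the test suite exercises 1,000 fully randomised sessions
for the COD-safety audit and 10-seed ensembles for the learning criterion.
Calibration probes use 10,000 s of simulated time; distributional checks
(uniformity of first draws, closeness of the draw stream to an exponential)
use 10,000 samples, where the Kolmogorov-Smirnov distance to Exp(T) is
expected around 1/(2·20) from list discreteness alone, hence the 0.05-0.08
acceptance bands. Timer comparisons use a 1e-9 tolerance on times rounded
to 1 µs; ties in the permutation null use a relative 1e-12 guard so exact
p values are unaffected by floating-point summation order.

## Known limitations

* Agents are not fitted to, and make no claims about, human data; pass/fail
  of the simulated criteria says nothing about which explanation of
  instructed choice-test behaviour (rule choice vs direct contingency
  control) is correct — both are expressible as agent configurations.
* The generator emulates programmed contingencies and schedule structure,
  not human response topography: no warm-up drift, no post-reinforcement
  pausing, no session fatigue, and exponential inter-response times with a
  constant rate. Passing tests validate the engine and analysis stack, not
  behavioural realism.
* Group statistics printed for the original eight-participant experiments
  that depend on unpublished raw counts (e.g. the BS-component statistics)
  cannot be recomputed and are out of scope; only structural/designed
  quantities and the worked exclusive-preference statistic are reproduced.
* Stimulus rendering (flash, colors, layout) is carried as logged metadata
  only; nothing is drawn.
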