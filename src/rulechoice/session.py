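"""Session orchestration: training, rule test and choice test.

Runs a full experimental session for one simulated participant:

* **training** -- three blocks of six cycles of a two-component multiple
  schedule (Rich: conc VI 10 s EXT; Lean: conc VI 60 s EXT), 60 s
  components separated by 10 s inter-component intervals (140 s per cycle),
  30 s rests between blocks, a fixed number of Lean components run as conc
  EXT EXT, and a stability criterion on the last six observation periods of
  each component;
* **rule test** (experiment 1 only) -- four fill-in sentences probing verbal
  recall of the two rules, exact lowercase space-free matching, pass only
  with 4/4 correct on the first cycle;
* **choice test** -- two cycles of a four-component multiple schedule
  adding a both-stimuli (BS) component with the discriminative colors
  alternating every 400 ms and a no-stimulus (NS) component, both under
  conc EXT EXT.

All randomness funnels through two seeded generators: the engine generator
(component orders, interval draws, forced-extinction placement, BS initial
color, sentence order) and the agent's own generator, so a session replays
bit-for-bit from its seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from . import analysis
from .agents import (
    Agent,
    AlwaysRespondProbe,
    DecisionContext,
    RateLearningAgent,
    RuleFollowingAgent,
)
from .errors import ConfigError, PhaseNotApplicableError
from .events import Event, EventLog
from .schedules import (
    ConcurrentPair,
    Outcome,
    ScheduleKind,
    ScheduleState,
    quantize,
)

FLASH_MS = 235  # discriminative-stimulus flash period, logged as metadata only


# ---------------------------------------------------------------------------
# Declarative component / condition descriptions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScheduleSpec:
    kind: ScheduleKind
    mean_s: float | None = None  # VI only

    def __str__(self) -> str:
        return f"VI-{self.mean_s:g} s" if self.kind is ScheduleKind.VI else "EXT"

    @classmethod
    def vi(cls, mean_s: float) -> "ScheduleSpec":
        return cls(ScheduleKind.VI, float(mean_s))

    @classmethod
    def ext(cls) -> "ScheduleSpec":
        return cls(ScheduleKind.EXT)


@dataclass(frozen=True)
class ComponentSpec:
    """One component of the multiple schedule.

    Rich and Lean carry exactly one VI and one EXT side and a steady color;
    BS alternates both colors and NS shows none, both with EXT on both
    sides.
    """

    label: Literal["Rich", "Lean", "BS", "NS"]
    stimulus: Literal["red", "blue", "alternating", "none"]
    left: ScheduleSpec
    right: ScheduleSpec
    duration_s: float = 60.0
    alternation_period_ms: int | None = None  # BS only
    forced_ext: bool = False  # Lean only: run as conc EXT EXT

    def __post_init__(self):
        kinds = {self.left.kind, self.right.kind}
        if self.label in ("Rich", "Lean") and not self.forced_ext:
            if kinds != {ScheduleKind.VI, ScheduleKind.EXT}:
                raise ConfigError(
                    f"{self.label} component needs one VI and one EXT side"
                )
        if self.label in ("BS", "NS") and kinds != {ScheduleKind.EXT}:
            raise ConfigError(f"{self.label} component must be EXT on both sides")

    @property
    def vi_side(self) -> str | None:
        if self.left.kind is ScheduleKind.VI:
            return "left"
        if self.right.kind is ScheduleKind.VI:
            return "right"
        return None


@dataclass(frozen=True)
class ConditionRow:
    """One counterbalancing row: stimulus colors x VI sides x VI means, plus
    the two rules (experiment 1)."""

    participant_id: str
    experiment: int
    rich: ComponentSpec
    lean: ComponentSpec

    @property
    def rich_color(self) -> str:
        return self.rich.stimulus

    @property
    def lean_color(self) -> str:
        return self.lean.stimulus

    @property
    def rich_side(self) -> str:
        return self.rich.vi_side

    @property
    def lean_side(self) -> str:
        return self.lean.vi_side

    @property
    def rule_map(self) -> dict[str, str]:
        """color -> instructed side (the VI side under that color)."""
        return {self.rich_color: self.rich_side, self.lean_color: self.lean_side}

    def rules_text(self) -> list[str]:
        return [
            f"When the circle is {c}, press the {s} chest."
            for c, s in self.rule_map.items()
        ]


def _component(label, color, vi_mean, vi_side) -> ComponentSpec:
    vi, ext = ScheduleSpec.vi(vi_mean), ScheduleSpec.ext()
    left, right = (vi, ext) if vi_side == "left" else (ext, vi)
    return ComponentSpec(label=label, stimulus=color, left=left, right=right)


# The four counterbalanced combinations of (color of the VI-10 component) x
# (side of the VI), each used by two participants per experiment.
_BASE_COMBOS = [
    # (rich color, rich VI side, lean color, lean VI side)
    ("red", "left", "blue", "right"),
    ("blue", "left", "red", "right"),
    ("red", "right", "blue", "left"),
    ("blue", "right", "red", "left"),
]

_IDS = {1: ["GP101", "GP201", "GP301", "GP401", "GP102", "GP202", "GP302", "GP402"],
        2: ["CP111", "CP211", "CP311", "CP411", "CP112", "CP212", "CP312", "CP412"]}


def build_condition_table(
    experiment: int = 1, rich_mean_s: float = 10.0, lean_mean_s: float = 60.0
) -> list[ConditionRow]:
    """The 8 counterbalanced condition rows for one experiment.

    Four combinations of stimulus color and VI side for the richer (VI 10 s)
    component, crossed with the complementary assignment for the leaner
    (VI 60 s) component, each combination assigned to two participants.
    """
    if experiment not in _IDS:
        raise ConfigError(f"experiment must be 1 or 2, got {experiment!r}")
    rows = []
    for i, pid in enumerate(_IDS[experiment]):
        rich_color, rich_side, lean_color, lean_side = _BASE_COMBOS[i % 4]
        rows.append(
            ConditionRow(
                participant_id=pid,
                experiment=experiment,
                rich=_component("Rich", rich_color, rich_mean_s, rich_side),
                lean=_component("Lean", lean_color, lean_mean_s, lean_side),
            )
        )
    return rows


def condition_by_id(condition_id: str) -> ConditionRow:
    for exp in (1, 2):
        for row in build_condition_table(exp):
            if row.participant_id == condition_id:
                return row
    raise ConfigError(f"unknown condition id {condition_id!r}", keys=["condition"])


# ---------------------------------------------------------------------------
# Session configuration
# ---------------------------------------------------------------------------


class AgentSpec(BaseModel):
    """Agent type + parameters + RNG seed, as stored in the config file."""

    type: Literal["rule_following", "rate_learning", "always_respond"]
    params: dict[str, Any] = Field(default_factory=dict)
    seed: Optional[int] = None


class SessionConfig(BaseModel):
    """Full declarative description of one session."""

    condition: str
    participant_id: Optional[str] = None
    experiment: Literal[1, 2] = 1
    n_blocks: int = 3
    cycles_per_block: int = 6
    component_duration_s: float = 60.0
    ici_s: float = 10.0
    rest_s: float = 30.0
    cod_s: float = 3.0
    criterion_pct: Optional[float] = None  # default 95 (exp 1) / 80 (exp 2)
    n_forced_ext_lean: int = 6
    choice_test_cycles: int = 2
    vi_list_length: int = 20
    bs_alternation_ms: int = 400
    reinforce_post_cod_unconditionally: bool = False
    point_value: float = 0.7  # currency units credited per reinforcer
    seed: int = 0
    agent: AgentSpec = Field(default_factory=lambda: AgentSpec(type="rule_following"))

    @field_validator("n_blocks", "cycles_per_block", "choice_test_cycles",
                     "vi_list_length")
    @classmethod
    def _positive(cls, v, info):
        if v < 1:
            raise ValueError(f"{info.field_name} must be >= 1")
        return v

    @model_validator(mode="after")
    def _check(self):
        total_lean = self.n_blocks * self.cycles_per_block
        if not 0 <= self.n_forced_ext_lean <= total_lean:
            raise ValueError(
                f"n_forced_ext_lean must be in [0, {total_lean}] "
                f"(total Lean components in training)"
            )
        if self.participant_id is None:
            object.__setattr__(self, "participant_id", self.condition)
        return self

    @property
    def effective_criterion_pct(self) -> float:
        if self.criterion_pct is not None:
            return self.criterion_pct
        return 95.0 if self.experiment == 1 else 80.0


def make_agent(config: SessionConfig, condition: ConditionRow) -> Agent:
    spec = config.agent
    seed = spec.seed if spec.seed is not None else config.seed + 1
    params = dict(spec.params)
    if spec.type == "rule_following":
        params.setdefault("rule_map", condition.rule_map)
        params.setdefault("rich_color", condition.rich_color)
        return RuleFollowingAgent(seed=seed, **params)
    if spec.type == "rate_learning":
        return RateLearningAgent(seed=seed, **params)
    if spec.type == "always_respond":
        return AlwaysRespondProbe(seed=seed, **params)
    raise ConfigError(f"unknown agent type {spec.type!r}", keys=["agent.type"])


# ---------------------------------------------------------------------------
# Session runner
# ---------------------------------------------------------------------------


@dataclass
class SentenceRecord:
    kind: str  # color_blank | side_blank
    given: str
    expected: str
    answer: str
    correct: bool


@dataclass
class SessionResult:
    log: EventLog
    training_passed: bool
    rule_test_passed: Optional[bool]  # None if phase not run / exp 2
    choice_test_run: bool
    rule_answers: list[SentenceRecord] = field(default_factory=list)
    total_reinforcers: int = 0
    earnings: float = 0.0

    @property
    def completed(self) -> bool:
        return self.choice_test_run


class Session:
    """Runs one participant's session end to end.

    Phase order is fixed: training, then (experiment 1 only) the rule test,
    then the choice test; a phase only runs when its predecessor's criterion
    was met.
    """

    def __init__(self, config: SessionConfig, agent: Agent | None = None):
        self.config = config
        self.condition = condition_by_id(config.condition)
        if self.condition.experiment != config.experiment:
            # condition ids encode the experiment; accept either but keep the
            # configured experiment number authoritative for phase structure
            self.condition = ConditionRow(
                participant_id=self.condition.participant_id,
                experiment=config.experiment,
                rich=self.condition.rich,
                lean=self.condition.lean,
            )
        self.agent = agent if agent is not None else make_agent(config, self.condition)
        self.rng = np.random.default_rng(config.seed)
        self.t = 0.0
        self.total_reinforcers = 0
        meta = {
            "config": config.model_dump(),
            "engine_seed": config.seed,
            "agent_seed": getattr(self.agent, "seed", None),
            "rich_side": self.condition.rich_side,
            "lean_side": self.condition.lean_side,
            "rich_color": self.condition.rich_color,
            "lean_color": self.condition.lean_color,
            "instructed_sides": {
                "Rich": self.condition.rich_side,
                "Lean": self.condition.lean_side,
            },
            "flash_ms": FLASH_MS,
        }
        self.log = EventLog(meta=meta)

    # -- phase drivers ------------------------------------------------------

    def run(self) -> SessionResult:
        training_passed = self.run_training()
        rule_test_passed: Optional[bool] = None
        answers: list[SentenceRecord] = []
        choice_run = False
        if training_passed:
            if self.config.experiment == 1:
                answers, rule_test_passed = self.run_rule_test()
                if rule_test_passed:
                    self.run_choice_test()
                    choice_run = True
            else:
                self.run_choice_test()
                choice_run = True
        earnings = round(self.total_reinforcers * self.config.point_value, 6)
        return SessionResult(
            log=self.log,
            training_passed=training_passed,
            rule_test_passed=rule_test_passed,
            choice_test_run=choice_run,
            rule_answers=answers,
            total_reinforcers=self.total_reinforcers,
            earnings=earnings,
        )

    def run_training(self) -> bool:
        cfg = self.config
        total_lean = cfg.n_blocks * cfg.cycles_per_block
        forced_idx = set(
            self.rng.choice(total_lean, size=cfg.n_forced_ext_lean, replace=False)
        )
        comp_index = 0
        lean_count = 0
        for block in range(1, cfg.n_blocks + 1):
            for cycle in range(1, cfg.cycles_per_block + 1):
                order = [self.condition.rich, self.condition.lean]
                if self.rng.random() < 0.5:
                    order.reverse()
                for spec in order:
                    forced = False
                    if spec.label == "Lean":
                        forced = lean_count in forced_idx
                        lean_count += 1
                    comp_index += 1
                    self._run_component(
                        spec, phase="training", block=block, cycle=cycle,
                        comp_index=comp_index, forced_ext=forced,
                    )
                    self._rest(cfg.ici_s, "ici", block, cycle)
            if block < cfg.n_blocks:
                self._rest(cfg.rest_s, "block_rest", block, 0)
        return analysis.training_criterion(
            self.log, threshold_pct=cfg.effective_criterion_pct
        )

    def run_rule_test(self) -> tuple[list[SentenceRecord], bool]:
        """Four fill-in sentences in random order; exact lowercase space-free
        match required; answers are immutable once validated."""
        if self.config.experiment != 1:
            raise PhaseNotApplicableError("experiment 2 has no rule-test phase")
        rule_map = self.condition.rule_map
        color_of_side = {s: c for c, s in rule_map.items()}
        items = [
            ("side_blank", "red", rule_map["red"]),
            ("side_blank", "blue", rule_map["blue"]),
            ("color_blank", "left", color_of_side["left"]),
            ("color_blank", "right", color_of_side["right"]),
        ]
        order = self.rng.permutation(len(items))
        records = []
        for i in order:
            kind, given, expected = items[int(i)]
            self.log.log(self.t, "rule_test", 0, 1, 0, "", "sentence_shown",
                         kind=kind, given=given)
            raw = self.agent.answer(kind, given)
            # exact-match scoring: the expected token is lowercase with no
            # spaces; any deviation (case, whitespace) is an error
            correct = raw == expected
            records.append(SentenceRecord(kind, given, expected, raw, correct))
            self.log.log(self.t, "rule_test", 0, 1, 0, "", "sentence_answered",
                         kind=kind, given=given, answer=raw, correct=correct)
        passed = all(r.correct for r in records)
        return records, passed

    def run_choice_test(self) -> None:
        cfg = self.config
        bs = ComponentSpec(
            label="BS", stimulus="alternating",
            left=ScheduleSpec.ext(), right=ScheduleSpec.ext(),
            duration_s=cfg.component_duration_s,
            alternation_period_ms=cfg.bs_alternation_ms,
        )
        ns = ComponentSpec(
            label="NS", stimulus="none",
            left=ScheduleSpec.ext(), right=ScheduleSpec.ext(),
            duration_s=cfg.component_duration_s,
        )
        components = [self.condition.rich, self.condition.lean, bs, ns]
        comp_index = 0
        for cycle in range(1, cfg.choice_test_cycles + 1):
            for i in self.rng.permutation(4):
                comp_index += 1
                self._run_component(
                    components[int(i)], phase="choice_test", block=0,
                    cycle=cycle, comp_index=comp_index,
                )
                self._rest(cfg.ici_s, "ici", 0, cycle)

    # -- component engine ---------------------------------------------------

    def _make_schedule(self, spec: ScheduleSpec) -> ScheduleState:
        if spec.kind is ScheduleKind.VI:
            return ScheduleState.vi(
                spec.mean_s, self.rng, n_intervals=self.config.vi_list_length
            )
        return ScheduleState.ext()

    def _run_component(self, spec: ComponentSpec, phase: str, block: int,
                       cycle: int, comp_index: int, forced_ext: bool = False) -> None:
        cfg = self.config
        duration = cfg.component_duration_s
        if forced_ext:
            left, right = ScheduleState.ext(), ScheduleState.ext()
        else:
            left, right = self._make_schedule(spec.left), self._make_schedule(spec.right)
        pair = ConcurrentPair(
            left=left, right=right, rng=self.rng,
            cod_duration_s=cfg.cod_s,
            reinforce_post_cod_unconditionally=cfg.reinforce_post_cod_unconditionally,
        )
        bs_initial = None
        if spec.label == "BS":
            bs_initial = "red" if self.rng.random() < 0.5 else "blue"
        t0 = self.t
        self.log.log(
            t0, phase, block, cycle, comp_index, spec.label, "component_on",
            stimulus=spec.stimulus, duration_s=duration, forced_ext=forced_ext,
            left_schedule=str(spec.left) if not forced_ext else "EXT",
            right_schedule=str(spec.right) if not forced_ext else "EXT",
            flash_ms=FLASH_MS,
            alternation_ms=spec.alternation_period_ms,
            initial_color=bs_initial,
        )
        alt_s = (spec.alternation_period_ms or 0) / 1000.0
        steady = spec.stimulus if spec.stimulus in ("red", "blue") else None
        for t_rel in self.agent.response_times(duration):
            pair.advance_to(t_rel)
            if pair.cod_active:
                # operanda withdrawn: the opportunity passes with no response
                continue
            if spec.label == "BS":
                half = int(t_rel / alt_s)
                displayed = bs_initial if half % 2 == 0 else (
                    "blue" if bs_initial == "red" else "red"
                )
            else:
                displayed = steady
            ctx = DecisionContext(
                phase=phase, label=spec.label, stimulus=steady,
                displayed_color=displayed,
            )
            side = self.agent.choose(ctx)
            outcome = pair.register_response(side)
            t_abs = round(t0 + t_rel, 6)
            self.log.log(t_abs, phase, block, cycle, comp_index, spec.label,
                         f"response_{side}", outcome=outcome.value)
            if outcome is Outcome.REINFORCED:
                self.total_reinforcers += 1
                armed_at = pair.last_armed_at_s
                self.log.log(t_abs, phase, block, cycle, comp_index, spec.label,
                             f"reinforcer_{side}",
                             armed_at_s=round(t0 + armed_at, 6)
                             if not math.isnan(armed_at) else None)
            elif outcome is Outcome.COD_TRIGGERED:
                self.log.log(t_abs, phase, block, cycle, comp_index, spec.label,
                             "cod_on", to=side)
                self.log.log(round(min(t_abs + cfg.cod_s, t0 + duration), 6),
                             phase, block, cycle, comp_index, spec.label, "cod_off")
            self.agent.observe(ctx, side, outcome)
        self.t = round(t0 + duration, 6)
        self.log.log(self.t, phase, block, cycle, comp_index, spec.label,
                     "component_off")

    def _rest(self, duration_s: float, kind: str, block: int, cycle: int) -> None:
        phase = "rest"
        self.log.log(self.t, phase, block, cycle, 0, "", "rest_on",
                     kind=kind, duration_s=duration_s)
        self.t = round(self.t + duration_s, 6)
        self.log.log(self.t, phase, block, cycle, 0, "", "rest_off", kind=kind)


# ---------------------------------------------------------------------------
# Single-schedule calibration probe
# ---------------------------------------------------------------------------


@dataclass
class ProbeResult:
    """Obtained-reinforcement report for a free-running single schedule."""

    mean_s: float | None  # None for EXT
    duration_s: float
    n_responses: int
    n_reinforcers: int
    reinforcer_times_s: list[float]

    @property
    def rate_per_min(self) -> float:
        return 60.0 * self.n_reinforcers / self.duration_s

    @property
    def rate_ci_per_min(self) -> tuple[float, float]:
        """Normal-approximation 95% CI on the obtained reinforcers/min."""
        half = 1.96 * math.sqrt(max(self.n_reinforcers, 1)) * 60.0 / self.duration_s
        return (max(0.0, self.rate_per_min - half), self.rate_per_min + half)

    @property
    def inter_reinforcer_times_s(self) -> np.ndarray:
        return np.diff(np.asarray(self.reinforcer_times_s), prepend=0.0)


def run_probe(
    mean_s: float | None,
    duration_s: float,
    response_rate_hz: float = 1.0,
    seed: int = 0,
    n_intervals: int = 20,
) -> ProbeResult:
    """Run an always-respond probe on a single free-running VI (or EXT).

    The schedule samples intervals without replacement from a
    Fleshler-Hoffman list that regenerates on exhaustion; the probe responds
    at every decision opportunity, so the obtained reinforcer rate tracks
    the programmed rate (up to the ~half-IRT collection delay).
    """
    from .schedules import quantize_up

    if not duration_s > 0:
        raise ConfigError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    agent_rng = np.random.default_rng(seed + 1)
    if mean_s is None:
        sched = ScheduleState.ext()
    else:
        sched = ScheduleState.vi(mean_s, rng, n_intervals=n_intervals)
    t = 0.0
    n_resp = 0
    reinf_times: list[float] = []
    mean_irt = 1.0 / response_rate_hz
    done = False
    while not done:
        for irt in agent_rng.exponential(mean_irt, size=4096):
            nxt = round(t + quantize_up(irt), 6)
            if nxt >= duration_s:
                done = True
                break
            n_resp += 1
            if sched.kind is ScheduleKind.VI:
                sched.advance(round(nxt - t, 6), nxt)
                if sched.armed:
                    reinf_times.append(nxt)
                    sched.collect(rng)
            t = nxt
    return ProbeResult(
        mean_s=mean_s,
        duration_s=duration_s,
        n_responses=n_resp,
        n_reinforcers=len(reinf_times),
        reinforcer_times_s=reinf_times,
    )
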