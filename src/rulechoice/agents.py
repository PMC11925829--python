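"""Synthetic participants.

Agents generate response streams against the task engine, standing in for
the human participants of the two experiments.  They are explicitly
*stand-ins*: the target behavioural patterns (immediate exclusive rule
following with instructions; gradual preference development without them)
are observed regularities, and none of the mechanisms here is claimed as a
model of human participants.

All agents emit decision opportunities as a Poisson-like process:
inter-response times are exponential with mean ``1 / response_rate_hz``,
snapped up to the 10 ms engine grid.  The default 1 Hz rate produces
per-component response counts of the order seen in free-operant button
pressing (a few dozen responses per 60 s component).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, InvalidParameterError
from .schedules import Outcome, Side, other_side, quantize_up

COLORS = ("red", "blue")
SIDES = ("left", "right")


@dataclass(frozen=True)
class DecisionContext:
    """What the agent can see at one decision opportunity."""

    phase: str  # training | choice_test | probe
    label: str  # Rich | Lean | BS | NS | probe
    stimulus: str | None  # steady discriminative stimulus color, or None
    displayed_color: str | None  # color on screen right now (BS alternation)


class Agent:
    """Base agent: exponential response emission plus a choice policy."""

    def __init__(self, response_rate_hz: float = 1.0, seed: int | None = None):
        if not response_rate_hz > 0:
            raise InvalidParameterError("response_rate_hz must be positive")
        self.response_rate_hz = float(response_rate_hz)
        self.seed = seed
        self.rng = np.random.default_rng(seed)

    def response_times(self, duration_s: float) -> list[float]:
        """Decision-opportunity times within a component, strictly increasing
        on the 10 ms grid."""
        times: list[float] = []
        t = 0.0
        mean_irt = 1.0 / self.response_rate_hz
        while True:
            t = round(t + quantize_up(self.rng.exponential(mean_irt)), 6)
            if t >= duration_s:
                return times
            times.append(t)

    def choose(self, ctx: DecisionContext) -> Side:  # pragma: no cover - abstract
        raise NotImplementedError

    def observe(self, ctx: DecisionContext, side: Side, outcome: Outcome) -> None:
        """Feedback hook; default agents do not learn."""

    def answer(self, kind: str, given: str) -> str:
        """Answer a rule-test sentence; non-verbal agents answer blank."""
        return ""


class RuleFollowingAgent(Agent):
    """Emulates instructed performance: responds to the alternative mapped by
    the rule for the current discriminative stimulus.

    Parameters
    ----------
    rule_map : dict
        ``{color: side}`` mapping stated by the two rules.
    rich_color : str
        The color whose rule is associated with the richer schedule; used
        only when both stimuli are shown at once.
    compliance : float in [0, 1]
        Probability of following the applicable rule on each response.
    bs_rich_weight : float in [0, 1]
        Probability of following the richer rule when both stimuli are
        present.  1.0 emulates exclusive richer-rule control, 0.5
        indifference between the two rules; the default reflects a majority
        preference for the richer rule.
    bias : float in [0, 1]
        Probability of the left alternative when no stimulus is shown.
    rule_recall : float in [0, 1]
        Probability of answering a rule-test sentence correctly; below 1
        exercises the test-failure path.
    """

    def __init__(
        self,
        rule_map: dict[str, str],
        rich_color: str,
        response_rate_hz: float = 1.0,
        compliance: float = 1.0,
        bs_rich_weight: float = 0.7,
        bias: float = 0.5,
        rule_recall: float = 1.0,
        seed: int | None = None,
    ):
        super().__init__(response_rate_hz, seed)
        for name, p in (
            ("compliance", compliance),
            ("bs_rich_weight", bs_rich_weight),
            ("bias", bias),
            ("rule_recall", rule_recall),
        ):
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1], got {p}")
        if set(rule_map) != set(COLORS) or not set(rule_map.values()) <= set(SIDES):
            raise ConfigError(f"rule_map must map {COLORS} onto sides, got {rule_map}")
        if rich_color not in COLORS:
            raise ConfigError(f"rich_color must be one of {COLORS}")
        self.rule_map = dict(rule_map)
        self.rich_color = rich_color
        self.compliance = compliance
        self.bs_rich_weight = bs_rich_weight
        self.bias = bias
        self.rule_recall = rule_recall

    def choose(self, ctx: DecisionContext) -> Side:
        if ctx.label == "BS":
            rich_side = self.rule_map[self.rich_color]
            follow_rich = self.rng.random() < self.bs_rich_weight
            return rich_side if follow_rich else other_side(rich_side)
        if ctx.stimulus is None:  # NS or unsignalled context
            return "left" if self.rng.random() < self.bias else "right"
        if ctx.stimulus not in self.rule_map:
            raise ConfigError(f"no rule for stimulus {ctx.stimulus!r}")
        instructed = self.rule_map[ctx.stimulus]
        follow = self.rng.random() < self.compliance
        return instructed if follow else other_side(instructed)

    def answer(self, kind: str, given: str) -> str:
        if kind == "side_blank":  # given a color, name the side
            correct = self.rule_map[given]
        elif kind == "color_blank":  # given a side, name the color
            correct = next(c for c, s in self.rule_map.items() if s == given)
        else:
            raise ConfigError(f"unknown sentence kind {kind!r}")
        if self.rng.random() < self.rule_recall:
            return correct
        # a recall failure: the other token of the same category
        wrong = other_side(correct) if correct in SIDES else (
            COLORS[1] if correct == COLORS[0] else COLORS[0]
        )
        return wrong


class RateLearningAgent(Agent):
    """Develops a preference from obtained reinforcement, with no rules.

    Maintains an exponentially weighted average ``Q(stimulus, side)`` of
    reinforcers obtained per response (a melioration-flavoured local
    reinforcement-rate estimate) and chooses between sides by a softmax over
    the estimates for the current stimulus context.  When both stimuli are
    shown at once the agent evaluates each side by the best estimate it has
    for that side under either stimulus; with no stimulus it uses a separate
    no-stimulus context that never acquires training history, so choice
    starts (and stays, under extinction) near indifference.

    Defaults were fixed by a pre-release simulation study over seeds under
    the standard training conditions (see the package methods note).
    """

    def __init__(
        self,
        response_rate_hz: float = 1.0,
        learning_rate: float = 0.01,
        choice_temperature: float = 0.005,
        seed: int | None = None,
    ):
        super().__init__(response_rate_hz, seed)
        if not 0.0 < learning_rate <= 1.0:
            raise InvalidParameterError("learning_rate must be in (0, 1]")
        if not choice_temperature > 0:
            raise InvalidParameterError("choice_temperature must be positive")
        self.learning_rate = learning_rate
        self.choice_temperature = choice_temperature
        self.q: dict[tuple[str, str], float] = {}

    def _context_key(self, ctx: DecisionContext) -> str:
        if ctx.label == "BS":
            return ctx.displayed_color or COLORS[0]
        return ctx.stimulus if ctx.stimulus is not None else "none"

    def _value(self, ctx: DecisionContext, side: Side) -> float:
        if ctx.label == "BS":
            return max(self.q.get((c, side), 0.0) for c in COLORS)
        return self.q.get((self._context_key(ctx), side), 0.0)

    def choose(self, ctx: DecisionContext) -> Side:
        dv = (self._value(ctx, "left") - self._value(ctx, "right")) / self.choice_temperature
        p_left = 1.0 / (1.0 + np.exp(-dv))
        return "left" if self.rng.random() < p_left else "right"

    def observe(self, ctx: DecisionContext, side: Side, outcome: Outcome) -> None:
        if outcome is Outcome.BLOCKED:
            return
        r = 1.0 if outcome is Outcome.REINFORCED else 0.0
        key = (self._context_key(ctx), side)
        q = self.q.get(key, 0.0)
        self.q[key] = q + self.learning_rate * (r - q)


class AlwaysRespondProbe(Agent):
    """Calibration probe: responds to one side at every opportunity."""

    def __init__(self, side: Side = "left", response_rate_hz: float = 1.0,
                 seed: int | None = None):
        super().__init__(response_rate_hz, seed)
        if side not in SIDES:
            raise InvalidParameterError(f"side must be left/right, got {side!r}")
        self.side = side

    def choose(self, ctx: DecisionContext) -> Side:
        return self.side
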