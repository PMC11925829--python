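"""Dependent variables and statistics for event logs.

Computes the response-allocation measures used for concurrent-choice data
(percentage of responses to the instructed / VI alternative per observation
period, pooled choice-test percentages) and the Fisher-Pitman exact
permutation test for paired samples used for the group comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, ProtocolError
from .events import EventLog

#: Responses with these outcomes count as emitted behaviour toward a side.
#: A changeover press is a press (it is counted), even though it never
#: counts toward the schedule; blocked opportunities are never logged.
_RESPONSE_OUTCOMES = {"recorded", "reinforced", "cod_triggered"}


@dataclass(frozen=True)
class ObservationPeriodCounts:
    """Response and reinforcer counts for one component presentation."""

    period_index: int
    component_label: str
    responses_left: int
    responses_right: int
    responses_instructed: int
    reinforcers: int

    @property
    def total_responses(self) -> int:
        return self.responses_left + self.responses_right

    @property
    def percent_instructed(self) -> float:
        """100 x instructed / total; NaN (undefined) for a silent period."""
        if self.total_responses == 0:
            return float("nan")
        return 100.0 * self.responses_instructed / self.total_responses


def _instructed_side(log: EventLog, component_label: str) -> str:
    sides = log.meta.get("instructed_sides", {})
    if component_label not in sides:
        raise InvalidParameterError(
            f"unknown component label {component_label!r}; expected one of "
            f"{sorted(sides) or ['Rich', 'Lean']}"
        )
    return sides[component_label]


def observation_period_counts(
    log: EventLog, component_label: str, phase: str = "training"
) -> list[ObservationPeriodCounts]:
    """Per-presentation counts for one component label within a phase."""
    instructed = _instructed_side(log, component_label)
    events = [
        e for e in log.events
        if e.phase == phase and e.component_label == component_label
    ]
    if not events:
        raise ProtocolError(
            f"log contains no {phase!r} events for component {component_label!r}"
        )
    periods: list[ObservationPeriodCounts] = []
    counts = None
    for e in events:
        if e.event == "component_on":
            counts = {"left": 0, "right": 0, "reinf": 0}
        elif e.event == "component_off":
            periods.append(
                ObservationPeriodCounts(
                    period_index=len(periods) + 1,
                    component_label=component_label,
                    responses_left=counts["left"],
                    responses_right=counts["right"],
                    responses_instructed=counts[instructed],
                    reinforcers=counts["reinf"],
                )
            )
            counts = None
        elif counts is not None:
            if e.event in ("response_left", "response_right"):
                if e.payload.get("outcome") in _RESPONSE_OUTCOMES:
                    counts[e.event.removeprefix("response_")] += 1
            elif e.event in ("reinforcer_left", "reinforcer_right"):
                counts["reinf"] += 1
    return periods


def percent_instructed_series(
    log: EventLog, component_label: str, phase: str = "training"
) -> pd.Series:
    """Percentage of responses to the instructed/VI alternative per
    observation period.

    Periods with zero responses yield NaN (an undefined preference, flagged
    with a warning), never 0%: a silent period carries no allocation
    information and is excluded from averages.
    """
    periods = observation_period_counts(log, component_label, phase)
    vals = [p.percent_instructed for p in periods]
    n_undef = sum(np.isnan(v) for v in vals)
    if n_undef:
        warnings.warn(
            f"{n_undef} observation period(s) of {component_label} had zero "
            "responses; their allocation is undefined (NaN)",
            stacklevel=2,
        )
    return pd.Series(
        vals, index=pd.RangeIndex(1, len(vals) + 1, name="observation_period"),
        name=f"pct_instructed_{component_label}",
    )


def stability_check(
    series: Sequence[ObservationPeriodCounts] | pd.Series,
    last_k: int = 6,
    threshold_pct: float = 95.0,
) -> bool:
    """Stability/advancement criterion for one component.

    Given per-period counts, pools responses over the last ``last_k``
    observation periods and checks that the pooled percentage of responses
    to the instructed alternative is at or above ``threshold_pct`` (the
    criterion is on pooled responses, not on a mean of percentages).  A
    plain percentage series is accepted as a convenience, in which case the
    unweighted mean of the defined values is used.
    """
    if len(series) < last_k:
        raise InvalidParameterError(
            f"need at least {last_k} observation periods, got {len(series)}"
        )
    tail = list(series)[-last_k:] if not isinstance(series, pd.Series) else series.iloc[-last_k:]
    if isinstance(series, pd.Series):
        vals = tail.dropna()
        if vals.empty:
            return False
        return bool(vals.mean() >= threshold_pct)
    total = sum(p.total_responses for p in tail)
    if total == 0:
        return False
    instructed = sum(p.responses_instructed for p in tail)
    return 100.0 * instructed / total >= threshold_pct


def training_criterion(
    log: EventLog, threshold_pct: float, last_k: int = 6
) -> bool:
    """True iff the pooled last-``k``-period allocation meets the threshold
    in BOTH training components."""
    return all(
        stability_check(
            observation_period_counts(log, label, phase="training"),
            last_k=last_k,
            threshold_pct=threshold_pct,
        )
        for label in ("Rich", "Lean")
    )


def pool_choice_test(log: EventLog, component_label: str) -> dict[str, float]:
    """Pooled response percentages for one choice-test component.

    Counts are summed across the component's presentations, then converted
    to percentages.  For Rich/Lean the split is instructed vs uninstructed
    alternative; for BS/NS it is the alternative tied to the Rich rule vs
    the one tied to the Lean rule (per the session's condition row).  A
    component with zero responses overall yields NaN for both percentages.
    """
    if component_label in ("Rich", "Lean"):
        ref_side = _instructed_side(log, component_label)
        keys = ("instructed", "uninstructed")
    elif component_label in ("BS", "NS"):
        ref_side = log.meta["rich_side"]
        keys = ("rich", "lean")
    else:
        raise InvalidParameterError(f"unknown component label {component_label!r}")
    left = right = 0
    for e in log.select(phase="choice_test", component_label=component_label):
        if e.event in ("response_left", "response_right") and \
                e.payload.get("outcome") in _RESPONSE_OUTCOMES:
            if e.event == "response_left":
                left += 1
            else:
                right += 1
    total = left + right
    if total == 0:
        return {keys[0]: float("nan"), keys[1]: float("nan"), "n_responses": 0}
    ref = left if ref_side == "left" else right
    return {
        keys[0]: 100.0 * ref / total,
        keys[1]: 100.0 * (total - ref) / total,
        "n_responses": total,
    }


# ---------------------------------------------------------------------------
# Fisher-Pitman paired exact permutation test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedPermutationResult:
    """Result of the paired (sign-flip) permutation test.

    ``T`` is the sum of paired differences and ``M_dif`` their mean, so
    ``T = n_pairs * M_dif``; ``p`` is the two-tailed probability that a
    random sign assignment gives ``|sum| >= |T|``.
    """

    T: float
    M_dif: float
    p: float
    n_pairs: int
    method: str  # "exact" | "monte_carlo"
    n_permutations: int


def fisher_pitman_paired(
    x: Iterable[float],
    y: Iterable[float],
    n_exact_max: int = 20,
    n_permutations: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> PairedPermutationResult:
    """Two-tailed Fisher-Pitman permutation test for related samples.

    The null hypothesis of zero mean difference is tested by the sign-flip
    distribution of the paired differences ``d_i = x_i - y_i``: under the
    null each ``|d_i|`` is equally likely to carry either sign.  For
    ``n <= n_exact_max`` all ``2^n`` assignments are enumerated and

    ``p = #{s in {-1,+1}^n : |sum_i s_i d_i| >= |T|} / 2^n``

    with ties at ``|T|`` counted (inclusive, keeping the test exact and
    conservative).  Above ``n_exact_max`` a Monte-Carlo estimate is used
    with the observed assignment included in the count.  Pairs in which
    either value is undefined (NaN) are dropped with a warning, reducing
    ``n``.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise InvalidParameterError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} pair(s) with undefined values",
            stacklevel=2,
        )
    d = (x - y)[keep]
    n = d.size
    if n < 2:
        raise InvalidParameterError(f"need at least 2 defined pairs, got {n}")
    T = float(d.sum())
    M_dif = T / n
    tol = 1e-12 * max(1.0, float(np.abs(d).sum()))
    if np.allclose(d, 0.0):
        return PairedPermutationResult(T=0.0, M_dif=0.0, p=1.0, n_pairs=n,
                                       method="exact", n_permutations=2 ** n)
    if n <= n_exact_max:
        # enumerate all sign assignments; |sums| is symmetric so signs of d
        # itself do not matter
        m = 2 ** n
        bits = (np.arange(m, dtype=np.uint32)[:, None] >> np.arange(n)) & 1
        signs = bits.astype(np.int8) * 2 - 1
        sums = signs @ d
        p = float(np.count_nonzero(np.abs(sums) >= abs(T) - tol)) / m
        return PairedPermutationResult(T=T, M_dif=M_dif, p=p, n_pairs=n,
                                       method="exact", n_permutations=m)
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    hits = 0
    chunk = 20_000
    remaining = n_permutations
    while remaining > 0:
        k = min(chunk, remaining)
        signs = rng.integers(0, 2, size=(k, n), dtype=np.int8) * 2 - 1
        sums = signs @ d
        hits += int(np.count_nonzero(np.abs(sums) >= abs(T) - tol))
        remaining -= k
    p = (1 + hits) / (1 + n_permutations)
    return PairedPermutationResult(T=T, M_dif=M_dif, p=float(p), n_pairs=n,
                                   method="monte_carlo",
                                   n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# Report assembly (used by the CLI and batch runner)
# ---------------------------------------------------------------------------


def training_report(log: EventLog) -> pd.DataFrame:
    """Tidy per-period table for both training components."""
    frames = []
    for label in ("Rich", "Lean"):
        periods = observation_period_counts(log, label, phase="training")
        frames.append(
            pd.DataFrame(
                {
                    "component": label,
                    "observation_period": [p.period_index for p in periods],
                    "responses_left": [p.responses_left for p in periods],
                    "responses_right": [p.responses_right for p in periods],
                    "responses_instructed": [p.responses_instructed for p in periods],
                    "reinforcers": [p.reinforcers for p in periods],
                    "pct_instructed": [p.percent_instructed for p in periods],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def choice_test_report(log: EventLog) -> pd.DataFrame:
    """Pooled choice-test percentages for all four components of one log."""
    rows = []
    for label in ("Rich", "Lean", "BS", "NS"):
        pooled = pool_choice_test(log, label)
        (k1, v1), (k2, v2) = [(k, v) for k, v in pooled.items() if k != "n_responses"]
        rows.append(
            {
                "component": label,
                "alternative_1": k1,
                "pct_1": v1,
                "alternative_2": k2,
                "pct_2": v2,
                "n_responses": pooled["n_responses"],
            }
        )
    return pd.DataFrame(rows)


def group_comparisons(
    choice_reports: dict[str, pd.DataFrame], rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Paired permutation tests across participants, one per component.

    For each component the two pooled percentages per participant form the
    pair (instructed vs uninstructed for Rich/Lean; Rich-rule vs Lean-rule
    alternative for BS/NS); the test asks whether their mean difference is
    zero across participants.
    """
    rows = []
    for label in ("Rich", "Lean", "BS", "NS"):
        xs, ys = [], []
        for pid, rep in choice_reports.items():
            row = rep[rep["component"] == label].iloc[0]
            xs.append(row["pct_1"])
            ys.append(row["pct_2"])
        res = fisher_pitman_paired(xs, ys, rng=rng)
        rows.append(
            {
                "comparison": label,
                "n": res.n_pairs,
                "T": res.T,
                "M_dif": res.M_dif,
                "p": res.p,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)
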