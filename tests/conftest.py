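"""Shared fixtures and log-auditing helpers."""

from __future__ import annotations

import numpy as np
import pytest

import rulechoice as rc


def make_config(condition="GP101", experiment=1, seed=0, agent_type="rule_following",
                agent_params=None, agent_seed=None, **overrides) -> rc.SessionConfig:
    return rc.SessionConfig(
        condition=condition,
        experiment=experiment,
        seed=seed,
        agent=rc.AgentSpec(type=agent_type, params=agent_params or {},
                           seed=agent_seed if agent_seed is not None else seed + 1),
        **overrides,
    )


@pytest.fixture(scope="session")
def exp1_result():
    """One complete Experiment-1 session with a fully compliant rule agent."""
    return rc.Session(make_config("GP101", seed=11)).run()


@pytest.fixture(scope="session")
def exp2_result():
    """One complete Experiment-2 session with the default learning agent."""
    return rc.Session(
        make_config("CP111", experiment=2, seed=21, agent_type="rate_learning")
    ).run()


def random_config(rng: np.random.Generator) -> rc.SessionConfig:
    """A randomised session configuration for stress/property tests."""
    experiment = int(rng.integers(1, 3))
    table = rc.build_condition_table(experiment)
    condition = table[int(rng.integers(len(table)))].participant_id
    if experiment == 1:
        agent_type = "rule_following"
        params = {
            "compliance": float(rng.uniform(0.5, 1.0)),
            "response_rate_hz": float(rng.uniform(0.5, 2.0)),
            "bs_rich_weight": float(rng.uniform(0.3, 1.0)),
        }
    else:
        agent_type = "rate_learning"
        params = {"response_rate_hz": float(rng.uniform(0.5, 2.0))}
    return make_config(
        condition, experiment=experiment, seed=int(rng.integers(2**31)),
        agent_type=agent_type, agent_params=params,
        agent_seed=int(rng.integers(2**31)),
    )


# ---------------------------------------------------------------------------
# Log audits
# ---------------------------------------------------------------------------


def audit_cod_safety(log: rc.EventLog, cod_s: float = 3.0) -> None:
    """Assert no reinforcer is ever delivered within ``cod_s`` of a
    changeover onto the reinforced side, within any component."""
    last_cod_on = None
    for e in log.events:
        if e.event == "component_on":
            last_cod_on = None
        elif e.event == "cod_on":
            last_cod_on = e
        elif e.event.startswith("reinforcer_"):
            if last_cod_on is not None:
                gap = e.t_s - last_cod_on.t_s
                assert gap >= cod_s - 1e-9, (
                    f"reinforcer at t={e.t_s} only {gap:.3f}s after changeover"
                )


def audit_reinforcer_structure(log: rc.EventLog) -> None:
    """Assert every reinforcer records a prior arming time within the same
    component, and that only VI sides ever deliver."""
    comp_on_t = None
    comp_schedules = {}
    for e in log.events:
        if e.event == "component_on":
            comp_on_t = e.t_s
            comp_schedules = {
                "left": e.payload["left_schedule"],
                "right": e.payload["right_schedule"],
            }
        elif e.event.startswith("reinforcer_"):
            side = e.event.removeprefix("reinforcer_")
            assert comp_schedules[side].startswith("VI"), (
                f"reinforcer on {comp_schedules[side]} side at t={e.t_s}"
            )
            armed_at = e.payload.get("armed_at_s")
            assert armed_at is not None
            assert comp_on_t - 1e-9 <= armed_at <= e.t_s + 1e-9


def audit_ext_silent(log: rc.EventLog) -> None:
    """Assert EXT alternatives and forced-EXT/BS/NS components never deliver."""
    in_ext_component = False
    for e in log.events:
        if e.event == "component_on":
            in_ext_component = (
                e.payload.get("forced_ext")
                or e.component_label in ("BS", "NS")
            )
        elif e.event.startswith("reinforcer_") and in_ext_component:
            raise AssertionError(f"reinforcer in an all-EXT component at t={e.t_s}")
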