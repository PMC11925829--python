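"""Timestamped event log of a simulated session.

Every response, reinforcer, COD, stimulus/rest transition and rule-test
sentence is one row.  The log carries a metadata header (configuration echo,
seeds, the instructed-side mapping needed by the analysis layer) so a log
file is self-describing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .errors import ProtocolError

#: Column order of the tabular representation.
COLUMNS = [
    "t_s",
    "phase",
    "block",
    "cycle",
    "component_index",
    "component_label",
    "event",
    "payload",
]

EVENT_TYPES = {
    "component_on",
    "component_off",
    "response_left",
    "response_right",
    "reinforcer_left",
    "reinforcer_right",
    "cod_on",
    "cod_off",
    "rest_on",
    "rest_off",
    "sentence_shown",
    "sentence_answered",
}


@dataclass(frozen=True)
class Event:
    """One logged event.  ``block``/``cycle``/``component_index`` are 0 when
    not applicable (rest periods, rule-test sentences)."""

    t_s: float
    phase: str
    block: int
    cycle: int
    component_index: int
    component_label: str
    event: str
    payload: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.event not in EVENT_TYPES:
            raise ProtocolError(f"unknown event type {self.event!r}")


@dataclass
class EventLog:
    """A session's metadata header plus its ordered event rows."""

    meta: dict
    events: list[Event] = field(default_factory=list)

    def append(self, event: Event) -> None:
        if self.events and event.t_s < self.events[-1].t_s - 1e-9:
            raise ProtocolError(
                f"event at t={event.t_s} would break timestamp monotonicity "
                f"(last t={self.events[-1].t_s})"
            )
        self.events.append(event)

    def log(self, t_s, phase, block, cycle, component_index, component_label, event, **payload):
        self.append(
            Event(
                t_s=round(t_s, 3),
                phase=phase,
                block=block,
                cycle=cycle,
                component_index=component_index,
                component_label=component_label,
                event=event,
                payload=payload,
            )
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view; payload serialised as a canonical JSON string."""
        rows = [
            (
                round(e.t_s, 3),
                e.phase,
                e.block,
                e.cycle,
                e.component_index,
                e.component_label,
                e.event,
                json.dumps(e.payload, sort_keys=True),
            )
            for e in self.events
        ]
        return pd.DataFrame(rows, columns=COLUMNS)

    def select(self, **where) -> list[Event]:
        """Events matching all given attribute values (e.g. phase='training')."""
        out = self.events
        for key, val in where.items():
            out = [e for e in out if getattr(e, key) == val]
        return out

    def validate(self) -> None:
        """Check structural invariants: monotone timestamps and matched
        component_on/off pairs exactly ``duration_s`` apart."""
        last = -float("inf")
        open_comp: Event | None = None
        for e in self.events:
            if e.t_s < last - 1e-9:
                raise ProtocolError(f"timestamps decrease at t={e.t_s}")
            last = e.t_s
            if e.event == "component_on":
                if open_comp is not None:
                    raise ProtocolError("nested component_on")
                open_comp = e
            elif e.event == "component_off":
                if open_comp is None:
                    raise ProtocolError("component_off without component_on")
                dur = round(e.t_s - open_comp.t_s, 3)
                want = round(float(open_comp.payload.get("duration_s", dur)), 3)
                if abs(dur - want) > 1e-6:
                    raise ProtocolError(
                        f"component span {dur} s != declared duration {want} s"
                    )
                open_comp = None
        if open_comp is not None:
            raise ProtocolError("unterminated component")

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventLog):
            return NotImplemented
        return self.meta == other.meta and self.to_frame().equals(other.to_frame())
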