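"""Behavioural event logs: loading, validation and scoring-window filters.

An event is one timestamped agonistic act between two identified pigs,
recorded as seconds from mixing.  Point behaviours have duration 0; state
behaviours end at ``t_start + duration_s``.  Intervals are half-open,
``[t_start, t_start + duration_s)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .ethogram import Ethogram, default_ethogram

#: default continuous observation window after mixing, seconds (5 h)
OBSERVATION_WINDOW_S = 18_000.0

EVENT_COLUMNS = ["time_s", "actor", "receiver", "behaviour", "kind", "duration_s"]


class EventValidationError(ValueError):
    """An event log row violates the ethogram or the event invariants."""


@dataclass(frozen=True)
class BehaviourEvent:
    """One agonistic act: actor does ``code`` to receiver at ``t_start``."""

    t_start: float
    actor: str
    receiver: Optional[str]
    code: str
    duration_s: float = 0.0

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration_s

    def sort_key(self) -> tuple:
        # ties broken by (t_start, actor, code), lexicographically
        return (self.t_start, self.actor, self.code)


def validate_event(
    event: BehaviourEvent,
    ethogram: Ethogram,
    observation_window_s: float = OBSERVATION_WINDOW_S,
    row: Optional[int] = None,
) -> None:
    where = "" if row is None else f" (row {row})"
    if event.code not in ethogram:
        raise EventValidationError(
            f"unknown behaviour code {event.code!r}{where}; "
            f"known codes: {', '.join(ethogram.codes)}"
        )
    if event.t_start < 0:
        raise EventValidationError(f"negative time {event.t_start}{where}")
    if event.duration_s < 0:
        raise EventValidationError(f"negative duration {event.duration_s}{where}")
    is_point = ethogram.is_point(event.code)
    if is_point and event.duration_s != 0:
        raise EventValidationError(
            f"point behaviour {event.code!r} must have duration 0, "
            f"got {event.duration_s}{where}"
        )
    if not is_point and event.duration_s == 0:
        raise EventValidationError(
            f"state behaviour {event.code!r} must have duration > 0{where}"
        )
    if event.receiver is not None and event.actor == event.receiver:
        raise EventValidationError(f"actor equals receiver ({event.actor!r}){where}")
    if event.t_end > observation_window_s:
        raise EventValidationError(
            f"event ends at {event.t_end} s, beyond the "
            f"{observation_window_s} s observation window{where}"
        )


def sort_events(events: Iterable[BehaviourEvent]) -> list[BehaviourEvent]:
    return sorted(events, key=BehaviourEvent.sort_key)


def load_events(
    path,
    ethogram: Optional[Ethogram] = None,
    observation_window_s: float = OBSERVATION_WINDOW_S,
) -> list[BehaviourEvent]:
    """Read an event CSV, validate every row, and return sorted events.

    Expected columns: ``time_s, actor, receiver, behaviour, kind, duration_s``.
    The ``kind`` column is checked for consistency with the ethogram.
    """
    df = pd.read_csv(path, dtype={"actor": str, "receiver": str})
    return frame_to_events(df, ethogram, observation_window_s)


def frame_to_events(
    df: pd.DataFrame,
    ethogram: Optional[Ethogram] = None,
    observation_window_s: float = OBSERVATION_WINDOW_S,
) -> list[BehaviourEvent]:
    ethogram = ethogram or default_ethogram()
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise EventValidationError(f"missing event columns: {missing}")
    events = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        receiver = row.receiver
        if receiver is None or (isinstance(receiver, float) and pd.isna(receiver)):
            receiver = None
        elif isinstance(receiver, str) and receiver.strip() == "":
            receiver = None
        event = BehaviourEvent(
            t_start=float(row.time_s),
            actor=str(row.actor),
            receiver=None if receiver is None else str(receiver),
            code=str(row.behaviour),
            duration_s=float(row.duration_s),
        )
        validate_event(event, ethogram, observation_window_s, row=row_no)
        if str(row.kind) != ethogram.kind(event.code):
            raise EventValidationError(
                f"kind {row.kind!r} disagrees with ethogram "
                f"({ethogram.kind(event.code)!r}) for {event.code!r} (row {row_no})"
            )
        events.append(event)
    return sort_events(events)


def events_to_frame(
    events: Sequence[BehaviourEvent], ethogram: Optional[Ethogram] = None
) -> pd.DataFrame:
    ethogram = ethogram or default_ethogram()
    return pd.DataFrame(
        {
            "time_s": [e.t_start for e in events],
            "actor": [e.actor for e in events],
            "receiver": [e.receiver for e in events],
            "behaviour": [e.code for e in events],
            "kind": [ethogram.kind(e.code) for e in events],
            "duration_s": [e.duration_s for e in events],
        }
    )


def write_events_csv(events: Sequence[BehaviourEvent], path, ethogram=None) -> None:
    events_to_frame(events, ethogram).to_csv(path, index=False)


def filter_subtle(
    events: Sequence[BehaviourEvent],
    cutoff_s: Optional[float] = None,
    ethogram: Optional[Ethogram] = None,
) -> list[BehaviourEvent]:
    """Drop subtle behaviours (shove, flick) occurring after the cutoff.

    Subtle behaviours are too brief to score reliably once the acute
    post-mixing aggression has subsided, so they are only scored within the
    first 2 h.  The boundary is inclusive: an event at exactly ``cutoff_s``
    is retained.  No other behaviour is ever removed.
    """
    ethogram = ethogram or default_ethogram()
    if cutoff_s is None:
        cutoff_s = ethogram.subtle_cutoff_s
    return [
        e
        for e in events
        if not (ethogram.is_subtle(e.code) and e.t_start > cutoff_s)
    ]


def involvement_seconds(
    events: Sequence[BehaviourEvent], ethogram: Optional[Ethogram] = None
) -> dict[str, float]:
    """Per-pig seconds of agonistic involvement (as actor or receiver).

    Point behaviours contribute one second, state behaviours their duration;
    only agonistic categories count.
    """
    ethogram = ethogram or default_ethogram()
    totals: dict[str, float] = {}
    for e in events:
        if not ethogram.is_agonistic(e.code):
            continue
        w = 1.0 if ethogram.is_point(e.code) else e.duration_s
        for pig in (e.actor, e.receiver):
            if pig is not None:
                totals[pig] = totals.get(pig, 0.0) + w
    return totals
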