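"""Fight bout assembly from dyadic event streams.

A fight bout is a run of mutual fighting between one dyad.  Fighting that
pauses (a within-fight "rest", or a short break) resumes into the same bout
as long as aggressive acts between the dyad never cease for 60 s or more.
A bout's outcome is *decided* when exactly one participant retreats within
the reciprocation window (3 s) of the last aggressive act; the other pig is
the winner.  If both or neither retreat, the outcome is undecided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .ethogram import Ethogram, default_ethogram
from .events import BehaviourEvent, EventValidationError, sort_events


@dataclass(frozen=True)
class FightBout:
    """One mutual-fighting bout between ``pig_a`` and ``pig_b``."""

    pig_a: str
    pig_b: str
    t_start: float
    t_end: float
    initiator: str
    winner: Optional[str] = None
    events: tuple[BehaviourEvent, ...] = field(default_factory=tuple)

    @property
    def duration_s(self) -> float:
        """Bout span, first to last fighting; within-bout rest included."""
        return self.t_end - self.t_start

    @property
    def fighting_seconds(self) -> float:
        """Active fighting time: summed durations of the fight states."""
        return sum(
            e.duration_s for e in self.events if e.code == "fight"
        )

    @property
    def decided(self) -> bool:
        return self.winner is not None

    @property
    def loser(self) -> Optional[str]:
        if self.winner is None:
            return None
        return self.pig_b if self.winner == self.pig_a else self.pig_a

    def dyad(self) -> frozenset:
        return frozenset((self.pig_a, self.pig_b))


def _dyad_key(event: BehaviourEvent) -> Optional[frozenset]:
    if event.receiver is None:
        return None
    return frozenset((event.actor, event.receiver))


def segment_fights(
    events: Sequence[BehaviourEvent], ethogram: Optional[Ethogram] = None
) -> list[FightBout]:
    """Assemble fight bouts from a sorted event stream.

    Per dyad, fight-state events are chained into a single bout while no gap
    of ``fight_gap_end_s`` (60 s) or more separates consecutive aggressive
    acts; rest states between fighting do not break a bout and their time
    counts inside the bout duration (bout span runs from the first to the
    last fight state).  Overlapping fight states for the same dyad are a
    scoring error and raise :class:`EventValidationError`.
    """
    ethogram = ethogram or default_ethogram()
    gap_end = ethogram.fight_gap_end_s
    window = ethogram.reciprocation_window_s

    by_dyad: dict[frozenset, list[BehaviourEvent]] = {}
    for e in sort_events(events):
        key = _dyad_key(e)
        if key is None or len(key) != 2:
            continue
        by_dyad.setdefault(key, []).append(e)

    bouts: list[FightBout] = []
    for dyad, dyad_events in by_dyad.items():
        fights = [e for e in dyad_events if ethogram.category(e.code) == "mutual_fight"]
        if not fights:
            continue
        for prev, nxt in zip(fights, fights[1:]):
            if nxt.t_start < prev.t_end:
                raise EventValidationError(
                    f"overlapping fight states for dyad {sorted(dyad)}: "
                    f"[{prev.t_start}, {prev.t_end}) and [{nxt.t_start}, {nxt.t_end})"
                )

        aggressive = [e for e in dyad_events if ethogram.is_aggressive_act(e.code)]
        # chain aggressive acts: a new cluster starts when the gap since the
        # latest act end reaches 60 s
        clusters: list[list[BehaviourEvent]] = []
        last_end = None
        for e in aggressive:
            if last_end is None or e.t_start - last_end >= gap_end:
                clusters.append([])
            clusters[-1].append(e)
            last_end = max(last_end, e.t_end) if last_end is not None else e.t_end

        for cluster in clusters:
            cluster_fights = [
                e for e in cluster if ethogram.category(e.code) == "mutual_fight"
            ]
            if not cluster_fights:
                continue
            t_start = cluster_fights[0].t_start
            t_end = max(e.t_end for e in cluster_fights)
            initiator = cluster_fights[0].actor
            pig_a, pig_b = sorted(dyad)

            # constituents: aggressive acts of the cluster within the bout
            # span, rest states inside the span, and terminal retreats
            constituents = [
                e for e in cluster if t_start <= e.t_start and e.t_end <= t_end
            ]
            constituents += [
                e
                for e in dyad_events
                if ethogram.category(e.code) == "rest"
                and t_start <= e.t_start
                and e.t_end <= t_end
            ]
            retreats = [
                e
                for e in dyad_events
                if ethogram.category(e.code) == "retreat"
                and t_end <= e.t_start <= t_end + window
            ]
            retreaters = {e.actor for e in retreats}
            winner = None
            if len(retreaters) == 1:
                (retreater,) = retreaters
                winner = pig_b if retreater == pig_a else pig_a
            constituents += retreats
            bouts.append(
                FightBout(
                    pig_a=pig_a,
                    pig_b=pig_b,
                    t_start=t_start,
                    t_end=t_end,
                    initiator=initiator,
                    winner=winner,
                    events=tuple(sort_events(constituents)),
                )
            )
    bouts.sort(key=lambda b: (b.t_start, b.pig_a, b.pig_b))
    return bouts
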