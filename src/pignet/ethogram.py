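"""Agonistic ethogram: behaviour codes, categories and timing conventions.

The ethogram distinguishes *point* behaviours (instantaneous acts such as a
head-knock, a single bite or a retreat) from *state* behaviours that carry a
duration (pushing, bullying, mutual fighting, within-fight rest).  Behaviour
categories group codes by their role in agonistic exchange:

``display``
    Mutual threat displays (heads-up, parallel walking).
``non_damaging``
    Contact aggression without biting (head-knock, lunge, shove, flick, push).
``single_bite`` / ``unilateral``
    Damaging aggression: a landed bite, or sustained one-sided biting/chasing
    ("bullying").
``mutual_fight``
    Reciprocated biting by both pigs.
``retreat``
    A submissive point behaviour signalling defeat.
``rest`` / ``mounting`` / ``other``
    Within-fight pauses and non-agonistic context behaviours.

A default ethogram is shipped as a YAML config (``data/ethogram.yaml``) and
can be extended or replaced by users with the same schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Iterator

import yaml

POINT = "point"
STATE = "state"

CATEGORIES = frozenset(
    {
        "display",
        "non_damaging",
        "single_bite",
        "unilateral",
        "mutual_fight",
        "retreat",
        "rest",
        "mounting",
        "other",
    }
)

#: categories counted as agonistic behaviour (edges of the ALL network)
AGONISTIC_CATEGORIES = frozenset(
    {"display", "non_damaging", "single_bite", "unilateral", "mutual_fight"}
)

#: damaging aggression: biting behaviours (edges of the UNI network)
DAMAGING_CATEGORIES = frozenset({"single_bite", "unilateral"})

#: aggressive acts whose cessation for >= 60 s ends a fight bout
AGGRESSIVE_ACT_CATEGORIES = frozenset(
    {"non_damaging", "single_bite", "unilateral", "mutual_fight"}
)


@dataclass(frozen=True)
class EthogramEntry:
    """One behaviour code with its category and point/state kind."""

    code: str
    category: str
    kind: str
    subtle: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown behaviour category: {self.category!r}")
        if self.kind not in (POINT, STATE):
            raise ValueError(f"kind must be 'point' or 'state', got {self.kind!r}")


class Ethogram:
    """A validated set of :class:`EthogramEntry` plus timing conventions."""

    def __init__(
        self,
        entries: Iterable[EthogramEntry],
        reciprocation_window_s: float = 3.0,
        fight_gap_end_s: float = 60.0,
        subtle_cutoff_s: float = 7200.0,
    ) -> None:
        self._entries: dict[str, EthogramEntry] = {}
        for entry in entries:
            if entry.code in self._entries:
                raise ValueError(f"duplicate behaviour code: {entry.code!r}")
            self._entries[entry.code] = entry
        self.reciprocation_window_s = float(reciprocation_window_s)
        self.fight_gap_end_s = float(fight_gap_end_s)
        self.subtle_cutoff_s = float(subtle_cutoff_s)

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __iter__(self) -> Iterator[EthogramEntry]:
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self._entries)

    def entry(self, code: str) -> EthogramEntry:
        try:
            return self._entries[code]
        except KeyError:
            raise KeyError(f"behaviour code not in ethogram: {code!r}") from None

    def kind(self, code: str) -> str:
        return self.entry(code).kind

    def category(self, code: str) -> str:
        return self.entry(code).category

    def is_point(self, code: str) -> bool:
        return self.kind(code) == POINT

    def is_subtle(self, code: str) -> bool:
        return self.entry(code).subtle

    def is_agonistic(self, code: str) -> bool:
        return self.category(code) in AGONISTIC_CATEGORIES

    def is_damaging(self, code: str) -> bool:
        return self.category(code) in DAMAGING_CATEGORIES

    def is_aggressive_act(self, code: str) -> bool:
        return self.category(code) in AGGRESSIVE_ACT_CATEGORIES

    @classmethod
    def from_mapping(cls, doc: dict) -> "Ethogram":
        entries = [
            EthogramEntry(
                code=str(b["code"]),
                category=str(b["category"]),
                kind=str(b["kind"]),
                subtle=bool(b.get("subtle", False)),
            )
            for b in doc["behaviours"]
        ]
        return cls(
            entries,
            reciprocation_window_s=doc.get("reciprocation_window_s", 3.0),
            fight_gap_end_s=doc.get("fight_gap_end_s", 60.0),
            subtle_cutoff_s=doc.get("subtle_cutoff_s", 7200.0),
        )

    @classmethod
    def from_yaml(cls, path) -> "Ethogram":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))


@lru_cache(maxsize=1)
def default_ethogram() -> Ethogram:
    """The packaged post-regrouping agonistic ethogram."""
    text = resources.files("pignet").joinpath("data/ethogram.yaml").read_text()
    return Ethogram.from_mapping(yaml.safe_load(text))
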