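"""Construction of the four post-mixing aggression networks.

Network types:

``ALL``
    Every agonistic behaviour (damaging and non-damaging, including
    displays), directed actor -> receiver, weighted by duration with point
    behaviours worth one second.
``UNI``
    Unidirectional, non-reciprocated damaging aggression (single bites and
    bullying) where the receiver delivered no damaging act back within the
    reciprocation window; directed, duration-weighted.
``FIGHT``
    Mutual fight bouts, undirected, weighted by bout duration (within-bout
    rest included).
``WIN``
    Decided fight bouts, directed winner -> loser, weighted by the count of
    decided fights won.

Littermate dyads are excluded from every network: aggression is directed
almost exclusively at unfamiliar pigs and centralities are normalised by
the number of non-littermates, so littermate edges would corrupt that
denominator.  Pigs with no edges are retained as isolated nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import pandas as pd

from .bouts import FightBout
from .ethogram import Ethogram, default_ethogram
from .events import BehaviourEvent

NET_TYPES = ("ALL", "UNI", "FIGHT", "WIN")

ROSTER_COLUMNS = ["pig_id", "pen_id", "litter_id", "sex", "weight_kg"]


@dataclass
class AgonisticNetwork:
    """One aggression network: a networkx graph tagged with its type."""

    net_type: str
    graph: nx.Graph

    @property
    def directed(self) -> bool:
        return self.graph.is_directed()

    @property
    def is_multigraph(self) -> bool:
        return self.graph.is_multigraph()

    def nodes(self):
        return self.graph.nodes

    def copy(self) -> "AgonisticNetwork":
        return AgonisticNetwork(self.net_type, self.graph.copy())


def validate_roster(roster: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ROSTER_COLUMNS if c not in roster.columns]
    if missing:
        raise ValueError(f"missing roster columns: {missing}")
    if roster["pig_id"].duplicated().any():
        raise ValueError("duplicate pig IDs in roster")
    return roster


def nonlittermate_counts(roster: pd.DataFrame) -> dict[str, int]:
    """Per pig, the number of pen-mates from a different litter."""
    counts = {}
    for pen, pen_df in roster.groupby("pen_id"):
        litter_sizes = pen_df["litter_id"].value_counts()
        n = len(pen_df)
        for r in pen_df.itertuples(index=False):
            counts[str(r.pig_id)] = int(n - litter_sizes[r.litter_id])
    return counts


def _base_graph(net_type: str, roster: pd.DataFrame, multigraph: bool) -> nx.Graph:
    if net_type == "FIGHT":
        G = nx.MultiGraph() if multigraph else nx.Graph()
    else:
        G = nx.MultiDiGraph() if multigraph else nx.DiGraph()
    nonlit = nonlittermate_counts(roster)
    for r in roster.itertuples(index=False):
        G.add_node(
            str(r.pig_id),
            pen_id=str(r.pen_id),
            litter_id=str(r.litter_id),
            sex=str(r.sex),
            weight_kg=float(r.weight_kg),
            n_nonlittermates=nonlit[str(r.pig_id)],
        )
    return G


def _littermate_lookup(roster: pd.DataFrame) -> dict[str, str]:
    return {str(r.pig_id): str(r.litter_id) for r in roster.itertuples(index=False)}


def build_network(
    events: Sequence[BehaviourEvent],
    bouts: Sequence[FightBout],
    net_type: str,
    roster: pd.DataFrame,
    ethogram: Optional[Ethogram] = None,
) -> AgonisticNetwork:
    """Build one aggression network (with parallel edges; see ``simplify``).

    ``events`` should already be filtered (subtle-behaviour cutoff applied)
    and ``bouts`` segmented from the same stream.
    """
    if net_type not in NET_TYPES:
        raise ValueError(f"unknown network type {net_type!r}; expected {NET_TYPES}")
    ethogram = ethogram or default_ethogram()
    validate_roster(roster)
    litter_of = _littermate_lookup(roster)

    def littermates(a: str, b: str) -> bool:
        return litter_of.get(a) is not None and litter_of.get(a) == litter_of.get(b)

    G = _base_graph(net_type, roster, multigraph=True)

    if net_type in ("ALL", "UNI"):
        if net_type == "UNI":
            pool = [
                e
                for e in events
                if e.receiver is not None and ethogram.is_damaging(e.code)
            ]
        else:
            pool = [
                e
                for e in events
                if e.receiver is not None and ethogram.is_agonistic(e.code)
            ]
        window = ethogram.reciprocation_window_s
        for e in pool:
            if littermates(e.actor, e.receiver):
                continue
            if net_type == "UNI" and _reciprocated(e, pool, window):
                continue
            weight = 1.0 if ethogram.is_point(e.code) else e.duration_s
            if weight > 0:
                G.add_edge(e.actor, e.receiver, weight=weight)
    elif net_type == "FIGHT":
        # active fighting time, not the bout span: within-bout rest carries
        # no aggression, and this keeps FIGHT weights a subset of ALL
        for b in bouts:
            if littermates(b.pig_a, b.pig_b):
                continue
            w = b.fighting_seconds
            if w > 0:
                G.add_edge(b.pig_a, b.pig_b, weight=w)
    else:  # WIN
        for b in bouts:
            if not b.decided or littermates(b.pig_a, b.pig_b):
                continue
            G.add_edge(b.winner, b.loser, weight=1.0)
    return AgonisticNetwork(net_type, G)


def _reciprocated(
    e: BehaviourEvent, damaging: Sequence[BehaviourEvent], window: float
) -> bool:
    # a damaging act by the receiver back at the actor overlapping
    # [t_start - w, t_end + w] makes the exchange reciprocated
    lo, hi = e.t_start - window, e.t_end + window
    return any(
        o.actor == e.receiver
        and o.receiver == e.actor
        and o.t_start <= hi
        and o.t_end >= lo
        for o in damaging
    )


def simplify(net: AgonisticNetwork) -> AgonisticNetwork:
    """Merge parallel edges of a dyad by summing weights (idempotent)."""
    G = net.graph
    simple = nx.DiGraph() if G.is_directed() else nx.Graph()
    simple.add_nodes_from(G.nodes(data=True))
    if G.is_multigraph():
        edge_iter = ((u, v, d) for u, v, k, d in G.edges(keys=True, data=True))
    else:
        edge_iter = G.edges(data=True)
    for u, v, d in edge_iter:
        w = float(d.get("weight", 1.0))
        if simple.has_edge(u, v):
            simple[u][v]["weight"] += w
        else:
            simple.add_edge(u, v, weight=w)
    return AgonisticNetwork(net.net_type, simple)


def unweighted_view(net: AgonisticNetwork) -> AgonisticNetwork:
    """Same topology with every edge weight set to one."""
    out = net.copy()
    for _, _, d in out.graph.edges(data=True):
        d["weight"] = 1.0
    return out


def total_edge_weight(net: AgonisticNetwork) -> float:
    return float(sum(d.get("weight", 1.0) for _, _, d in net.graph.edges(data=True)))


def to_edge_frame(net: AgonisticNetwork) -> pd.DataFrame:
    rows = [
        {
            "source": u,
            "target": v,
            "weight": d.get("weight", 1.0),
            "net_type": net.net_type,
        }
        for u, v, d in net.graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "weight", "net_type"])


def write_edge_csv(net: AgonisticNetwork, path) -> None:
    to_edge_frame(net).to_csv(path, index=False)


def write_graphml(net: AgonisticNetwork, path) -> None:
    G = net.graph.copy()
    G.graph["net_type"] = net.net_type
    nx.write_graphml(G, path)
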