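"""Centrality measures with group-size normalisation.

All measures are computed on simplified networks (one edge per dyad) whose
nodes carry an ``n_nonlittermates`` attribute, the number of potential
(unfamiliar) opponents in the pen.  Size corrections:

* degree family: divided by the focal pig's number of non-littermates, so
  an unweighted degree of 1 means the pig interacted with every potential
  opponent;
* betweenness: the raw fractional-split value divided by the number of
  ordered (directed) or unordered (undirected) pairs of other nodes,
  ``(n-1)(n-2)`` or ``(n-1)(n-2)/2`` with ``n`` = non-littermates + 1;
* eigenvector: scaled so the maximum entry is one (already scale-free).

Betweenness uses the fractional split: for every pair (a, b) each node x
on a shortest a-b path receives (shortest a-b paths through x) / (all
shortest a-b paths).  The weighted variant travels on edge distances
1/weight, so strong ties are cheap to traverse.  Eigenvector centrality is
an undirected measure and is computed on the undirected weighted
projection (reciprocal directed weights summed).

An exhaustive path-enumeration oracle (``betweenness_oracle``) is provided
for small graphs so the shortest-path implementation can be verified
independently.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .networks import AgonisticNetwork

DEGREE_METRICS = (
    "degree",
    "indegree",
    "outdegree",
    "w_degree",
    "w_indegree",
    "w_outdegree",
)

#: weighted metric -> its unweighted counterpart, for the redundancy screen
REDUNDANCY_PAIRS = {
    "w_degree": "degree",
    "w_indegree": "indegree",
    "w_outdegree": "outdegree",
    "w_betweenness": "betweenness",
}


@dataclass(frozen=True)
class CentralityRecord:
    pig: str
    net_type: str
    metric: str
    raw: float
    normalised: float
    n_nonlittermates: int


def _records(net, metric, raw_values, normalised_values) -> list[CentralityRecord]:
    out = []
    for node in net.graph.nodes:
        out.append(
            CentralityRecord(
                pig=node,
                net_type=net.net_type,
                metric=metric,
                raw=float(raw_values[node]),
                normalised=float(normalised_values[node]),
                n_nonlittermates=int(net.graph.nodes[node]["n_nonlittermates"]),
            )
        )
    return out


def _check_simple(net: AgonisticNetwork) -> None:
    if net.is_multigraph:
        raise ValueError("centrality requires a simplified network")


def degree(
    net: AgonisticNetwork, mode: str = "all", weighted: bool = False
) -> list[CentralityRecord]:
    """Degree centrality, raw and normalised by non-littermate count.

    Unweighted: the number of distinct opponents interacted with in the
    given direction.  Weighted ("strength"): the summed edge weight.
    """
    _check_simple(net)
    if mode not in ("in", "out", "all"):
        raise ValueError(f"mode must be in/out/all, got {mode!r}")
    G = net.graph
    if mode in ("in", "out") and not G.is_directed():
        raise ValueError(f"mode {mode!r} undefined on an undirected network")
    raw = {}
    for node in G.nodes:
        if weighted:
            if not G.is_directed():
                val = sum(d["weight"] for _, _, d in G.edges(node, data=True))
            else:
                val = 0.0
                if mode in ("in", "all"):
                    val += sum(d["weight"] for _, _, d in G.in_edges(node, data=True))
                if mode in ("out", "all"):
                    val += sum(d["weight"] for _, _, d in G.out_edges(node, data=True))
        else:
            if not G.is_directed():
                val = G.degree(node)
            elif mode == "in":
                val = G.in_degree(node)
            elif mode == "out":
                val = G.out_degree(node)
            else:
                val = len(set(G.predecessors(node)) | set(G.successors(node)))
        raw[node] = float(val)
    normalised = {
        node: raw[node] / G.nodes[node]["n_nonlittermates"]
        if G.nodes[node]["n_nonlittermates"] > 0
        else 0.0
        for node in G.nodes
    }
    prefix = "w_" if weighted else ""
    name = {"in": "indegree", "out": "outdegree", "all": "degree"}[mode]
    return _records(net, prefix + name, raw, normalised)


def _with_distances(G: nx.Graph) -> nx.Graph:
    H = G.copy()
    for _, _, d in H.edges(data=True):
        d["dist"] = 1.0 / d["weight"]
    return H


def betweenness(
    net: AgonisticNetwork, weighted: bool = False
) -> list[CentralityRecord]:
    """Fractional-split betweenness (Brandes), raw and size-normalised.

    The weighted variant uses edge distance 1/weight.  Unreachable pairs
    contribute nothing.
    """
    _check_simple(net)
    G = net.graph
    if weighted:
        raw = nx.betweenness_centrality(
            _with_distances(G), normalized=False, weight="dist"
        )
    else:
        raw = nx.betweenness_centrality(G, normalized=False, weight=None)
    normalised = {}
    for node in G.nodes:
        n = G.nodes[node]["n_nonlittermates"] + 1
        pairs = (n - 1) * (n - 2)
        if not G.is_directed():
            pairs /= 2.0
        normalised[node] = raw[node] / pairs if pairs > 0 else 0.0
    return _records(net, "w_betweenness" if weighted else "betweenness", raw, normalised)


def undirected_projection(net: AgonisticNetwork) -> nx.Graph:
    """Undirected weighted projection: reciprocal directed weights summed."""
    G = net.graph
    H = nx.Graph()
    H.add_nodes_from(G.nodes(data=True))
    for u, v, d in G.edges(data=True):
        w = float(d.get("weight", 1.0))
        if H.has_edge(u, v):
            H[u][v]["weight"] += w
        else:
            H.add_edge(u, v, weight=w)
    return H


def eigenvector(net: AgonisticNetwork) -> list[CentralityRecord]:
    """Leading-eigenvector centrality on the undirected weighted projection.

    Computed by exact symmetric eigendecomposition; entries are
    non-negative and scaled so the maximum is one.  Networks without edges
    yield all zeros.
    """
    _check_simple(net)
    H = undirected_projection(net)
    nodelist = list(H.nodes)
    raw = {node: 0.0 for node in nodelist}
    if H.number_of_edges() > 0:
        A = nx.to_numpy_array(H, nodelist=nodelist, weight="weight")
        eigvals, eigvecs = np.linalg.eigh(A)
        v = np.abs(eigvecs[:, -1])
        raw = dict(zip(nodelist, v))
    vmax = max(raw.values(), default=0.0)
    normalised = {
        node: (val / vmax if vmax > 0 else 0.0) for node, val in raw.items()
    }
    return _records(net, "eigenvector", raw, normalised)


def eigenvector_residual(net: AgonisticNetwork) -> float:
    """Relative residual ||Av - lambda v|| / ||v|| of the computed vector."""
    H = undirected_projection(net)
    if H.number_of_edges() == 0:
        return 0.0
    A = nx.to_numpy_array(H, weight="weight")
    eigvals, eigvecs = np.linalg.eigh(A)
    v = eigvecs[:, -1]
    lam = eigvals[-1]
    return float(np.linalg.norm(A @ v - lam * v) / np.linalg.norm(v))


def betweenness_oracle(
    net: AgonisticNetwork, weighted: bool = False, max_nodes: int = 8
) -> dict[str, float]:
    """Exhaustive-enumeration betweenness for graphs of <= ``max_nodes``.

    Enumerates every simple path between every pair, keeps the shortest,
    and splits each pair's unit of betweenness equally across the tied
    shortest paths.  Independent of the shortest-path implementation used
    by :func:`betweenness`; intended as a test oracle.
    """
    G = net.graph
    if G.number_of_nodes() > max_nodes:
        raise ValueError(f"oracle refuses graphs with more than {max_nodes} nodes")
    if net.is_multigraph:
        raise ValueError("oracle requires a simplified network")
    nodes = list(G.nodes)
    scores = {node: 0.0 for node in nodes}
    directed = G.is_directed()
    pairs = (
        itertools.permutations(nodes, 2)
        if directed
        else itertools.combinations(nodes, 2)
    )

    def edge_dist(u, v):
        return 1.0 / G[u][v]["weight"] if weighted else 1.0

    def all_simple_paths(s, t):
        stack = [(s, [s], 0.0)]
        while stack:
            node, path, length = stack.pop()
            if node == t:
                yield path, length
                continue
            for nbr in G[node] if directed else G.adj[node]:
                if nbr not in path:
                    stack.append((nbr, path + [nbr], length + edge_dist(node, nbr)))

    for s, t in pairs:
        best = None
        shortest: list[list[str]] = []
        for path, length in all_simple_paths(s, t):
            if best is None or length < best - 1e-12:
                best, shortest = length, [path]
            elif abs(length - best) <= 1e-12:
                shortest.append(path)
        if not shortest:
            continue
        share = 1.0 / len(shortest)
        for path in shortest:
            for mid in path[1:-1]:
                scores[mid] += share
    return scores


def centrality_table(net: AgonisticNetwork) -> pd.DataFrame:
    """All applicable centrality records for one network as a tidy table.

    Directed networks get the in/out/all degree family and betweenness;
    the undirected FIGHT network gets all-degree and betweenness; the
    FIGHT and WIN networks additionally get eigenvector centrality.
    """
    records: list[CentralityRecord] = []
    modes = ("all", "in", "out") if net.directed else ("all",)
    for mode in modes:
        for wtd in (False, True):
            records += degree(net, mode=mode, weighted=wtd)
    for wtd in (False, True):
        records += betweenness(net, weighted=wtd)
    if net.net_type in ("FIGHT", "WIN"):
        records += eigenvector(net)
    return pd.DataFrame(
        {
            "pig": [r.pig for r in records],
            "net_type": [r.net_type for r in records],
            "metric": [r.metric for r in records],
            "raw": [r.raw for r in records],
            "normalised": [r.normalised for r in records],
            "n_nonlittermates": [r.n_nonlittermates for r in records],
        }
    )


def redundancy_screen(
    table: pd.DataFrame, threshold: float = 0.8
) -> pd.DataFrame:
    """Flag weighted metrics that duplicate their unweighted counterparts.

    Within each network type, a weighted metric is redundant iff its
    Pearson correlation with the unweighted counterpart exceeds
    ``threshold`` (strictly).  Metrics with zero variance are skipped with
    a warning.
    """
    rows = []
    for net_type, sub in table.groupby("net_type"):
        wide = sub.pivot_table(
            index="pig", columns="metric", values="normalised", aggfunc="first"
        )
        for w_metric, u_metric in REDUNDANCY_PAIRS.items():
            if w_metric not in wide.columns or u_metric not in wide.columns:
                continue
            paired = wide[[w_metric, u_metric]].dropna()
            if len(paired) < 3:
                continue
            x, y = paired[w_metric].to_numpy(), paired[u_metric].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(
                    f"zero variance for {w_metric}/{u_metric} in {net_type}; skipped",
                    stacklevel=2,
                )
                continue
            r = float(stats.pearsonr(x, y).statistic)
            # strict > threshold; the epsilon keeps an exactly-threshold
            # correlation on the non-redundant side despite rounding
            redundant = r > threshold + 1e-12
            rows.append(
                {
                    "net_type": net_type,
                    "metric": w_metric,
                    "counterpart": u_metric,
                    "r": r,
                    "n": len(paired),
                    "redundant": redundant,
                }
            )
    return pd.DataFrame(
        rows, columns=["net_type", "metric", "counterpart", "r", "n", "redundant"]
    )
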