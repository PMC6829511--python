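"""Shortest-path census and the communication-robustness (CR) index.

For a node pair (A, B) on the persistence-filtered structure network, l is the
unweighted shortest-path length and σ_AB the exact number of distinct shortest
paths.  The CR index

    CR_AB = σ_AB · p_T / l

rises with path redundancy and interaction persistence and falls with
topological distance, ranking robust short communication routes (for example
between Ca²⁺-binding EF-hands and the residues of a target interface).
σ is accumulated exactly on the BFS predecessor DAG; explicit path listing is
capped (the count stays exact beyond the cap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .exceptions import UnknownNodeError

#: Default EF-hand representative residues (EF2, EF3).
DEFAULT_EF_REPRESENTATIVES = ("E85", "E121")

MAX_LISTED_PATHS = 10_000


@dataclass
class PathCensus:
    source: str
    target: str
    length: int | None         # None when disconnected
    sigma: int                 # 0 when disconnected
    paths: list[tuple] = field(default_factory=list)  # capped listing

    @property
    def connected(self) -> bool:
        return self.sigma > 0


@dataclass
class CRScore:
    value: float
    source: str
    target: str


def _check_nodes(network: nx.Graph, nodes) -> None:
    missing = [n for n in nodes if n not in network]
    if missing:
        raise UnknownNodeError(missing)


def shortest_path_census(network: nx.Graph, source: str, target: str,
                         max_paths: int = MAX_LISTED_PATHS) -> PathCensus:
    """BFS distance l and exact shortest-path count σ between two nodes."""
    _check_nodes(network, [source, target])
    if source == target:
        raise ValueError("source and target must differ")
    # BFS with path-count accumulation over the predecessor DAG
    dist = {source: 0}
    sigma = {source: 1}
    preds: dict[str, list[str]] = {source: []}
    queue = [source]
    while queue:
        nxt = []
        for u in queue:
            if u == target:
                continue
            for v in network[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    sigma[v] = sigma[u]
                    preds[v] = [u]
                    nxt.append(v)
                elif dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        queue = nxt
        if target in dist and queue and dist[queue[0]] > dist[target]:
            break
    if target not in dist:
        return PathCensus(source, target, None, 0)
    # enumerate up to max_paths shortest paths by backtracking the DAG
    paths: list[tuple] = []
    stack = [(target, (target,))]
    while stack and len(paths) < max_paths:
        node, tail = stack.pop()
        if node == source:
            paths.append(tuple(reversed(tail)))
            continue
        for p in preds[node]:
            stack.append((p, tail + (p,)))
    return PathCensus(source, target, dist[target], sigma[target], paths)


def cr_index(census: PathCensus, p_t: float,
             form: str = "ratio") -> CRScore:
    """CR = σ·p_T/l (``form='ratio'``, the default reading); ``form='product'``
    exposes the alternative σ·p_T·l for sensitivity checks only."""
    if p_t <= 0:
        raise ValueError("p_T must be positive")
    if not census.connected:
        return CRScore(0.0, census.source, census.target)
    if form == "ratio":
        value = census.sigma * p_t / census.length
    elif form == "product":
        value = census.sigma * p_t * census.length
    else:
        raise ValueError("form must be 'ratio' or 'product'")
    return CRScore(float(value), census.source, census.target)


def ef_interface_report(
    network: nx.Graph,
    ef_nodes,
    interface_nodes,
    p_t: float,
    top_k: int = 3,
) -> pd.DataFrame:
    """CR scores for every (EF-hand, interface-residue) pair.

    Returns a DataFrame with columns source, target, l, sigma, cr and a
    boolean ``top`` marking, per EF-hand representative, the ``top_k``
    highest-CR interface partners.
    """
    ef_nodes = list(ef_nodes)
    interface_nodes = list(interface_nodes)
    if not ef_nodes or not interface_nodes:
        raise ValueError("node lists must be nonempty")
    _check_nodes(network, ef_nodes + interface_nodes)
    rows = []
    for ef in ef_nodes:
        for tgt in interface_nodes:
            if ef == tgt:
                continue
            census = shortest_path_census(network, ef, tgt)
            score = cr_index(census, p_t)
            rows.append({
                "source": ef, "target": tgt,
                "l": census.length if census.connected else 0,
                "sigma": census.sigma, "cr": score.value,
            })
    df = pd.DataFrame(rows, columns=["source", "target", "l", "sigma", "cr"])
    df["top"] = False
    for ef in ef_nodes:
        idx = df[df["source"] == ef].nlargest(top_k, "cr").index
        df.loc[idx, "top"] = True
    return df.sort_values(["source", "cr"],
                          ascending=[True, False]).reset_index(drop=True)
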