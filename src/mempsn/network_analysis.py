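"""Persistence-threshold selection, network assembly, hubs and contact profiles.

The persistence threshold p_T (percent scale) is chosen by the
largest-hydrophobic-cluster criterion: sweep a persistence cutoff over the
hydrophobic interaction graph, record the size of the largest connected
component at each cutoff, fit a logistic to the size-versus-cutoff curve and
take its inflection point.  The three class graphs (H-bond, salt bridge,
hydrophobic) filtered at p_T are then merged into a single structure network.

Scales: p_T lives on the percent scale (e.g. 20.2); persistences are fractions
in [0, 1] (e.g. 0.13).  Conversions are explicit at every interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import ThresholdUndefinedError
from .interactions import CLASSES, PersistenceTable, canonical_pair

#: Fig-style degree colour classes for major hubs.
DEGREE_COLORS = {7: "blue", 8: "yellow", 9: "orange"}

#: Default reporting filter for per-residue lipid-contact profiles.
REPORT_THRESHOLD = 0.13


def _logistic(c, bottom, amplitude, inflection, width):
    return bottom + amplitude / (1.0 + np.exp((c - inflection) / width))


@dataclass
class ThresholdResult:
    p_t: float
    cutoffs: np.ndarray        # percent grid
    sizes: np.ndarray          # largest-component size at each cutoff
    fit_params: tuple          # (bottom, amplitude, inflection, width)

    def __float__(self):
        return float(self.p_t)


def largest_component_sizes(table: dict[tuple[str, str], float],
                            cutoffs_percent: np.ndarray) -> np.ndarray:
    """Largest connected-component size of the graph filtered at each cutoff.

    ``table`` maps node pairs to persistence fractions.  Isolated nodes do not
    count as clusters: an empty filtered graph has size 0.
    """
    edges = sorted(table.items(), key=lambda kv: -kv[1])
    sizes = np.zeros(len(cutoffs_percent), dtype=int)
    # sweep from high cutoff to low, adding surviving edges incrementally
    order = np.argsort(cutoffs_percent)[::-1]
    g = nx.Graph()
    k = 0
    for pos in order:
        c = cutoffs_percent[pos] / 100.0
        while k < len(edges) and edges[k][1] >= c - 1e-12:
            (a, b), _ = edges[k]
            g.add_edge(a, b)
            k += 1
        sizes[pos] = max((len(cc) for cc in nx.connected_components(g)),
                         default=0) if g.number_of_edges() else 0
    return sizes


def select_threshold(
    hydrophobic_table: PersistenceTable | dict,
    step: float = 0.2,
    return_details: bool = False,
):
    """Choose p_T (percent) at the inflection of the largest-cluster curve.

    Raises :class:`ThresholdUndefinedError` when the curve is degenerate
    (constant size) or the logistic fit fails, suggesting a manual p_T.
    """
    if isinstance(hydrophobic_table, PersistenceTable):
        table = hydrophobic_table.class_table("hydrophobic")
    else:
        table = dict(hydrophobic_table)
    if not table:
        raise ThresholdUndefinedError(
            "hydrophobic graph is empty; supply p_T manually"
        )
    cutoffs = np.arange(0.0, 100.0 + step / 2, step)
    sizes = largest_component_sizes(table, cutoffs)
    if sizes.max() == sizes.min():
        raise ThresholdUndefinedError(
            "largest-cluster size curve is constant; supply p_T manually"
        )
    # degenerate single-step curves carry no inflection information
    if len(np.unique(sizes)) <= 2:
        raise ThresholdUndefinedError(
            "largest-cluster size curve is a single step; supply p_T manually"
        )
    lo, hi = float(sizes.min()), float(sizes.max())
    half = hi / 2.0
    guess_c0 = float(cutoffs[np.argmin(np.abs(sizes - half))])
    p0 = (lo, hi - lo, guess_c0, 2.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params, _ = curve_fit(
                _logistic, cutoffs, sizes.astype(float), p0=p0,
                bounds=([0.0, 0.0, 0.0, 1e-3],
                        [hi, 2 * hi, 100.0, 50.0]),
                maxfev=20000,
            )
    except (RuntimeError, ValueError) as exc:
        raise ThresholdUndefinedError(
            f"logistic fit failed ({exc}); supply p_T manually"
        ) from exc
    result = ThresholdResult(float(params[2]), cutoffs, sizes, tuple(params))
    return result if return_details else result.p_t


def build_network(
    tables: PersistenceTable | dict[str, PersistenceTable],
    p_t: float,
) -> nx.Graph:
    """Filter each class graph at persistence ≥ p_T/100 and merge.

    Accepts one multi-class :class:`PersistenceTable` or a mapping
    {class: table}.  Edges carry per-class persistences, the contributing
    class list and ``max_persistence``; the graph records ``p_t``.
    """
    if not 0 < p_t < 100:
        raise ValueError("p_T must lie in (0, 100) on the percent scale")
    if isinstance(tables, PersistenceTable):
        class_tables = {cls: tables.class_table(cls) for cls in CLASSES}
    else:
        class_tables = {
            cls: (t.class_table(cls) if isinstance(t, PersistenceTable)
                  else dict(t))
            for cls, t in tables.items()
        }
    g = nx.Graph(p_t=float(p_t))
    threshold = p_t / 100.0
    for cls, table in class_tables.items():
        for (a, b), p in table.items():
            if p < threshold:
                continue
            a, b = canonical_pair(a, b)
            if g.has_edge(a, b):
                data = g[a][b]
            else:
                g.add_edge(a, b, classes="", max_persistence=0.0)
                data = g[a][b]
            data[f"persistence_{cls}"] = float(p)
            contributed = set(data["classes"].split(",")) - {""}
            contributed.add(cls)
            data["classes"] = ",".join(sorted(contributed))
            data["max_persistence"] = max(data["max_persistence"], float(p))
    return g


def hubs(network: nx.Graph, min_degree: int = 3) -> pd.DataFrame:
    """Per-node degree table with hub flags and the degree colour code
    (blue/yellow/orange for degrees 7/8/9) used for rendering major hubs."""
    rows = [
        {"node": n, "degree": int(d), "is_hub": d >= min_degree,
         "color": DEGREE_COLORS.get(int(d), "")}
        for n, d in network.degree()
    ]
    df = pd.DataFrame(rows, columns=["node", "degree", "is_hub", "color"])
    return df.sort_values(["degree", "node"],
                          ascending=[False, True]).reset_index(drop=True)


def degree_delta(network_a: nx.Graph, network_b: nx.Graph,
                 min_degree: int = 7) -> pd.DataFrame:
    """Signed per-node degree difference A − B, restricted to nodes that are
    hubs (degree ≥ ``min_degree``) in at least one state.

    Nodes missing from one network carry degree 0 there and are flagged.
    """
    nodes_a, nodes_b = set(network_a), set(network_b)
    if nodes_a and nodes_b and not (nodes_a & nodes_b):
        warnings.warn("networks share no nodes; delta report is empty")
        return pd.DataFrame(
            columns=["node", "degree_a", "degree_b", "delta", "missing_in"]
        )
    rows = []
    for n in sorted(nodes_a | nodes_b):
        da = network_a.degree(n) if n in nodes_a else 0
        db = network_b.degree(n) if n in nodes_b else 0
        if max(da, db) < min_degree:
            continue
        missing = "B" if n not in nodes_b else ("A" if n not in nodes_a else "")
        rows.append({"node": n, "degree_a": int(da), "degree_b": int(db),
                     "delta": int(da - db), "missing_in": missing})
    return pd.DataFrame(
        rows, columns=["node", "degree_a", "degree_b", "delta", "missing_in"]
    )


def lipid_contact_profile(
    table: PersistenceTable,
    report_threshold: float = REPORT_THRESHOLD,
    aggregate: str = "max",
) -> pd.DataFrame:
    """Per-residue lipid-engagement profile stacked by interaction class.

    For every protein residue (or MYR), persistences over its lipid partners
    are aggregated within each class — by default the maximum over partners
    (how persistently the residue is lipid-engaged, regardless of which lipid;
    ``aggregate='sum'`` totals over partners instead).  Rows where all three
    classes are ≤ ``report_threshold`` are omitted.
    """
    if aggregate not in ("max", "sum"):
        raise ValueError("aggregate must be 'max' or 'sum'")
    per_res: dict[str, dict[str, float]] = {}
    for (a, b, cls), p in table.items():
        # the protein-side node is the one that is not a lipid key
        residue = b if ("_" in a and not a.startswith("MYR")) else a
        slot = per_res.setdefault(residue, dict.fromkeys(CLASSES, 0.0))
        if aggregate == "max":
            slot[cls] = max(slot[cls], p)
        else:
            slot[cls] += p
    rows = [
        {"residue": res, **vals}
        for res, vals in sorted(per_res.items())
        if any(v > report_threshold for v in vals.values())
    ]
    return pd.DataFrame(rows, columns=["residue", *CLASSES])


def plot_contact_profile(profile: pd.DataFrame, ax=None):
    """Stacked per-residue bar chart of the lipid-contact profile."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.4 * len(profile)), 3))
    bottom = np.zeros(len(profile))
    colors = {"hbond": "tab:blue", "hydrophobic": "tab:red",
              "saltbridge": "gold"}
    for cls in CLASSES:
        ax.bar(profile["residue"], profile[cls], bottom=bottom,
               color=colors[cls], label=cls)
        bottom += profile[cls].to_numpy()
    ax.set_ylabel("persistence")
    ax.legend()
    ax.tick_params(axis="x", rotation=90)
    return ax


# -- export / import -------------------------------------------------------

def write_graphml(network: nx.Graph, path) -> None:
    nx.write_graphml(network, str(path))


def read_graphml(path) -> nx.Graph:
    g = nx.read_graphml(str(path))
    return nx.Graph(g)


def edge_list_frame(network: nx.Graph) -> pd.DataFrame:
    rows = []
    for a, b, data in network.edges(data=True):
        for cls in CLASSES:
            p = data.get(f"persistence_{cls}")
            if p is not None:
                rows.append({"node_a": a, "node_b": b, "class": cls,
                             "persistence": p})
    return pd.DataFrame(rows, columns=["node_a", "node_b", "class",
                                       "persistence"])


def network_from_edge_list(df: pd.DataFrame, p_t: float) -> nx.Graph:
    """Rebuild a structure network from its exported edge list (idempotent
    with :func:`edge_list_frame`)."""
    tables: dict[str, dict] = {cls: {} for cls in CLASSES}
    for a, b, cls, p in zip(df["node_a"], df["node_b"],
                            df["class"], df["persistence"]):
        tables[str(cls)][canonical_pair(str(a), str(b))] = float(p)
    return build_network(tables, p_t)
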