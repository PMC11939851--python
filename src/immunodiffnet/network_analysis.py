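"""Differential-correlation network assembly, class-specific degrees, hubs.

A differential network has one node per marker and one edge per marker
pair that is (i) significantly differentially correlated between the two
conditions of a contrast and (ii) not in a same-sign class (+/+, -/-): a
pair whose correlation keeps its sign in both conditions carries no
between-condition signal. The class 0/0 never forms an edge either (no
correlation anywhere). Isolated nodes are retained for bookkeeping.

Hubs are called per edge class: a node is a hub when its class-specific
degree lies strictly above the 90th percentile (nearest-rank convention)
of the degrees of the nodes touched by that class.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .differential_correlation import (
    EDGE_CLASSES,
    SAME_SIGN_CLASSES,
    DiffCorrRecord,
)
from .errors import ConfigError, ValidationError

__all__ = ["DifferentialNetwork", "HubConfig", "build_network",
           "class_specific_degree", "select_hubs", "class_histogram",
           "export_network", "load_network"]


@dataclass(frozen=True)
class HubConfig:
    """Hub rule: strictly exceed the ``percentile``-th nearest-rank
    percentile of the class-specific degree distribution. By default only
    nodes incident to at least one edge of the class enter the
    distribution; ``include_isolated=True`` counts every node."""

    percentile: float = 90.0
    include_isolated: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 100:
            raise ConfigError("percentile must be in (0, 100)")


@dataclass
class DifferentialNetwork:
    """Class-labelled differential-correlation graph."""

    graph: nx.Graph
    dropped_classes: frozenset[str] = field(
        default_factory=lambda: frozenset(SAME_SIGN_CLASSES))

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(records: list[DiffCorrRecord],
                  drop_classes=SAME_SIGN_CLASSES, *,
                  all_markers: list[str] | None = None,
                  marker_kinds: dict[str, str] | None = None,
                  ) -> DifferentialNetwork:
    """Assemble the network from one contrast's scan records.

    Edges are the significant records whose class is neither 0/0 nor in
    ``drop_classes``. All markers seen in the records (or the explicit
    ``all_markers`` panel) become nodes, so degree distributions include
    zero-degree nodes when requested downstream.
    """
    drop = frozenset(drop_classes) | {"0/0"}
    g = nx.Graph()
    if all_markers is not None:
        for mk in all_markers:
            g.add_node(mk, kind=(marker_kinds or {}).get(mk, ""))
    seen: set[frozenset[str]] = set()
    for rec in records:
        if rec.marker_i == rec.marker_j:
            raise ValidationError(f"self-pair record for {rec.marker_i!r}")
        key = frozenset((rec.marker_i, rec.marker_j))
        if key in seen:
            raise ValidationError(
                f"duplicate pair record {rec.marker_i!r}/{rec.marker_j!r}")
        seen.add(key)
        for mk in (rec.marker_i, rec.marker_j):
            if mk not in g:
                if all_markers is not None:
                    raise ValidationError(f"record marker {mk!r} not in panel")
                g.add_node(mk, kind=(marker_kinds or {}).get(mk, ""))
        if rec.error is not None or not rec.significant:
            continue
        if rec.edge_class in drop:
            continue
        g.add_edge(rec.marker_i, rec.marker_j,
                   edge_class=rec.edge_class, z_diff=float(rec.z_diff))
    return DifferentialNetwork(graph=g, dropped_classes=frozenset(drop_classes))


def class_specific_degree(net: DifferentialNetwork) -> pd.DataFrame:
    """Node x class table counting incident edges of each class."""
    classes = sorted({d["edge_class"] for _, _, d in net.graph.edges(data=True)})
    deg = pd.DataFrame(0, index=net.nodes, columns=classes, dtype=int)
    for u, v, d in net.graph.edges(data=True):
        deg.loc[u, d["edge_class"]] += 1
        deg.loc[v, d["edge_class"]] += 1
    return deg


def nearest_rank_percentile(values, percentile: float) -> float:
    """Nearest-rank percentile: the value at rank ceil(P/100 * n) of the
    ascending-sorted sample (no interpolation)."""
    vals = sorted(values)
    if not vals:
        raise ValidationError("empty sample has no percentile")
    rank = math.ceil(percentile / 100.0 * len(vals))
    rank = min(max(rank, 1), len(vals))
    return vals[rank - 1]


def select_hubs(degree_table: pd.DataFrame, cfg: HubConfig = HubConfig(),
                ) -> dict[str, set[str]]:
    """Per class, the nodes whose degree strictly exceeds the class's
    nearest-rank percentile. Classes without edges yield empty hub sets."""
    hubs: dict[str, set[str]] = {}
    for cls in degree_table.columns:
        col = degree_table[cls]
        population = col if cfg.include_isolated else col[col >= 1]
        if population.empty:
            hubs[cls] = set()
            continue
        cut = nearest_rank_percentile(population.to_numpy(), cfg.percentile)
        hubs[cls] = set(col.index[col > cut])
    return hubs


def class_histogram(net: DifferentialNetwork) -> dict[str, int]:
    """Edge counts per class; values sum to the number of retained edges."""
    hist: dict[str, int] = {}
    for _, _, d in net.graph.edges(data=True):
        hist[d["edge_class"]] = hist.get(d["edge_class"], 0) + 1
    return hist


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def export_network(net: DifferentialNetwork, path, fmt: str = "graphml", *,
                   hub_cfg: HubConfig = HubConfig()) -> None:
    """Write the network as GraphML (node kind, per-class degree and hub
    flags; edge class and z_diff) or as a flat TSV edge list."""
    if fmt == "graphml":
        g = net.graph.copy()
        deg = class_specific_degree(net)
        hubs = select_hubs(deg, hub_cfg)
        for node in g.nodes:
            for cls in deg.columns:
                safe = cls.replace("/", "_")
                g.nodes[node][f"degree[{safe}]"] = int(deg.loc[node, cls])
                g.nodes[node][f"hub[{safe}]"] = node in hubs[cls]
        g.graph["dropped_classes"] = ",".join(sorted(net.dropped_classes))
        nx.write_graphml(g, path)
    elif fmt == "tsv":
        rows = [{"marker_i": u, "marker_j": v, "class": d["edge_class"],
                 "z_diff": d["z_diff"]}
                for u, v, d in net.graph.edges(data=True)]
        pd.DataFrame(rows, columns=["marker_i", "marker_j", "class", "z_diff"]
                     ).to_csv(path, sep="\t", index=False)
    else:
        raise ConfigError(f"unknown export format {fmt!r}")


def load_network(path) -> DifferentialNetwork:
    """Re-import a GraphML export written by :func:`export_network`."""
    g = nx.read_graphml(path)
    g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    dropped = frozenset(filter(None, g.graph.get("dropped_classes", "").split(",")))
    clean = nx.Graph()
    for n, d in g.nodes(data=True):
        clean.add_node(n, kind=d.get("kind", ""))
    for u, v, d in g.edges(data=True):
        clean.add_edge(u, v, edge_class=d["edge_class"], z_diff=float(d["z_diff"]))
    return DifferentialNetwork(graph=clean, dropped_classes=dropped)


def export_summary(net: DifferentialNetwork, path, *,
                   hub_cfg: HubConfig = HubConfig()) -> None:
    """JSON summary: class histogram, hub lists, node/edge counts."""
    deg = class_specific_degree(net)
    hubs = select_hubs(deg, hub_cfg)
    summary = {
        "n_nodes": len(net.nodes),
        "n_edges": net.n_edges,
        "class_histogram": class_histogram(net),
        "hubs": {cls: sorted(nodes) for cls, nodes in hubs.items()},
        "dropped_classes": sorted(net.dropped_classes),
    }
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
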