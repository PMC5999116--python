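"""Directed impact networks: assembly, degree diagnostics and export.

Nodes are alignment positions (tagged with the protein in inter-protein
mode) and a directed edge i -> j means position i impacts position j. The
out-degree of a node is its impact factor, the in-degree its dependency
factor. The out-degree distribution at several gamma values is the
standard diagnostic for choosing the cut-off: with a permissive gamma the
network degrades towards a random (Poisson-like) degree profile, while an
informative cut-off keeps a heavy-tailed, hub-dominated profile.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx

from .encoding import EncodedMatrix
from .impact_core import (
    DetectionResult,
    EdgeRecord,
    dependency_factor,
    detect_edges,
    impact_factor,
    read_edges_tsv,
    write_edges_tsv,
)


class NetworkIntegrityError(ValueError):
    """Edge list violates a structural constraint (e.g. a self-loop)."""


@dataclass
class ImpactNetwork:
    """A directed network of impact relations.

    ``graph`` is a :class:`networkx.DiGraph` whose nodes carry ``impact``
    and ``dependency`` attributes and whose edges carry the probabilities
    and p-value of their :class:`EdgeRecord`. ``edges`` keeps the records
    themselves (duplicates collapsed to the smallest p-value).
    """

    graph: nx.DiGraph
    edges: list[EdgeRecord]
    gamma: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def impact(self) -> dict:
        return {n: d["impact"] for n, d in self.graph.nodes(data=True)}

    def dependency(self) -> dict:
        return {n: d["dependency"] for n, d in self.graph.nodes(data=True)}


def build_network(
    edges: Iterable[EdgeRecord], metadata: Optional[dict] = None
) -> ImpactNetwork:
    """Assemble EdgeRecords into an :class:`ImpactNetwork`.

    Self-loops are an integrity error (the identity relation is excluded
    upstream). Duplicate records for the same ordered pair collapse to the
    one with the smallest p-value (an absent p-value counts as largest).
    """
    best: dict[tuple, EdgeRecord] = {}
    gamma = None
    for e in edges:
        if e.source_key == e.target_key:
            raise NetworkIntegrityError(f"self-loop on {e.source_key}")
        gamma = e.gamma if gamma is None else gamma
        key = (e.source_key, e.target_key)
        old = best.get(key)
        if old is None or _pv(e) < _pv(old):
            best[key] = e
    kept = list(best.values())
    g = nx.DiGraph()
    for e in kept:
        g.add_edge(
            e.source_key,
            e.target_key,
            p11=e.p11,
            p00=e.p00,
            p_value=float("nan") if e.p_value is None else e.p_value,
            gamma=e.gamma,
        )
    imp = impact_factor(kept)
    dep = dependency_factor(kept)
    for node in g.nodes:
        g.nodes[node]["impact"] = imp.get(node, 0)
        g.nodes[node]["dependency"] = dep.get(node, 0)
    return ImpactNetwork(graph=g, edges=kept, gamma=gamma, metadata=metadata or {})


def _pv(e: EdgeRecord) -> float:
    return float("inf") if e.p_value is None else e.p_value


def out_degree_distribution(
    net: ImpactNetwork, all_positions: Optional[Iterable] = None
) -> dict[int, int]:
    """Histogram out-degree -> node count.

    Only nodes appearing in the network are counted unless
    ``all_positions`` supplies the full position list, in which case
    positions without edges contribute to degree 0.
    """
    degrees = dict(net.graph.out_degree())
    if all_positions is not None:
        for p in all_positions:
            degrees.setdefault(p, 0)
    return dict(sorted(Counter(degrees.values()).items()))


def degree_distribution_scan(
    matrix: EncodedMatrix,
    gammas: Sequence[float],
    significance: bool = False,
    p_threshold: float = 0.01,
    n_permutations: int = 2000,
    seed: int = 0,
    include_all_positions: bool = False,
) -> dict[float, dict[int, int]]:
    """Out-degree distributions across a grid of gamma cut-offs.

    Runs edge detection per gamma (significance off by default, for speed)
    and returns one histogram per cut-off for power-law-vs-Poisson
    inspection; no distribution fitting is attempted.
    """
    out: dict[float, dict[int, int]] = {}
    positions = (
        [
            (lbl if matrix.position_tags is None else f"{matrix.position_tags[c]}{lbl}")
            for c, lbl in enumerate(matrix.position_labels)
        ]
        if include_all_positions
        else None
    )
    for gamma in gammas:
        res = detect_edges(
            matrix,
            gamma,
            p_threshold=p_threshold,
            n_permutations=n_permutations,
            seed=seed,
            significance=significance,
        )
        net = build_network(res.edges)
        out[gamma] = out_degree_distribution(net, all_positions=positions)
    return out


def export_network(net: ImpactNetwork, path: str | Path, format: str) -> None:
    """Write the network as GraphML, Graphviz DOT, or a TSV edge list.

    GraphML and DOT carry impact/dependency on nodes and the probabilities
    and p-value on edges; ``edge_tsv`` round-trips the EdgeRecords exactly
    through :func:`impactnet.impact_core.read_edges_tsv`.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "dot":
        _write_dot(net, path)
    elif format == "edge_tsv":
        write_edges_tsv(net.edges, path)
    else:
        raise ValueError(f"unknown export format {format!r}")


def _write_dot(net: ImpactNetwork, path: Path) -> None:
    # hand-rolled writer: only node/edge attribute lists, no layout hints
    lines = ["digraph impact {"]
    for n, d in net.graph.nodes(data=True):
        lines.append(
            f'  "{n}" [impact={d["impact"]}, dependency={d["dependency"]}];'
        )
    for u, v, d in net.graph.edges(data=True):
        lines.append(
            f'  "{u}" -> "{v}" [p11={d["p11"]:.6g}, p00={d["p00"]:.6g}, '
            f'p_value={d["p_value"]:.6g}, weight=1.0];'
        )
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")


def import_edge_tsv(path: str | Path) -> ImpactNetwork:
    """Rebuild an ImpactNetwork from an exported edge TSV."""
    return build_network(read_edges_tsv(path))
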