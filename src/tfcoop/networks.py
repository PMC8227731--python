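"""Phenotype cooperation networks and their comparison.

Significant TF pairs form an undirected network per phenotype: nodes are
factors, edges carry the pair's z-score.  Hubs are the most-connected nodes
(degree, with deterministic tie-breaks).  Comparing two phenotype networks
partitions their edges into common and phenotype-specific sets and flags
"partner-switching" factors — present in both networks but with no shared
cooperation edge, i.e. the factor pairs with different partners in each
phenotype.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .coop_score import PairKey, PairStatistics

__all__ = [
    "CooperationNetwork",
    "NetworkComparison",
    "build_network",
    "hubs",
    "compare_networks",
    "export_network",
    "export_comparison",
    "read_network_tsv",
]


@dataclass
class CooperationNetwork:
    """TFs as nodes, significant pairs as z-weighted edges, for one phenotype."""

    phenotype: str
    edges: dict[PairKey, float] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for key in self.edges:
            out.add(key.tf_a)
            out.add(key.tf_b)
        return out

    def degree(self, tf: str) -> int:
        return sum(1 for k in self.edges if tf in (k.tf_a, k.tf_b))

    def incident(self, tf: str) -> list[PairKey]:
        return [k for k in self.edges if tf in (k.tf_a, k.tf_b)]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(phenotype=self.phenotype)
        g.add_nodes_from(sorted(self.nodes))
        for key, z in self.edges.items():
            g.add_edge(key.tf_a, key.tf_b, z=z)
        return g


@dataclass(frozen=True)
class NetworkComparison:
    """Edge partition and node overlap between two phenotype networks."""

    phenotype_a: str
    phenotype_b: str
    common_edges: frozenset
    specific_edges_a: frozenset
    specific_edges_b: frozenset
    shared_nodes: frozenset
    switching_nodes: frozenset


def build_network(sig: Sequence[PairStatistics], phenotype: str) -> CooperationNetwork:
    """One z-weighted edge per significant pair; nodes are pair endpoints."""
    net = CooperationNetwork(phenotype=phenotype)
    for s in sig:
        net.edges[s.key] = s.z
    return net


def hubs(net: CooperationNetwork, k: int = 3) -> list[str]:
    """Top-k nodes by degree; ties by summed |z| of incident edges, then name."""
    if k < 1:
        raise ValueError("k must be >= 1")

    def rank_key(tf: str):
        deg = net.degree(tf)
        weight = sum(abs(net.edges[e]) for e in net.incident(tf))
        return (-deg, -weight, tf)

    return sorted(net.nodes, key=rank_key)[:k]


def compare_networks(a: CooperationNetwork, b: CooperationNetwork) -> NetworkComparison:
    """Partition edges into common / specific and find partner-switching TFs."""
    edges_a, edges_b = set(a.edges), set(b.edges)
    common = edges_a & edges_b
    shared = a.nodes & b.nodes
    switching = {
        tf for tf in shared
        if not any(tf in (k.tf_a, k.tf_b) for k in common)
    }
    return NetworkComparison(
        phenotype_a=a.phenotype,
        phenotype_b=b.phenotype,
        common_edges=frozenset(common),
        specific_edges_a=frozenset(edges_a - common),
        specific_edges_b=frozenset(edges_b - common),
        shared_nodes=frozenset(shared),
        switching_nodes=frozenset(switching),
    )


def export_network(net: CooperationNetwork, path: str | Path, format: str = "tsv") -> None:
    """Serialize a network as a GraphML document or a TSV edge list.

    TSV stores z at full precision (``repr``) so edge weights round-trip
    bit-exactly.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif format == "tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["tf_a", "tf_b", "z"])
            for key in sorted(net.edges):
                w.writerow([key.tf_a, key.tf_b, repr(net.edges[key])])
    else:
        raise ValueError(f"unknown format {format!r} (use 'graphml' or 'tsv')")


def read_network_tsv(path: str | Path, phenotype: str = "") -> CooperationNetwork:
    net = CooperationNetwork(phenotype=phenotype)
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            net.edges[PairKey(row["tf_a"], row["tf_b"])] = float(row["z"])
    return net


def export_comparison(cmp: NetworkComparison, path: str | Path, format: str = "tsv") -> None:
    """Serialize a comparison; every edge is labeled with its category."""
    labeled: list[tuple[PairKey, str]] = (
        [(k, "common") for k in cmp.common_edges]
        + [(k, "specific_a") for k in cmp.specific_edges_a]
        + [(k, "specific_b") for k in cmp.specific_edges_b]
    )
    path = Path(path)
    if format == "tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["tf_a", "tf_b", "category"])
            for key, cat in sorted(labeled, key=lambda t: (t[0], t[1])):
                w.writerow([key.tf_a, key.tf_b, cat])
    elif format == "graphml":
        g = nx.Graph(phenotype_a=cmp.phenotype_a, phenotype_b=cmp.phenotype_b)
        for key, cat in labeled:
            g.add_edge(key.tf_a, key.tf_b, category=cat)
        for tf in cmp.switching_nodes:
            g.add_node(tf, switching=True)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {format!r} (use 'graphml' or 'tsv')")
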