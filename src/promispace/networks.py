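"""Ligand-based target networks.

Two network views of compound–target activity data:

* the shared-compound target network — targets are connected when they
  share at least a minimum number of active compounds (default five), with
  edges classified as intra- or inter-family by the targets' family labels;
* the compound–target bipartite network with the compound-side degree
  distribution (how many targets each compound is annotated with).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import MalformedInputError
from .io import TargetProfile

__all__ = [
    "TargetNetwork",
    "BipartiteNetwork",
    "build_target_network",
    "build_bipartite_network",
    "write_graphml",
    "read_target_network_graphml",
    "write_sif",
    "write_degree_distribution_csv",
]


@dataclass
class TargetNetwork:
    """Target co-activity network. Node attribute ``family``; edge attribute
    ``shared_compounds``. Only targets incident to at least one qualifying
    edge appear."""

    graph: nx.Graph
    min_shared: int

    @property
    def intra_family_edges(self) -> int:
        return sum(
            1
            for u, v in self.graph.edges
            if self.graph.nodes[u]["family"] == self.graph.nodes[v]["family"]
        )

    @property
    def inter_family_edges(self) -> int:
        return self.graph.number_of_edges() - self.intra_family_edges


@dataclass
class BipartiteNetwork:
    """Compound–target bipartite network; node attribute ``side`` is
    'compound' or 'target'. ``n_duplicates`` reports dropped duplicate
    interaction rows."""

    graph: nx.Graph
    n_duplicates: int

    @property
    def compound_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["side"] == "compound"}

    @property
    def target_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["side"] == "target"}

    @property
    def degree_distribution(self) -> dict[int, int]:
        """compound degree → number of compounds"""
        dist: dict[int, int] = {}
        for n in self.compound_nodes:
            d = self.graph.degree(n)
            dist[d] = dist.get(d, 0) + 1
        return dict(sorted(dist.items()))


def build_target_network(
    profiles: Sequence[TargetProfile],
    families: Mapping[str, str],
    min_shared: int = 5,
) -> TargetNetwork:
    """Connect targets sharing at least ``min_shared`` active compounds.

    Targets without a family label are classified as "other" with a
    warning. Isolated targets (no qualifying pair) are excluded, matching
    the pair-based reporting convention.
    """
    if min_shared < 1:
        raise MalformedInputError("min_shared must be >= 1")
    compounds_of: dict[str, set[str]] = {}
    for p in profiles:
        for t in p.targets:
            compounds_of.setdefault(t, set()).add(p.compound_id)

    def family_of(target: str) -> str:
        if target not in families:
            warnings.warn(f"target {target!r} has no family label; classified 'other'")
            return "other"
        return families[target]

    g = nx.Graph()
    for t1, t2 in combinations(sorted(compounds_of), 2):
        shared = len(compounds_of[t1] & compounds_of[t2])
        if shared >= min_shared:
            for t in (t1, t2):
                if t not in g:
                    g.add_node(t, family=family_of(t))
            g.add_edge(t1, t2, shared_compounds=shared)
    return TargetNetwork(g, min_shared)


def build_bipartite_network(interactions: Iterable[tuple[str, str]]) -> BipartiteNetwork:
    """Bipartite network mirroring a compound–target interaction set.

    Duplicate interaction rows are dropped and counted.
    """
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    g = nx.Graph()
    for compound, target in interactions:
        if (compound, target) in seen:
            n_dup += 1
            continue
        seen.add((compound, target))
        # side-prefixing keeps a compound and a target with the same raw id apart
        g.add_node(f"c:{compound}", side="compound", label=compound)
        g.add_node(f"t:{target}", side="target", label=target)
        g.add_edge(f"c:{compound}", f"t:{target}")
    return BipartiteNetwork(g, n_dup)


# ---------------------------------------------------------------------------
# exports

def write_graphml(network: TargetNetwork | BipartiteNetwork, path) -> None:
    nx.write_graphml(network.graph, path)


def read_target_network_graphml(path, min_shared: int) -> TargetNetwork:
    g = nx.read_graphml(path)
    # GraphML round-trips ints as ints via typed keys
    return TargetNetwork(g, min_shared)


def write_sif(network: TargetNetwork | BipartiteNetwork, path, relation: str = "shares_compounds") -> None:
    """Simple interaction format: one `source relation target` line per edge."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(network.graph.edges):
            fh.write(f"{u}\t{relation}\t{v}\n")


def write_degree_distribution_csv(network: BipartiteNetwork, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["degree", "n_compounds"])
        for d, n in network.degree_distribution.items():
            writer.writerow([d, n])
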