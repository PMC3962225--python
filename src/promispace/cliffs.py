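"""Promiscuity cliffs: MMPs with large target-count differences.

A promiscuity cliff is a matched molecular pair whose two compounds differ
by at least a threshold number of target annotations (default 50, inclusive)
— a small structural modification causing a large-magnitude change in
promiscuity. Cliffs organize into a network whose nodes are compounds and
whose edges are cliffs; compounds involved in multiple cliffs are
promiscuity hubs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .errors import MalformedInputError, MissingProfileError
from .fragmentation import MatchedMolecularPair

__all__ = [
    "PromiscuityCliff",
    "CliffNetwork",
    "find_cliffs",
    "build_cliff_network",
    "transformation_frequency",
    "write_cliff_csv",
    "read_cliff_csv",
]


@dataclass(frozen=True)
class PromiscuityCliff:
    """An MMP annotated with both compounds' target counts."""

    mmp: MatchedMolecularPair
    t_a: int
    t_b: int

    @property
    def delta(self) -> int:
        return abs(self.t_a - self.t_b)

    @property
    def oriented_transformation(self) -> tuple[str, str]:
        """Substituent exchange oriented from the less to the more
        promiscuous compound."""
        if self.t_a <= self.t_b:
            return (self.mmp.substituent_a, self.mmp.substituent_b)
        return (self.mmp.substituent_b, self.mmp.substituent_a)


@dataclass
class CliffNetwork:
    """Compound-level cliff network; hubs are nodes of degree >= 2."""

    graph: nx.Graph

    @property
    def hubs(self) -> set[str]:
        return {n for n, d in self.graph.degree() if d >= 2}


def find_cliffs(
    mmps: Iterable[MatchedMolecularPair],
    profiles: Mapping[str, int],
    delta_threshold: int = 50,
) -> set[PromiscuityCliff]:
    """MMPs whose target counts differ by at least ``delta_threshold``.

    ``profiles`` maps compound id → target count T (0 allowed for inactive
    compounds). A compound missing from the mapping is an error.
    """
    cliffs: set[PromiscuityCliff] = set()
    for mmp in mmps:
        for cid in (mmp.compound_a, mmp.compound_b):
            if cid not in profiles:
                raise MissingProfileError(f"no target count for compound {cid!r}")
        t_a, t_b = profiles[mmp.compound_a], profiles[mmp.compound_b]
        if abs(t_a - t_b) >= delta_threshold:
            cliffs.add(PromiscuityCliff(mmp, t_a, t_b))
    return cliffs


def build_cliff_network(cliffs: Iterable[PromiscuityCliff]) -> CliffNetwork:
    """Network whose nodes are cliff compounds (annotated with T for color
    mapping) and whose edges are cliffs."""
    g = nx.Graph()
    for c in cliffs:
        g.add_node(c.mmp.compound_a, target_count=c.t_a)
        g.add_node(c.mmp.compound_b, target_count=c.t_b)
        g.add_edge(c.mmp.compound_a, c.mmp.compound_b, delta=c.delta)
    return CliffNetwork(g)


def transformation_frequency(cliffs: Iterable[PromiscuityCliff]) -> dict[tuple[str, str], int]:
    """How often each oriented transformation (low-T → high-T substituent
    exchange) occurs across the cliff set; supports checking whether any
    transformation consistently introduces cliffs."""
    freq: dict[tuple[str, str], int] = {}
    for c in cliffs:
        key = c.oriented_transformation
        freq[key] = freq.get(key, 0) + 1
    return freq


# ---------------------------------------------------------------------------
# exports

_CLIFF_HEADER = [
    "compound_a",
    "compound_b",
    "t_a",
    "t_b",
    "delta",
    "core",
    "substituent_a",
    "substituent_b",
]


def write_cliff_csv(cliffs: Iterable[PromiscuityCliff], path) -> None:
    rows = sorted(
        (
            c.mmp.compound_a,
            c.mmp.compound_b,
            c.t_a,
            c.t_b,
            c.delta,
            c.mmp.core,
            c.mmp.substituent_a,
            c.mmp.substituent_b,
        )
        for c in cliffs
    )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CLIFF_HEADER)
        writer.writerows(rows)


def read_cliff_csv(path) -> set[PromiscuityCliff]:
    out: set[PromiscuityCliff] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _CLIFF_HEADER:
            raise MalformedInputError(f"{path}: expected cliff header {_CLIFF_HEADER}, got {header}")
        for i, row in enumerate(reader, start=2):
            if len(row) != 8:
                raise MalformedInputError(f"{path}: row {i} has {len(row)} fields, expected 8")
            ca, cb, t_a, t_b, _delta, core, sa, sb = row
            out.add(PromiscuityCliff(MatchedMolecularPair(ca, cb, core, sa, sb), int(t_a), int(t_b)))
    return out
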