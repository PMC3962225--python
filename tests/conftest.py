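"""Shared fixtures and independent brute-force oracles.

The oracles re-derive results by exhaustive enumeration (all-pairs
fragment comparison, all-pairs profile intersection) without using the
indexing/grouping machinery they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from promispace.fragmentation import (
    MatchedMolecularPair,
    SizeLimits,
    enumerate_fragmentations,
    passes_size_restrictions,
)
from promispace.io import TargetProfile
from promispace.fixtures import CORE_LIBRARY, SUBSTITUENT_LIBRARY
from promispace._chem import attach


# ---------------------------------------------------------------------------
# oracles

def brute_force_mmps(structures: dict[str, str], limits: SizeLimits) -> set[MatchedMolecularPair]:
    """All-pairs fragment-comparison MMP oracle.

    Compares every fragmentation of every compound pair directly; keeps,
    per unordered pair, the MMP with the largest shared core (ties broken
    by the lexicographically smaller core string).
    """
    frags = {
        cid: [
            f
            for f in enumerate_fragmentations(smi, cid)
            if passes_size_restrictions(f, limits)
        ]
        for cid, smi in structures.items()
    }
    out: set[MatchedMolecularPair] = set()
    for ca, cb in combinations(sorted(structures), 2):
        best = None
        for fa in frags[ca]:
            for fb in frags[cb]:
                if fa.core != fb.core or fa.substituent == fb.substituent:
                    continue
                if abs(fa.substituent_heavy_atoms - fb.substituent_heavy_atoms) > limits.max_exchange_delta:
                    continue
                key = (-fa.core_heavy_atoms, fa.core)
                if best is None or key < best[0]:
                    if fa.substituent <= fb.substituent:
                        mmp = MatchedMolecularPair(ca, cb, fa.core, fa.substituent, fb.substituent)
                    else:
                        mmp = MatchedMolecularPair(cb, ca, fa.core, fb.substituent, fa.substituent)
                    best = ((key[0], key[1]), mmp)
        if best is not None:
            out.add(best[1])
    return out


def brute_force_target_edges(
    profiles: list[TargetProfile], min_shared: int
) -> dict[frozenset[str], int]:
    """Pairwise set-intersection oracle for the shared-compound network."""
    compounds_of: dict[str, set[str]] = {}
    for p in profiles:
        for t in p.targets:
            compounds_of.setdefault(t, set()).add(p.compound_id)
    edges = {}
    for t1, t2 in combinations(sorted(compounds_of), 2):
        shared = len(compounds_of[t1] & compounds_of[t2])
        if shared >= min_shared:
            edges[frozenset((t1, t2))] = shared
    return edges


# ---------------------------------------------------------------------------
# molecule pools

def molecule_pool() -> dict[str, str]:
    """A structurally varied pool: every library core × substituent
    combination, chain-homolog extras that stress the multiple-shared-core
    deduplication path, and fragmentation-free cycloalkanes."""
    from rdkit import Chem

    pool: dict[str, str] = {}
    cores = [c for fam in CORE_LIBRARY.values() for c in fam]
    for i, core in enumerate(cores):
        for j, sub in enumerate(SUBSTITUENT_LIBRARY):
            pool[f"P{i:02d}{j:02d}"] = attach(core, sub)
    for j, sub in enumerate(("[*:1]CC", "[*:1]CCC", "[*:1]CCCC")):
        for i, core in enumerate(cores[:4]):
            pool[f"H{i:02d}{j}"] = attach(core, sub)
    for k, n in enumerate(range(3, 11)):
        pool[f"R{k}"] = Chem.CanonSmiles("C1" + "C" * (n - 2) + "C1")
    return pool


@pytest.fixture(scope="session")
def pool() -> dict[str, str]:
    return molecule_pool()


def sample_structures(pool: dict[str, str], rng: np.random.Generator, n: int) -> dict[str, str]:
    ids = sorted(pool)
    chosen = rng.choice(len(ids), size=min(n, len(ids)), replace=False)
    return {ids[i]: pool[ids[i]] for i in chosen}


# ---------------------------------------------------------------------------
# toy profiles

def profiles_from_counts(counts: dict[str, int]) -> list[TargetProfile]:
    """Profiles with the given T values over a shared target universe."""
    return [
        TargetProfile(cid, frozenset(f"T{i:03d}" for i in range(t)))
        for cid, t in counts.items()
    ]


@pytest.fixture
def toy_profiles() -> list[TargetProfile]:
    return profiles_from_counts({"a": 1, "b": 1, "c": 2, "d": 6})
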