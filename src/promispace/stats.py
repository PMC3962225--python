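"""Promiscuity summary statistics.

Promiscuity rates are averages of the per-compound target count T taken
over *multi-target* compounds only (T ≥ 2): including single-target
compounds would deflate the rate. Threshold probabilities — the chance of a
compound being active against at least two, or more than five, targets —
use *all* compounds in the denominator, including single-target and (for
binary profiling matrices) inactive ones. Stratified variants restrict
profiles to one target family, or bin compounds by molecular weight.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from ._chem import molecular_weight
from .errors import MalformedInputError
from .io import TargetProfile

__all__ = [
    "PromiscuitySummary",
    "MWBinSpec",
    "summarize",
    "summarize_by_family",
    "summarize_by_mw",
    "high_promiscuity_fraction",
    "write_summary_json",
    "read_summary_json",
    "write_distribution_csv",
]


@dataclass(frozen=True)
class PromiscuitySummary:
    """Promiscuity statistics of one compound population.

    rate: mean T over multi-target compounds (None when there are none —
        undefined, never reported as 0).
    p_at_least_2 / p_more_than_5: fractions of all compounds (inactive
        compounds included, when present) with T ≥ 2 / T > 5.
    distribution: histogram of T over all compounds.
    """

    n_compounds_total: int
    n_multi_target: int
    rate: float | None
    p_at_least_2: float
    p_more_than_5: float
    distribution: dict[int, int]


@dataclass(frozen=True)
class MWBinSpec:
    """Molecular-weight bins: left-open intervals (e0, e1], (e1, e2], ...,
    plus an open-ended last bin. Defaults give seven bins of 100 Da from
    (0, 200] up to (700, ∞)."""

    edges: tuple[float, ...] = (0.0, 200.0, 300.0, 400.0, 500.0, 600.0, 700.0)

    def __post_init__(self):
        if any(a >= b for a, b in zip(self.edges, self.edges[1:])):
            raise MalformedInputError("MW bin edges must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        labs = [f"({g:g},{h:g}]" for g, h in zip(self.edges, self.edges[1:])]
        labs.append(f"({self.edges[-1]:g},inf)")
        return labs

    def assign(self, mw: float) -> str:
        """Bin label for a molecular weight; values at an edge fall into the
        lower bin, values beyond the last edge into the open last bin."""
        for g, h in zip(self.edges, self.edges[1:]):
            if g < mw <= h:
                return f"({g:g},{h:g}]"
        return f"({self.edges[-1]:g},inf)"


def _counts(profiles: Sequence[TargetProfile]) -> list[int]:
    return [p.target_count for p in profiles]


def summarize(profiles: Sequence[TargetProfile], n_inactive: int = 0) -> PromiscuitySummary:
    """Promiscuity summary of a profile set.

    ``n_inactive`` adds compounds with T = 0 (rows of a binary matrix with
    no activity) to the distribution and probability denominators; they
    never enter the rate.
    """
    if not profiles and n_inactive == 0:
        raise MalformedInputError("summarize needs at least one profile")
    counts = _counts(profiles)
    total = len(counts) + n_inactive
    multi = [t for t in counts if t >= 2]
    distribution: dict[int, int] = {}
    if n_inactive:
        distribution[0] = n_inactive
    for t in counts:
        distribution[t] = distribution.get(t, 0) + 1
    return PromiscuitySummary(
        n_compounds_total=total,
        n_multi_target=len(multi),
        rate=sum(multi) / len(multi) if multi else None,
        p_at_least_2=len(multi) / total,
        p_more_than_5=sum(1 for t in counts if t > 5) / total,
        distribution=dict(sorted(distribution.items())),
    )


def summarize_by_family(
    profiles: Sequence[TargetProfile],
    target_families: Mapping[str, str],
    family: str,
) -> PromiscuitySummary:
    """Summary restricted to one target family.

    Each compound's target set is intersected with the family's targets;
    the multi-target condition applies within the family. Compounds with no
    target in the family are dropped from the population.
    """
    family_targets = {t for t, f in target_families.items() if f == family}
    if not family_targets:
        raise MalformedInputError(f"no targets annotated with family {family!r}")
    restricted = []
    for p in profiles:
        within = p.targets & family_targets
        if within:
            restricted.append(TargetProfile(p.compound_id, frozenset(within)))
    if not restricted:
        raise MalformedInputError(f"no compound is active against family {family!r}")
    return summarize(restricted)


def summarize_by_mw(
    profiles: Sequence[TargetProfile],
    structures: Mapping[str, str],
    bins: MWBinSpec | None = None,
) -> list[tuple[str, PromiscuitySummary | None]]:
    """Per-molecular-weight-bin summaries.

    ``structures`` maps compound id → SMILES; weights are computed on the
    desalted structure. Every compound lands in exactly one bin; bins with
    no compounds report None. Returned in bin order.
    """
    bins = bins or MWBinSpec()
    by_bin: dict[str, list[TargetProfile]] = {label: [] for label in bins.labels}
    for p in profiles:
        try:
            smiles = structures[p.compound_id]
        except KeyError:
            raise MalformedInputError(f"no structure for compound {p.compound_id!r}")
        by_bin[bins.assign(molecular_weight(smiles, p.compound_id))].append(p)
    return [
        (label, summarize(members) if members else None)
        for label, members in by_bin.items()
    ]


def high_promiscuity_fraction(
    profiles: Sequence[TargetProfile],
    threshold: int,
    n_inactive: int = 0,
) -> float:
    """Fraction of all compounds (inactives included) with T > threshold."""
    if threshold < 1:
        raise MalformedInputError("threshold must be >= 1")
    total = len(profiles) + n_inactive
    if total == 0:
        raise MalformedInputError("no compounds")
    return sum(1 for p in profiles if p.target_count > threshold) / total


# ---------------------------------------------------------------------------
# exports

def write_summary_json(summary: PromiscuitySummary, path) -> None:
    payload = {
        "n_compounds_total": summary.n_compounds_total,
        "n_multi_target": summary.n_multi_target,
        "rate": summary.rate,
        "p_at_least_2": summary.p_at_least_2,
        "p_more_than_5": summary.p_more_than_5,
        "distribution": {str(k): v for k, v in summary.distribution.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_summary_json(path) -> PromiscuitySummary:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return PromiscuitySummary(
        n_compounds_total=payload["n_compounds_total"],
        n_multi_target=payload["n_multi_target"],
        rate=payload["rate"],
        p_at_least_2=payload["p_at_least_2"],
        p_more_than_5=payload["p_more_than_5"],
        distribution={int(k): v for k, v in payload["distribution"].items()},
    )


def write_distribution_csv(summary: PromiscuitySummary, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["target_count", "n_compounds"])
        for t, n in sorted(summary.distribution.items()):
            writer.writerow([t, n])
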