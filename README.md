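# promispace

Mining multi-target activity spaces: compound promiscuity statistics,
matched molecular pairs, promiscuity cliffs, ligand-based target networks,
and Compound Series Matrices.

## The problem

Many pharmaceutically relevant small molecules are *promiscuous*: they act
specifically on several biological targets, which is the molecular basis of
polypharmacology. Given curated compound–target activity data — potency
measurements (K_i or IC50) from medicinal-chemistry sources, or a binary
compound × target profiling matrix — one wants to quantify how promiscuous
compounds are, find small structural changes that cause large promiscuity
changes, and organize structurally related compound series in multi-target
space to generate design hypotheses. `promispace` implements that pipeline
for computational medicinal chemists.

## Methods in brief

* **Curation.** K_i and IC50 data are handled separately; only exact ("=")
  measurements at or below a potency cutoff (default 10 µM) count as
  active; approximate annotations (">", "<", "~") are excluded. Compounds
  are identified by desalted canonical structure; replicate potencies
  collapse to their geometric mean. Each compound gets a target profile
  with target count *T*.
* **Promiscuity statistics.** The promiscuity rate is the mean *T* over
  multi-target compounds (*T* ≥ 2); the probabilities P(T ≥ 2) and
  P(T > 5) use all compounds in the denominator. Both can be stratified by
  target family or molecular-weight bin.
* **Matched molecular pairs (MMPs).** Every acyclic single bond between
  heavy atoms is cut once; (core, substituent) fragments are indexed by
  core, and compounds sharing a core with different substituents form an
  MMP — a single-site chemical transformation — subject to transformation
  size restrictions (substituent ≤ 13 heavy atoms, core ≥ 2× substituent,
  exchange difference ≤ 8).
* **Promiscuity cliffs.** MMPs whose compounds differ by ≥ 50 target
  annotations; organized into a network whose multi-cliff compounds are
  promiscuity hubs.
* **Target networks.** Targets are connected when they share ≥ 5 active
  compounds, with intra-/inter-family edge classification; a bipartite
  compound–target network reports the compound degree distribution.
* **Compound Series Matrix (CSM).** A two-step MMP procedure: MMPs over
  compounds define analog series (one core, many R-groups); MMPs computed
  *over the cores themselves* relate series whose cores differ at a single
  site. Related series become one matrix: rows are cores, columns are
  substituents, filled cells are real compounds colored by *T*, and empty
  cells are virtual compounds — synthesizable design candidates.

A synthetic-fixtures module generates analog grids and binary profiling
matrices with planted ground truth (series, deletions, cliff pairs), so the
entire pipeline is testable without database downloads.

## Worked example

Four compounds in two analog series — toluene and anisole share a phenyl
core, 4-fluorotoluene and 4-fluorocumene a 4-fluorophenyl core — with
toy dopamine/serotonin/adrenergic activities:

```python
from promispace import build_series, build_csms, design_candidates, summarize
from promispace.io import TargetProfile

structures = {
    "tol":  "Cc1ccccc1",         # toluene
    "anis": "COc1ccccc1",        # anisole
    "ftol": "Cc1ccc(F)cc1",      # 4-fluorotoluene
    "fcum": "CC(C)c1ccc(F)cc1",  # 4-fluorocumene
}
target_sets = {"tol": {"D2", "5HT2A"}, "anis": {"D2"},
               "ftol": {"D2"}, "fcum": {"ADRB2"}}

series = build_series(structures)
(matrix,) = build_csms(series, target_sets=target_sets)
print("rows:   ", matrix.rows)
print("columns:", matrix.columns)
print(sorted(matrix.virtual_cells))
print([c.smiles for c in design_candidates(matrix, "CC(C)[*:1]")])

profiles = [TargetProfile(c, frozenset(t)) for c, t in target_sets.items()]
s = summarize(profiles)
print(f"rate={s.rate}  P(T>=2)={s.p_at_least_2}  P(T>5)={s.p_more_than_5}")
```

prints

```
rows:    ['c1ccc([*:1])cc1', 'Fc1ccc([*:1])cc1']
columns: ['C[*:1]', 'CO[*:1]', 'CC(C)[*:1]']
[('Fc1ccc([*:1])cc1', 'CO[*:1]'), ('c1ccc([*:1])cc1', 'CC(C)[*:1]')]
['CC(C)c1ccccc1']
rate=2.0  P(T>=2)=0.25  P(T>5)=0.0
```

The two series merge into one 2×3 CSM because their cores are a
core-level MMP (H → F at the para position). Four cells are real, two are
virtual; asking for design candidates in the isopropyl column reassembles
the missing phenyl + isopropyl compound, cumene. The promiscuity rate is
2.0 (toluene is the only multi-target compound, with two targets), and one
of four compounds is active against at least two targets.

## Command line

```sh
promispace simulate --out fixture --seed 5            # synthetic dataset
promispace rates   --input fixture/activities.csv --out rates_out
promispace csm     --input fixture/activities.csv --out csm_out
promispace cliffs  --input matrix.csv --out cliff_out --delta-threshold 50
promispace network --input fixture/activities.csv --out net_out --min-shared 5
```

Every run writes its artifacts plus a `manifest.json` with the tool
version, resolved configuration, and input digests.

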