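# Methods

## Scope and data model

`promispace` analyzes compound promiscuity — the specific activity of one
compound against multiple targets — from two kinds of input: long-format
potency tables (K_i or IC50, nM, with relation symbols) and wide binary
compound × target profiling matrices. The central per-compound quantity is
the target count *T*, the number of distinct targets with at least one
qualifying activity.

## Curation rules

* K_i and IC50 measurements are never pooled: `curate` selects one
  measurement type, mirroring the convention that equilibrium constants and
  assay-dependent IC50 values are analyzed as separate subsets.
* Only exact measurements (relation "=") survive; approximate annotations
  (">", "<", "~") are excluded outright rather than clamped.
* Activity requires potency ≤ 10 µM (10 000 nM) by default. The cutoff is
  a parameter.
* Compound identity is the desalted canonical SMILES (largest covalent
  unit, RDKit canonicalization). Input ids mapping to the same structure
  are merged with the union of their activities; the lexicographically
  smallest id represents the group, and the merge map is retained.
* Replicate measurements for one compound–target pair collapse to their
  geometric mean — potencies are log-scaled quantities, and activity
  status only requires one qualifying measurement, so the choice of
  aggregate does not affect any target count.

Curation is idempotent and row-order invariant; an empty post-filter result
raises rather than returning an empty container.

## Promiscuity statistics

The promiscuity rate is mean *T* over compounds with *T* ≥ 2. Excluding
single-target compounds is deliberate: including them would deflate the
average, and the rate is meant to describe the promiscuous subpopulation.
With no multi-target compounds the rate is undefined (`None`), never 0.
Threshold probabilities P(T ≥ 2) and P(T > 5) are computed over *all*
compounds; for binary matrices, all-zero rows count as inactive compounds
in the denominator and in the *T* histogram but never in the rate.

Family-restricted summaries intersect each compound's targets with the
family's targets and apply the multi-target condition within the family;
compounds with no target in the family are dropped from the population
(the statistic describes compounds active against that family). MW-binned
summaries use seven left-open bins, (0, 200], (200, 300], … (700, ∞);
only the first boundaries are canonical in the literature, the remaining
edges continue the evident 100-Da progression and are configurable. Edge
values fall into the lower bin; nothing is ever dropped silently.

## Fragmentation and matched molecular pairs

Single-cut fragmentation: every acyclic single bond between two heavy atoms
is cut once; ring bonds and bonds to hydrogen are never cut. Fragments are
canonicalized with a wildcard attachment token (`[*:1]`). The larger
fragment is the core, the smaller the substituent (ties broken
lexicographically on the canonical strings) — consistent with the size
restriction, which demands the core be at least twice the substituent.

Default transformation size restrictions: substituent ≤ 13 heavy atoms,
core ≥ 2 × substituent heavy atoms, exchanged-substituent size difference
≤ 8 heavy atoms. The conventional restrictions of this methodology line;
all three are configurable through `SizeLimits`.

MMP generation indexes size-admissible fragmentations by core; two
compounds sharing a core with distinct substituents form an MMP. When a
pair shares several cores, only the MMP with the largest core is kept (the
most conservative transformation; ties broken by the lexicographically
smaller core string), so each unordered compound pair yields at most one
MMP. Transformations are ordered lexicographically by substituent string,
which makes stored pairs unique and exports diff-stable. An exhaustive
all-pairs comparison oracle in the test suite verifies the indexed
implementation exactly on randomized compound sets.

Core-level MMPs (the second fragmentation round) treat cores as molecules:
the existing `[*:1]` marker is an inert atom that is never cut and does
not count as heavy; new cuts carry `[*:2]`. At this level, hydrogen
substituents are additionally enumerated (one per distinct H-bearing
position), so that cores differing by an H→R replacement — e.g. phenyl
vs. 4-methylphenyl — are related. Hydrogen enumeration is deliberately
absent at the compound level, where the cut-bond definition alone governs
(benzene has no fragmentations). Fragments from the second round are never
fragmented again; exactly two rounds exist, enforced structurally.

## Promiscuity cliffs

A promiscuity cliff is an MMP with |T_a − T_b| ≥ 50. The comparison is
inclusive ("50 or more"). The cliff network has compounds as nodes
(annotated with *T* for color mapping) and cliffs as edges; hubs are nodes
of degree ≥ 2. Transformation frequencies are counted with the exchange
oriented from the less to the more promiscuous compound; ties cannot occur
inside a cliff with any positive threshold.

## Target networks

The shared-compound target network connects two targets when at least five
compounds (configurable) are active against both. Targets without a
qualifying edge are excluded from the node set, matching pair-based
reporting. Edge weights (shared counts) are retained in exports so the
network can be re-thresholded without recomputation. Edges are classified
intra- or inter-family by the endpoint family labels; unlabeled targets
become "other" with a warning. The bipartite compound–target network
mirrors the interaction set exactly (duplicates dropped and counted) and
reports the compound-side degree distribution; compound and target node
namespaces are prefixed so identical raw ids cannot collide.

## Compound Series Matrices

Analog series are defined from compound-level MMPs: every core occurring in
at least one MMP collects all compounds fragmenting to it under the size
restrictions (a compound may join several series through different cores).
Series are merged into one CSM when their cores belong to the same
connected component of the core-level MMP graph; components are the
minimal grouping under which all rows of a matrix are transitively related
by single-site core changes, and they partition the series, so each series
appears in exactly one CSM. Components with a single core produce no
matrix.

Rows (cores) and columns (substituents) are ordered by heavy-atom count,
then lexicographically — deterministic, diff-stable exports. Each real
cell holds exactly one compound (a collision indicates an upstream
deduplication failure and raises); real and virtual cells tile the full
grid. Cell "color" is the raw target count; mapping counts to an actual
color spectrum is a rendering concern left to consumers of the JSON/CSV
exports.

Promiscuous submatrix extraction keeps real cells with *T* ≥ a threshold,
drops empty rows/columns, and recomputes virtual cells on the reduced
grid. Design candidates for a column are the virtual cells' core +
substituent reassemblies (RDKit `molzip` at the attachment points);
chemically invalid reassemblies are skipped with a warning, never
silently.

## Synthetic fixtures

The generators emulate the *structure* of curated activity collections at
desk scale; they make no attempt to mimic real chemical space beyond what
the pipeline's correctness depends on.

**Analog grids.** Cores come from scaffold families (benzene, pyridine,
thiophene, naphthalene); within a family, cores differ from the base
scaffold by a fluorine at varying ring positions. This choice is
load-bearing: H→F differences are invisible to compound-level
fragmentation (no H cuts there), and F positional isomers never produce
equal fragments, so no two compounds share an unplanned core — while at
the core level, F-cuts and H-cuts relate every decorated core to its base
scaffold, making each family one connected component by construction. The
substituent library (methyl, hydroxy, amino, cyano, methoxy, isopropyl,
dimethylamino, cyanomethyl) is chosen with pairwise-distinct inner
structure; chain homolog sets like methyl/ethyl/propyl are excluded
because cutting inside the longer homolog creates an alternative, larger
shared core (e.g. the benzylic core shared by ethyl- and propylbenzene)
that would legitimately displace the planted core under the largest-core
rule. The oracle-equivalence tests *do* include such homologs to exercise
that path; the planted-grid generator avoids them so its ground truth
stays exact.

Deletions are seeded-random over grid cells, constrained to leave at least
two compounds per series. Target counts follow a zero-truncated geometric
distribution (default p = 0.6: ~40% multi-target compounds, mean rate
≈ 2.7 over the multi-target subset), matching the heavy single-target skew
of curated potency data; targets are partitioned into five named families.
Potencies are log-uniform in [1 nM, 10 µM).

**Binary matrices.** Planted cliff pairs are genuine MMP partners (one
scaffold core, methyl vs. methoxy) with target counts differing by exactly
the requested delta; each pair uses a distinct core, so pairs never
interact. Background compounds are cycloalkanes of distinct ring sizes:
they contain no acyclic bonds, hence have no fragmentations and provably
cannot form MMPs — false-positive cliffs among the background are
structurally impossible, which is exactly what the recovery test needs to
demonstrate about the detector, not about the chemistry. Background
activity is i.i.d. Bernoulli per cell (default rate 0.02 on 100 targets,
a mostly-inactive matrix).

What passing these tests shows: the machinery (indexing, grouping,
bookkeeping, thresholds) is exact. What they do not show: behavior on
real, structurally diverse chemistry with ambiguous series membership,
tautomers, stereochemistry, or measurement noise — all outside the
generators' vocabulary.

## Problem sizes and determinism

The shipped studies use desk-scale sizes chosen to make every planted
property checkable by exhaustive comparison: grids of 8 cores × 6
substituents (~34 compounds after 20% deletion), binary matrices of 60
compounds × 100 targets (five planted cliffs, ≥ 1000 background pairs),
and oracle trials over 50 random sets of ≤ 30 compounds. The
acceptance-script network study uses a denser profile distribution
(p = 0.45, ten targets) because it reports the network over promiscuous
compounds, where shared-compound counts must plausibly reach the
five-compound edge threshold. All randomness flows from
`numpy.random.default_rng(seed)`; identical seeds give byte-identical
artifacts.

## Known limitations

* Single-cut MMPs only: compounds whose series membership requires double
  cuts (two variable positions) are not grouped.
* No stereochemistry or tautomer handling at the cut bond; attachment
  points are plain wildcards.
* Hydrogen replacements are related only at the core level, so an H→F
  analog pair is not a compound-level MMP here.
* The per-pair MMP convention (largest shared core) means re-thresholding
  series at a different granularity requires regeneration.
* `summarize_by_family` drops compounds with no target in the family;
  populations are therefore family-conditional and not comparable across
  families without care.
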