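# Methods

## The model

The analysis treats drug safety as a population-level network property.
Two bipartite drug–target graphs are built from interaction records — one
for approved, one for withdrawn drugs — and compared on a panel of
whole-graph metrics. The working hypothesis embodied in the pipeline: a
withdrawn-drug population is sparser (fewer targets per drug, more drugs
with no annotated target) and more centralized (interactions concentrated
on few targets) than the approved population, and an approved drug or an
unannotated natural product that *structurally* resembles a withdrawn drug
while sitting in the withdrawn drugs' target neighborhood deserves
pharmacovigilance attention.

All graphs are simple and undirected. Edges only ever join nodes of
different roles (drug/target, or drug/effect in the adverse-event network),
so no self-loops or parallel edges can arise; both are nevertheless
reported in the topology panel (always 0) because the panel mirrors what a
general graph tool would print. Isolated drug nodes are first-class
observables and are preserved; targets with no interaction never enter a
network, since they carry no information here.

## Topology panel: definitions and disconnected-graph conventions

Drug–target networks are routinely disconnected, so every distance-based
metric is defined over finite distances only:

* **shortest_paths** — number of ordered node pairs in the same component,
  `Σ_components n_i(n_i − 1)`;
* **characteristic path length** — mean distance over those pairs;
* **diameter** — maximum finite distance;
* **radius** — minimum within-component eccentricity over *non-isolated*
  nodes. Isolated nodes would trivially report eccentricity 0; excluding
  them makes "radius 1" mean what a practitioner expects — some hub reaches
  its whole component in one hop.

Degree-derived metrics: density `2E/(N(N−1))`; mean degree `2E/N` (the two
are linked by `density = mean_degree/(N−1)`, used as an internal
cross-check and exposed as `density_from_mean_degree`); heterogeneity is
the coefficient of variation of degree using the **population** standard
deviation (the convention of the common network-analysis tools this panel
mirrors); centralization is Freeman's degree centralization
`(N/(N−2))(k_max/(N−1) − density)`, which is 1 for a star and 0 for any
regular graph, and is reported as 0 with a warning when `N < 3` (the
formula is undefined there). Mean clustering averages the local triangle
fraction over *all* nodes, counting degree-<2 nodes as 0; on any bipartite
graph it is identically 0, which doubles as a construction check.

Drug degrees are binned into `≤2, (2,4], (4,6], (6,20], >20`, closed on the
right (a degree-2 drug falls in the first bin). The degree table's
"mean ± sd" uses the **sample** sd (ddof = 1), as printed degree tables
usually do; the distinction from the population sd used inside
heterogeneity is deliberate and only matters for tiny networks.

One caveat documented rather than hidden: under the finite-distance
convention, adding an edge that merges two components can *increase* the
characteristic path length (new, long finite pairs appear), so CPL
monotonicity under edge addition holds only on connected graphs and is
tested there.

## Centralities

Computed on the largest connected component (ties broken toward the
component containing the lexicographically smallest node id, so extraction
is deterministic and idempotent). The set: degree, eccentricity, closeness
`1/Σd` (with the averaged `(N−1)/Σd` variant emitted alongside),
unnormalized shortest-path betweenness with fractional credit for tied
paths and endpoints excluded, and eigenvector centrality scaled to max 1.

Eigenvector centrality is computed by power iteration with a uniform start
vector, tolerance 1e−10 (max-norm on the normalized iterate), capped at
10 000 iterations — on the **shifted** matrix `A + I`. The shift matters:
bipartite adjacency spectra are symmetric (`±λ_max`), so plain power
iteration oscillates between the two extreme eigenvectors; adding the
identity leaves all eigenvectors unchanged while making the Perron root
strictly dominant, so the iteration converges on every connected graph.

The target-set comparison between the two cores partitions target ids into
common/exclusive sets, annotates each common target with its degree in both
cores (high–high: crowded, historically risky targets; low–low: deserted
ones), and marks the common targets that are articulation points of a core
— removing one disconnects that graph, the operational reading of a
connectivity "bottleneck".

## Fingerprints and similarity

Tanimoto similarity `c/(a+b−c)` is computed on binary vectors; a pair of
all-zero fingerprints is defined as similarity 0 with a warning (no
evidence either way, and the 0/0 form should not crash a batch run).
`1 − tanimoto` is the Jaccard distance, a metric, which the tests verify on
random samples.

Structure-derived fingerprints use a hashed linear-path scheme: all linear
bond paths of 1–7 bonds, 2 bits per hashed path, 1024 bits (RDKit's
implementation of the classic Daylight-style scheme). SMILES are
canonicalized on ingest, so spelling variants of one molecule always map to
one fingerprint. Because commercial fingerprint schemes are not bit-exactly
reproducible and the pipeline's logic is scheme-agnostic, precomputed
fingerprints are accepted from a plain `id TAB bitstring` file and are the
primary interchange format; the similarity cutoff (default 0.7) is applied
**strictly** (`>`) by default, with an inclusive flag where the boundary
case should count.

## Pipeline conventions

Probe selection keeps withdrawn drugs with more than `min_neighbors = 8`
*distinct* approved partners in the shared-target network (strict
boundary: exactly 8 is excluded). Flagging compares each probe only against
its own shared-target partners, whereas natural-product triage compares
every compound against *all* drugs of both statuses; the asymmetry is
intentional — approved drugs carry target annotations that justify the
network restriction, natural products generally do not. Missing
fingerprints skip the affected pair with a log line rather than aborting:
a batch triage should degrade, not die, when a structure fails to parse.
Flag reports are canonically ordered (probe id, descending similarity,
partner id), making them invariant to input order. Percentages are rounded
half-up — 2 decimals for class/isolation percentages, 1 for market-status
proportions — matching how such tables are printed.

## Synthetic data: what it emulates, what it does not

The generator (`pvnet.synthetic_data`) produces DrugBank-shaped inputs
whose *statistics* match the study conditions: 1411 approved / 66 withdrawn
drugs; isolated fractions 9.28% / 34.85% (which at those sizes round to
exactly 131 and 23 drugs); five-bin degree profiles (37.42/30.26/11.91/
18.57/1.84 for approved, 59.09/16.67/12.12/12.12/0 for withdrawn) sampled
uniformly within bins after the isolated share is removed from the lowest
bin; 106 vs 1478 targets with 28 shared; interactions attach preferentially
to a hub subset (10× weight) headed by the shared targets, so hub and
bottleneck structure exists and the derived drug-drug network is
non-trivial; and a 2156-compound natural-product library.

Planted structure gives every downstream stage an exact ground truth:
probe withdrawn drugs wired through dedicated shared hubs to 12 approved
partners each; flag pairs planted at Tanimoto 0.85 (a base fingerprint
plus `m ≈ k(1−t)/t` extra bits, hard error if the target similarity is
unreachable within ±0.02 at the configured sparsity); natural products
planted into the four triage classes at configurable counts (defaults
1092/1/75, remainder background). Background fingerprints are independent
5%-sparse random vectors whose pairwise Tanimoto stays far below 0.7, so
recovery is exact by construction — which is precisely what the end-to-end
tests assert. One integer seed drives a single random stream; identical
configurations are byte-identical on disk.

What the generator does **not** emulate: real chemistry (synthetic
fingerprints are not derived from molecules), correlated target profiles,
fingerprint bit correlations, degree–similarity coupling, or curated
withdrawal reasons (market-status annotations are user-supplied or
rng-assigned and labelled synthetic). Passing tests therefore demonstrate
the correctness of the machinery and the recoverability of well-separated
signal, not the effect size the method would achieve on a real database
snapshot; the published absolute network statistics depend on a specific
snapshot and are not reproduction targets here, except where they are pure
arithmetic on printed counts (isolated percentages, density from node count
and mean degree, class proportions), which the acceptance script recomputes
exactly.

## Numerical and degenerate-input choices

* Rounding is half-up via decimal string representation (banker's rounding
  would flip printed ties).
* Empty graph: all metrics 0, no exceptions; a single drug table row with
  unknown status is skipped and logged, a duplicate id is a hard error.
* SDF ingest: V2000 only (V3000 records are rejected per record with a
  clear reason), molecule blocks that fail to parse or lack the id
  property are skipped and counted, never fatal.
* Degenerate Tanimoto (both empty) is 0 with a warning; ragged fingerprint
  lengths are hard errors everywhere.
* Problem sizes: drivers and the acceptance script run the full published
  scale (≈2 900 + 170 nodes, 2 156 × 1 477 similarity matrix) in seconds;
  tests use a scaled-down configuration (120/30 drugs, 512-bit
  fingerprints) with the same planted structure.

## Known limitations

* The radius and the disconnected-graph conventions are declared, not
  validated against any external tool's output on the original data.
* Fingerprint planting manipulates bit vectors directly; conclusions about
  chemistry require real structures through `path_fingerprint`.
* Betweenness on the full approved core (~2 700 nodes) takes ~20 s; the
  library does not parallelize it.
* A drug present in both input drug lists is kept in both networks but
  dropped from the derived drug-drug network (no self-pairing); overlap
  handling beyond that is out of scope.
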