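# Methods

## Model and procedure

`flowregions` treats regional care-network delineation as community
detection on weighted undirected flow graphs.

**Phase 1 (admission flows).** Nodes are residential zip units and
hospitals; the weight between zip `z` and hospital `h` is the number of
eligible *index* encounters of residents of `z` admitted to `h`.
Receiving legs of linked transfers are excluded so a transferred patient
contributes exactly one home→initial-hospital encounter; the phase-1
total weight therefore equals the index-encounter count. Zip units or
hospitals with no encounters are excluded by default (an option re-adds
them as isolated nodes).

**Phase 2 (transfer flows).** Nodes are the phase-1 communities; the
weight between two communities is the number of transfer pairs between
them, both directions summed (the modularity objective is undirected).
Within-community transfers are kept as self-loops so the phase-2 total
weight equals the transfer-pair count. A final region label of any zip or
hospital is the phase-2 label of its phase-1 community; phase-1
communities untouched by transfers remain standalone regions. Final
labels are renumbered by descending encounter volume for stable
reporting.

**Modularity convention.** For a partition `{c_i}`,
`Q = Σ_c [W_c/m − (K_c/2m)²]`, with `W_c` the intra-community weight
(each undirected edge once, self-loops once), `K_c` the summed node
strengths, and `m` the total weight. A self-loop of stored weight `w`
adds `2w` to its node's strength and `w` to `m`, so `Σ k_i = 2m` always.
This is the convention under which collapsing a community into a
super-node with a self-loop leaves `Q` exactly unchanged — the property
the Louvain aggregation phase depends on, asserted to 1e−12 in the test
suite. Under it, a loop-free graph in a single community scores exactly
0, two disconnected unit triangles split into triangles score 0.5, and a
single unit edge with singleton endpoints scores −0.5.

**Louvain.** All nodes start as singleton communities. Each pass visits
nodes in a seeded random order and re-assigns each to the neighboring
community with the largest positive modularity gain, computed
incrementally as `ΔQ = w_{i→c}/m − k_i·Σ_tot(c)/(2m²)` for an isolated
node joining `c` (the incremental gain is property-tested against full
recomputation to 1e−9). When a sweep makes no move, communities are
collapsed to super-nodes and the procedure recurses, stopping when a
full cycle improves `Q` by at most `min_gain`. Per-level `Q` is
non-decreasing by construction.

Numerical and determinism choices:

| choice | value | rationale |
| --- | --- | --- |
| resolution parameter | fixed at 1 | the objective has none |
| `min_gain` | 1e−10 (absolute) | float-safe convergence |
| gain tie-break | keep current community, else smallest label | determinism |
| sweep order | seeded shuffle per pass | reproducible, restartable |
| restarts | 5 by default (20 in oracle tests), best `Q` kept | order-dependence variance |
| strict-improvement epsilon | 1e−15 | avoid oscillating on float ties |

A brute-force maximizer (`brute_force_best_partition`) enumerates all
set partitions for graphs of ≤ 10 nodes (Bell-number guarded) and is the
independent optimality oracle: Louvain must never exceed it and matches
it on ≈ 98–99% of 200 random 4–8-node weighted graphs with 20 restarts.

**Degenerate inputs.** Zero-total-weight graphs raise an explicit
error (modularity is undefined at `m = 0`). A single node carrying all
weight in a self-loop scores `Q = 0`. Zero transfers make phase 2
degenerate: the final regions are the phase-1 communities, logged.

## Cohort and transfer linkage

Eligibility: age ≥ 18, nonelective, admitted from home, condition among
the eligible labels. Rules are applied in that sequence and each
excluded row is counted against the first rule it violates; the counts
are logged and attached to the result. Dates are integer day indices —
the linkage rule only needs day arithmetic.

Transfer linkage scans each patient's encounters in time order
(admission day, discharge day, encounter id). An encounter is a receiver
if some *earlier-sorted* encounter at a different facility was
discharged 0–1 days before its admission; among candidates the sender
with the latest discharge, then smallest facility id, wins. Each
receiver links at most once; chains A→B→C yield (A,B) and (B,C).
Restricting senders to earlier-sorted encounters resolves the ambiguity
of fully simultaneous pairs (both legs admitted and discharged the same
day), which would otherwise link in both directions. Encounters flagged
as transfers but lacking an adjacent sender are reported, not linked.

## Evaluation battery

For a partition of zips and hospitals, per region `r` over index
encounters: LI = (residents of `r` treated in `r`)/(residents of `r`);
MSI = (patients treated in `r` living elsewhere)/(patients treated in
`r`); NPF = incoming/outgoing (undefined and flagged when outgoing is
zero, as are LI/MSI for regions with no residents/patients).
Connectivity counts transfer pairs with both endpoints inside `r`.
Bookkeeping identities — Σ residents·(1−LI) = Σ treated·MSI (each
boundary crossing counted once from either side) and connectivity sum +
crossings = total pairs — are asserted on random fixtures.

Compactness is the corrected perimeter–area ratio `P/(2√(πA))` of the
region's footprint (union of member zip polygons, all boundary rings
counted): scale-invariant, 1 for a disc, 2/√π ≈ 1.128 for a square,
larger for more ragged shapes. Scale invariance is what makes the ratio
"corrected"; absolute values are comparable only between shapes, not
with other compactness conventions.

Reclassification anchors each reference region at its *central transfer
hub* — the member hospital with the largest transfer degree (ties:
larger encounter volume, then smaller id; "hub" is otherwise not a
standardized notion, so this definition is documented rather than
assumed). The reference region is matched to the detected region
containing its hub; members detected elsewhere count as reclassified,
as raw hospital shares and as encounter- and transfer-volume-weighted
shares, summarized by mean/median/IQR across reference regions plus the
overall reclassified-hospital percentage.

Mann-Whitney U compares per-region metric distributions between methods:
exact enumeration when both samples are small (min n ≤ 8) and tie-free,
otherwise the normal approximation with midranks, tie correction and
continuity correction (delegated to `scipy.stats.mannwhitneyu`).
Percentages in reports are rounded half-up to two decimals.

## Synthetic health systems

The generator emulates the *structure* of statewide encounter data
without reproducing any real records. Geography is a grid of unit-square
zip cells in `n_communities` contiguous horizontal blocks, so adjacent
communities share a boundary and footprint geometry has closed-form
area/perimeter. Hospitals occupy distinct cells; volumes are drawn from
a Zipf(2) tail with the top hospital inflated past the rest of its block
combined, guaranteeing one dominant transfer hub per community (real
volume distributions are heavy-tailed, but no published distributional
facts pin the tail index — this is the package's choice).

Encounters draw a uniform home zip; the destination hospital is
volume-proportional within the home community with probability
`1 − mixing_mu`, else volume-proportional outside it. A fraction
`transfer_rate` of clean index encounters gains a linked second
encounter at a different facility 0–1 days after discharge, routed
volume-proportionally within the sending hospital's community
(probability `1 − transfer_mixing`) or outside it. A `dirty_fraction`
(default 2%) of rows violates exactly one eligibility rule to exercise
the filters. The planted sending encounter id is carried in a
`transfer_src` column as ground-truth annotation only.

Defaults define the benchmark system used throughout the tests: 4
communities × 25 zips × 3 hospitals, 50 000 encounters, `mixing_mu`
0.02, `transfer_rate` 0.01 (statewide EGS transfer shares run ≈
0.8–1.2%), `transfer_mixing` 0.02, reference perturbation 0.25. Each
output table has its own RNG stream derived from the seed, so enlarging
the encounter count never changes the geography; identical config and
seed give byte-identical CSV/GeoJSON outputs.

The reference partition (legacy-regionalization analogue) relabels a
fixed count `round(reference_perturbation · n_zips)` of zip units to the
community of the nearest other-community centroid; hospitals inherit
their host zip's label.

What the generator does **not** emulate: real ZCTA shapes and population
density (cells are uniform squares, so compactness comparisons against
real-world values are not meaningful), diagnosis coding (conditions are
abstract labels with a skewed frequency mix), demographic covariates,
payer structure, cross-border flows, hospital closures/openings, and
distance-decay in destination choice beyond the community structure
itself. Transfer legs are generated with a "home" admission source so
the eligibility filter retains them for linkage; in real data receiving
legs are often coded as facility transfers and cohort construction would
treat them upstream. Passing tests therefore demonstrate correctness of
the algorithms and bookkeeping under known structure — not that detected
regions on real data would match any published regionalization.

## Problem sizes

The test suite and acceptance script run the benchmark system (50 000
encounters, 112 graph nodes) over 10 seeds, 200 oracle graphs of 4–8
nodes, and 100 random metric fixtures — sizes at which the exhaustive
partition enumeration and repeated end-to-end runs stay comfortable on a
single CPU while leaving every planted effect detectable. Statewide
analyses (10⁵–10⁶ encounters, thousands of zips) run through the same
code paths; the Louvain implementation is pure Python over dict
adjacency and handles the phase-1 graphs of such cohorts (tens of
thousands of edges) in seconds.

## Known limitations

* Louvain is a greedy heuristic: restarts reduce but do not remove
  order-dependence, and no exact replication of any particular igraph
  run is attempted (restart counts and RNG handling of other
  implementations are unspecified).
* Communities merged in an aggregation step can never split later
  (inherent to Louvain; refinement variants are out of scope).
* The hub definition and the self-loop convention are documented choices
  where the field's usage varies.
* Mann-Whitney p-values with very few regions per method are coarse;
  exact enumeration is used where valid, but power is inherently low.
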