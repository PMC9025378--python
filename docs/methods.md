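# Methods

This note documents the models and procedures phyllocore implements,
the parameter choices that matter, and the assumptions behind the
synthetic-data generator — in that order. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Data model

The universal input is an abundance table of non-negative integer read
counts, taxa × samples, each taxon carrying a taxonomy string. Counts
must be integers: relative-abundance inputs are rejected, because every
downstream normalization (relative abundance, Hellinger, binarization)
assumes reads. Files are plain TSV with taxa as rows (the common OTU
table orientation); a flag transposes sample-as-row files. Taxonomy
strings are parsed from three dialects — UNITE `k__…;p__…;g__…`
prefixes, plain binomials, single genus names — while placeholder
labels such as `Ascomycota sp. 52-1` are deliberately kept opaque:
no rank is guessed from them and the raw string survives any round
trip, since such labels are load-bearing identifiers in metabarcoding
studies. The display filter `filter_taxa_by_total` keeps taxa with
strictly more than the cutoff's reads ("more than 100 reads" means
101+), and is idempotent and monotone in the cutoff.

## Dissimilarities, ordination, dispersion

Bray–Curtis is computed on raw counts by default; Hellinger-transformed
input is an explicit option rather than the default because the index
is conventionally reported on the abundance table itself. Jensen–
Shannon divergence uses base-2 logarithms (bounded [0, 1], the
convention 0·log 0 = 0) and no square-root metric variant.

PCoA is classical scaling: eigendecomposition of the double-centred
−½D² matrix, axes ordered by decreasing eigenvalue, coordinates
returned only for eigenvalues above 1e−10 relative tolerance, negative
eigenvalues reported but excluded from coordinates. On Euclidean-
embeddable input the embedding reconstructs the distances to 1e−8
(verified against scikit-bio's implementation in the tests).

PERMDISP embeds the samples by PCoA retaining negative-eigenvalue axes
as "imaginary" coordinates — a sample's squared distance to its group
centroid is the real-axis contribution minus the imaginary-axis
contribution, floored at zero (the standard correction for
non-Euclidean dissimilarities). Group spread is summarized by the
one-way ANOVA F statistic on the centroid distances; significance comes
from `n_perm` (default 999) random permutations of the group labels
with centroids recomputed per permutation, and
p = (1 + #{F\* ≥ F}) / (1 + n_perm), so p is never exactly zero and is
bit-reproducible given the seed. Centroids (not spatial medians) are
used. When the centroid distances are constant to 1e−12, F is defined
as 0. Under an exchangeable null this permutation scheme is exact up to
Monte-Carlo error; the acceptance run measures a rejection rate near
0.05 over 500 null datasets and power ≥ 0.9 against a 3× dispersion
ratio at n = 20 per group.

The Spearman screen ranks taxa by total abundance (ties broken by
taxon id), takes the top k (default 100, the usual display cutoff),
ranks each taxon's values with average ranks, and computes all pairwise
correlations as Pearson on ranks with two-sided p from
t = ρ√((n−2)/(1−ρ²)). The t-approximation is used because exact
permutation is infeasible at the sample sizes involved (15–45) and the
approximation error is negligible beyond n ≈ 20. Default α = 0.01 on
raw p-values, with Benjamini–Hochberg available; constant taxa are
excluded and reported as diagnostics rather than errors. The antagonism
screen restricts the same machinery to a candidate set (typically the
strict core), returning only pairs with ρ < 0 and p < α, most negative
first.

## Similarity networks and the critical network

A [0, 1] dissimilarity matrix maps to integer percent similarity
S = round((1 − d)·100). Rounding of halves defaults to half-up (the
spreadsheet convention of the programs these matrices usually come
from); half-even is available. One graph is built per threshold
t = 0…100 with an edge wherever S ≥ t — the comparison is inclusive, so
a pair at exactly the threshold is connected — and isolated nodes are
retained so sample counts are conserved. Edge sets are nested in t, and
the per-step drops telescope exactly to |E(G₀)| − |E(G₁₀₀)|.

Three network-distance curves over the sweep are offered, recorded in
the sweep's `method` tag for provenance:

* **component** (default): D(t) = |R(G_t) Δ R(G_{t+1})| / C(n,2), where
  R(G) is the set of node pairs in the same connected component. This
  is the percolation reading of "most distant network": losing a
  redundant edge inside a well-connected cluster scores zero, while the
  step at which the network fragments scores every pair it separates.
  It is the default because critical-network selection is about finding
  the structural transition: on a two-block matrix with even blocks the
  fragmentation step separates all cross-block pairs at once (25 of 45
  for 10 nodes), strictly more than any within-block collapse can move
  (at most 20), which makes planted-block recovery deterministic —
  whereas the largest *edge*-drop step depends on how the integer
  similarity values happen to spread across adjacent thresholds and
  lands inside the planted gap only sporadically.
* **consecutive**: the same construction on raw edge sets,
  D(t) = |E(G_t) Δ E(G_{t+1})| / C(n,2).
* **from_initial**: D(t) = |E(G₀) Δ E(G_t)| / C(n,2), monotone in t.

The critical threshold t\* attains the curve's maximum (smallest such t
on ties); the critical graph is G_{t\*+1} for the step-wise methods
(the sparser network just after the largest drop) and G_{t\*} for
`from_initial`. A flat all-zero curve is flagged degenerate and
returns t\* = 0.

Communities of the critical network maximize Newman–Girvan modularity
heuristically — agglomerative greedy by default (deterministic), Louvain
with an explicit seed as the alternative — with Q reported; an edgeless
graph degenerates to singleton communities with Q = 0 by convention.

## Co-occurrence networks and strict cores

A taxon is present in a sample when it has ≥ `min_count` reads; the
default is 1 read, the only threshold consistent with treating the OTU
table's non-zero entries as observations, but it is configurable to
guard against index-hopping noise. The co-occurrence network of a
sample group has the present taxa as nodes and an edge wherever some
group sample holds both taxa (witness samples stored on the edge) — the
union over samples of the complete graph on each sample's present taxa.

A group's core is the taxa whose occupancy (fraction of group samples
where present) reaches the cutoff; the default cutoff 1.0 is the strict
core. Cores over a nested family of groups obey the nesting theorem —
at cutoff 1.0 the core of a superset group is a subset of the core of
each subset group — which the implementation checks and reports; a
non-empty nesting report indicates a bug, never data. The sampling unit
is the sequenced unit (leaf pool or individual leaf); pooling the
leaves of one tree into a tree-level unit (logical OR of presence) is
available as an explicit pre-step for intra-individual analyses.

## Guilds and Venn partitions

Guild assignment matches a taxon's parsed names against the lookup
table at the deepest available rank, species > genus > family > order >
class > phylum; the first hit wins and a taxon with no hit at any rank
is "unassigned" — a value, not an error. Records carrying several
trophic modes are kept as mode sets and reported as literal combination
categories ("pathotroph+saprotroph"). Trophic-mode profiles are
per-group probability vectors over mode categories plus unassigned,
weighted by taxa or by reads. Venn partitions enumerate every
inclusion/exclusion region of 2–5 named sets exactly; name matching is
exact string after whitespace trimming (synonym resolution is out of
scope).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design the package targets: two
sites, five adult trees per site, one focal tree with five individually
sequenced leaves, five plantlets at one site — 19 sampling units by
default — with 50 000 reads per unit. Per sample, taxon weights are
log-normal (base weights per taxon, per-sample log-normal
overdispersion of sd 0.8, a mild per-site taxon effect of sd 0.2), and
reads are multinomial at the fixed depth, so column sums equal the
configured depth exactly.

Planted structure, all recorded in a serializable truth object:

* **Nested cores.** Ten high-abundance taxa are assigned to hierarchy
  nodes (3 to all samples, 2 more to adults, 1 to plantlets, extras to
  site-level and leaf-level nodes). Presence everywhere in their node
  is enforced by a deterministic repair (a missing core taxon receives
  one read moved from the sample's most abundant taxon, conserving
  depth), and — so that each node's strict core equals *exactly* its
  planted set — any other taxon that comes out ubiquitous in a node is
  knocked out of one eligible sample of that node, its reads moved to
  the sample's top taxon.
* **Antagonist pair.** Two core taxa are coupled through a shared
  uniform latent factor U with opposite monotone loadings, a ∝ U^g and
  b ∝ (1−U)^g. The exponent g was calibrated once by pilot simulation
  (g = 1.5 for target ρ = −0.6, g = 1.05 for −0.5 at the default noise
  level, n = 45): a rank-based target needs monotone coupling, and the
  latent-factor construction keeps the marginals realistic. The
  realized Spearman ρ varies around the target with sd ≈ 0.1 across
  replicate datasets — individual draws outside ±0.15 of the target are
  expected; the tests therefore assert the replicate mean.
* **Stage shift.** Taxa of one order (Exobasidiales, the yeast-like
  group that dominates plantlet phyllospheres) are 8-fold enriched in
  plantlet samples, giving plantlets a distinct read-dominance profile.
* **Trophic modes.** Each genus draws a mode from configured fractions
  (0.55 saprotroph, 0.10 pathotroph, 0.02 symbiotroph, remainder
  unassigned), emitted as a matching guild-table fixture.

The **null generator** for calibration keeps the sampling design but
removes all planted structure, and deliberately differs in two further
ways: counts are independent Poisson per taxon around the expected
depth (a fixed multinomial column sum couples every taxon pair through
closure), and the weight panel is flat (log-normal sd 0.5) so no taxon
holds a share large enough for the closure of the relative transform to
induce visible negative correlation. Relative-abundance data can never
be exactly independent across taxa; the flat panel keeps the residual
coupling well below the resolution of the screen at the calibrated
sample sizes.

Planted **block similarity matrices** (integer similarities uniform in
disjoint within/between ranges, block membership encoded in the node
labels) provide the deterministic fixture for critical-network tests.

What the generator does **not** emulate: sequence-level artifacts (PCR
bias, chimeras, index hopping), taxonomic misassignment, spatial or
temporal autocorrelation beyond the site effect, and realistic
phylogenetic correlation among satellite taxa. Passing recovery tests
therefore demonstrates that the algorithms extract exactly the
structure they claim from data of realistic shape and noise — not that
real communities contain such structure.

## Problem sizes and numerical conventions

The test suite and acceptance script run the Monte-Carlo calibrations
at 100–500 replicates (500 null PERMDISP datasets of 30 samples at 199
permutations; 100 antagonist datasets of 45 samples; 200 null screens;
100 planted block matrices), sizes at which the binomial error of the
measured rates is well inside the asserted bands. Ties in critical-
threshold selection break to the smallest threshold, community labels
are assigned in sorted-node order, exports sort node labels, and all
stochastic stages require explicit seeds, so every output TSV is
byte-reproducible under a fixed configuration. Degenerate inputs take
defined values rather than errors where a convention exists (empty
cores, Q = 0 for edgeless graphs, F = 0 for constant dispersions,
degenerate-sweep flag for flat distance curves); genuine contract
violations (zero-read samples, non-nested hierarchies, overlapping
block ranges, relative-abundance inputs) raise immediately with the
offending identifiers named.

## Known limitations

PERMDISP compares dispersions, not locations: a significant result
means unequal spread, and the test says nothing about centroid
separation. The t-approximation for Spearman p-values is slightly
liberal below n ≈ 10 (the screen refuses n < 4). The co-occurrence
builder materializes per-sample cliques and is quadratic in the taxa
present per sample — fine at metabarcoding scale, not meant for
shotgun-scale tables. Guild matching is exact-string per rank;
synonyms and misspellings are the user's responsibility.
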