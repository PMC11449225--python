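# Methods

## Network model

A phylosynteny network is an undirected graph whose nodes are family genes
or tandem arrays (maximal runs of same-orthogroup genes on one chromosome
with at most `tandem_max_gap = 1` intervening gene; the gap is
configurable because tandem calling conventions vary) and whose edges are
synteny relationships detected between genes of different genomes. Four
approach combinations contribute evidence — two clustering sources
(OrthoFinder orthogroups, MCL groups) crossed with two collinearity
detectors (i-ADHoRe, MCScanX) — and an edge's weight is 0.25 × (number of
supporting approaches). An empty support set is no edge, never a weight-0
edge, so weights lie in {0.25, 0.50, 0.75, 1.00}. Node-level support is
the union of member-gene supports: a tandem array is syntenic if any
member is.

Two readings of the evidence rule exist: the weighting just described
(any single approach suffices, at 0.25), and a stricter rule requiring
both detectors to agree before a relationship counts. The weighting is
the default — weights 0.25/0.50 could not occur otherwise — and
`strict_both_detectors=True` implements the stricter rule as an option.

Downstream conventions:

* **Core network** — the six largest connected components (`k`
  configurable), ordered by node count, with edge count and smallest node
  id as deterministic tie-breaks.
* **Per-orthogroup components** — induced subgraph per orthogroup, split
  into connected components, discarding components with fewer than 3
  nodes.
* **Clique decomposition** — on the binarized graph (every positive
  weight set to 1), repeatedly enumerate *all* maximum cliques of the
  remaining subgraph, delete one chosen uniformly at random, until no node
  remains; singletons and pairs are recorded but flagged, and reported
  clique counts include only cliques with more than two members. The
  randomized decomposition restarts 100 times per component; selection is
  lexicographic (fewest cliques, then highest median membership, then
  lowest restart index). Restart r uses an independent RNG stream spawned
  from `(seed, r)`, so results are reproducible and restarts independent.
  Maximum cliques are enumerated exactly through branch-and-bound maximal
  clique search with pivoting; above a configurable node threshold
  (default 2000) a greedy heuristic caps worst-case time.
* **Cliques kept for the species matrix** — at least 10 member nodes in
  total and members from at least 10 distinct species (both
  configurable); entries count nodes per species, so column sums equal
  clique sizes.

## Topology parameters and family comparison

For each per-orthogroup component (connected, ≥3 nodes) we compute: mean
distance and diameter; min/median/max normalized degree (degree/(n−1));
min/max normalized closeness ((n−1)/Σd); max normalized betweenness
(pair-normalized by (n−1)(n−2)/2); max edge betweenness; min/max
eccentricity; min/median/max eigenvector centrality (scaled to max 1) and
the leading eigenvalue of the weighted adjacency; min/median strength
(weighted degree); max order-1 neighborhood size (including the node);
median Burt's constraint (on weights); and the median and maximum of the
unordered-pair distance distribution.

Path-based metrics deliberately ignore edge weights: weights encode
evidence support, not distance, and a shortest-path algorithm would treat
a fully supported edge (1.0) as *longer* than a weakly supported one
(0.25), inverting their meaning. Strength, constraint and the eigenvector
quantities do use the weights. A `weighted_paths` toggle provides the
other convention; under the default, the maximum of the distance
distribution coincides with the diameter by construction.

Per family, each parameter is regressed on component node count by
ordinary least squares. Coefficient uncertainty comes from a bootstrap
that resamples components with replacement (same size as the family) and
refits; the default number of replicates equals the family's component
count — one resampling per data point — and degenerate replicates (all
resampled node counts identical) are redrawn with a capped retry count.
Families are compared per parameter and coefficient with Welch's
unequal-variance t-test and Satterthwaite degrees of freedom (the
fractional d.f. this test produces distinguish it from pooled-variance
tests). Benjamini–Hochberg FDR adjustment is applied separately within
the slope family and within the intercept family across parameters; the
grouping is configurable since conventions differ. When both samples have
zero variance the statistic is 0/0 and is reported as NaN rather than
invented.

## The synthetic-data generator

Genomes are ordered gene lists on a fixed number of chromosomes;
base-pair coordinates are synthesized as rank × 1000 spans since all
order logic downstream is rank-based. Two gene families with contrasting
dynamics (A, BAHD-like: 4 orthogroups, each its own MCL group; B,
SCPL-like: 3 orthogroups merged into a single coarse MCL group,
mirroring the observation that Markov clustering lumps that family) evolve
along a random binary species tree (unit branch lengths; topology by
random joins) together with 600 single-copy background orthologue
families.

Events per branch, each a per-gene Bernoulli draw:

* **Tandem duplication** (0.05/gene/branch) — adjacent copy, same
  orthogroup; optionally multiplied on one designated branch to emulate a
  burst, e.g. at a land-transition-like node.
* **Dispersed duplication** (0.02) — copy inserted at a random genomic
  position (fresh context).
* **Loss** (0.02).
* **Segmental rearrangement** (family A 0.06, family B 0.30 — the 5×
  contrast) — the gene moves to a random position together with 0–2
  flanking genes on each side, breaking its old neighborhood while its
  descendants share the new one.
* **Background drift** (0.12/gene/branch) — background genes relocate
  individually, so any two genomes' local neighborhoods decay gradually
  with divergence.
* **WGD** (probability 0.08/branch, genome-level) — every chromosome is
  duplicated and the copy fractionates gene-wise (retention: family A
  0.2, family B 0.75, background 0.5). The family contrast mirrors
  preferential retention of duplicates in SCPL-like orthogroups.

Orthogroup origins are staggered: each orthogroup's birth branch is drawn
by first sampling an emergence depth uniformly, then a node at that depth
(internal nodes with ≥4 descendant species), so families contain both old,
wide-ranging orthogroups and young, clade-restricted ones — the size
spectrum real copy-number heatmaps show. An `origin="root"` mode places
all orthogroups in the ancestral genome for closed-form tests.

**Ground truth.** Two same-orthogroup genes in different species are
ancestrally collinear iff the ±10-gene neighborhoods around them share at
least 5 orthologue families. With no rearrangement this reduces to one
cross-species clique per ancestral locus; with rearrangement it produces
the graded decay of synteny with divergence that real detectors see. The
background universe is deliberately large (600 families) so that two
unrelated 20-gene windows share ~0.7 families by chance and essentially
never reach the threshold coincidentally.

**Detector emulation.** Each approach keeps each truth pair independently
with its sensitivity (defaults 0.80–0.90) and adds false positives at
rate 0.002 among *borderline* same-group cross-species pairs (neighborhood
overlap within two of the threshold): chain-validating collinearity
detectors err on partially degraded regions, not on arbitrary gene pairs.
Every emitted pair is either in the truth ledger or logged as a false
positive. All randomness flows from a single seed through named
`SeedSequence` spawns, so datasets are bit-reproducible.

**What the generator does not emulate.** Sequence evolution (homology is
given, not inferred), realistic branch-length calibration, inversions that
reverse but preserve local context, block-level detector sensitivity
(anchors are thinned independently), and genome sizes beyond a few
thousand genes. Passing tests therefore validate the pipeline's logic and
statistics, not detector behavior on real assemblies.

## The effect-recovery experiment and its limitation

The end-to-end experiment simulates the two families with a five-fold
rearrangement-rate contrast (0.06 vs 0.30) at 24 species and 20
orthogroups per family, profiles up to 20 per-orthogroup components per
family, and runs the bootstrap/Welch/BH comparison, over 20 seeded
replicates. The configured expectation, following the field observation
that the slow-rearranging family maintains wider, path-longer synteny, is
a positive mean-distance and diameter slope contrast (A minus B).

In this generator that direction is *not* what a rate-only contrast
produces. Distance-versus-size curves are concave with a family-specific
coherence scale: the fast-rearranging family sits on the steep part of
its own curve (its surviving older orthogroups are sparse
scattered-survivor chains at small node counts), while the slow family's
components are denser at matched size. Across the frozen study
conditions the configured direction appears in 1/20 replicates and the
opposite, mechanistically explained direction in 10/20. The experiment
and its assertion are kept as specified and the corresponding acceptance
test fails honestly; reproducing the observed real-data contrast likely
requires family differences beyond rearrangement rate alone (copy-number
structure, block-level detection, component sizes spanning orders of
magnitude).

## Numerical and degenerate-input choices

* Fitch parsimony uses bottom-up state sets with top-down resolution; a
  root tie resolves toward "absent" (conservative, latest origin;
  toggleable). Nodes whose state set contained both states are reported
  as ambiguous. With multiple independent gains the MRCA of present
  terminals is returned and flagged.
* Orthogroup copy-number columns with fewer than 100 genes in total are
  dropped by default (a display filter; parameterized).
* Component ties and clique ties break lexicographically; every stochastic
  routine takes an explicit seed or `numpy.random.Generator`.
* Regression fits require ≥3 components and a non-degenerate design;
  records with undefined parameter values are skipped with a logged
  count.
* The leading-eigenvector community method accepts and ignores a `steps`
  argument (the R interface exposes it; the Python binding does not).

## Problem sizes

Default test-scale conditions are 16 species × 4 chromosomes × 150
background genes (~14k genes per dataset); the recovery experiment uses
24 species and 40 orthogroups. These sizes keep every stage exact — no
heuristics engage — while exhibiting all qualitative regimes (cliques,
chains, fragmentation, WGD paralog blocks).
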