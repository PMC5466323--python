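# Methods

This note documents the models, null constructions, numerical choices and
limitations behind `multimorbnet`, in the order the pipeline runs them.

## Inputs and the interaction network

The functional interaction network (FIN) is an undirected simple graph over
opaque protein identifiers (UniProt accessions in practice). It is assembled
as the union of per-source interaction tables after source-specific
confidence filters, all strict inequalities:

| source      | kept when                          | rationale                       |
|-------------|------------------------------------|---------------------------------|
| reactome_fi | not *predicted* and score > 0.5    | curator-recommended cut         |
| hippie      | score > 0.73                       | the source's "high confidence"  |
| innatedb    | hpr < 20 and lpr < 20              | excludes promiscuous hub papers |
| generic     | always                             | pre-filtered edge lists         |

A record missing a field its source's filter needs is an error, never a
silent keep — the filters are part of the method, and silence would corrupt
them. Duplicate edges collapse under a lexicographically sorted edge key;
self-loops are dropped with a logged count. No identifier mapping is
performed: distinct accessions of one gene (e.g. several HLA-DRB1 entries)
remain distinct nodes, matching how the curated association tables count.

Disease protein sets may contain proteins absent from the FIN; restriction
to the network is an explicit, logged operation
(`DiseaseProteinSet.restrict_to`) because downstream statistics are defined
only on network nodes.

## Overlap statistics

Pair and triad overlap use the Jaccard index (intersection over union; for a
triad, triple intersection over triple union). Pairwise intersections
include proteins shared by all three diseases, so a triad's Jaccard is never
larger than any of its pairwise values.

*Proteome randomization null*: each disease is independently redrawn,
uniformly without replacement at its original size, from a proteome of
14,754 proteins; R = 1000 replicates by default. Tested with a one-sided
upper-tail z-test (the question is always "larger than random?").

*Catalogue resampling null*: R random pairs/trios of catalogue diseases,
drawn with replacement across replicates but distinct within one, rejecting
any draw in which one disease is an ancestor or descendant of another
(subtypes share proteins by construction and would bias the null upward).
Because this null is strongly skewed, it is assessed with the empirical
distribution; the add-one estimator p = (r+1)/(R+1) never reports zero and
its minimum, 1/(R+1), is the honest resolution of the test.

When a proteome null is degenerate (tiny sets: every replicate overlaps
zero), the z-test refuses and the pipeline reports the empirical p with a
blank z column.

## Connectivity

Topological overlap between nodes a and b counts third-party common
neighbors plus 1 if a and b are adjacent, normalized by the smaller degree.
The neighbor sets exclude a and b themselves, which is what keeps the ratio
at or below 1 (with adjacency, each node's neighborhood contains the other,
so at most min-degree − 1 third parties exist). Degree-0 nodes and proteins
absent from the FIN are dropped, with a logged count, before any TO
computation; a pair of adjacent degree-1 nodes scores TO = 1 by the formula
and is accepted as such.

Mean TO is reported for (a) all pairs within the proteins common to a
disease combination and (b) cross-disease pairs of proteins unique to each
disease (with a within-disease mode for single-disease cohesion). Fewer
than two usable common nodes yields an explicit "not computable" result.

*Binned node-swap null*: each disease protein is exchanged for a uniformly
chosen FIN node from the same connectivity bin, round(ln(d)+1) with
round-half-to-even (the convention of R's `round`, in which the original
analysis environment computed). The replacement map is injective within a
replicate, so per-disease counts and every intersection cell are preserved
exactly — the null randomizes *which* proteins are associated, not the
overlap structure. The candidate pool for a bin is all FIN nodes of that
bin (a node alone in its bin maps to itself). Sampling uses rejection from
the bin pool when the pool is large, falling back to explicit enumeration,
both uniform over unused candidates.

Edge-level overlap associates an edge to a disease when at least one
endpoint is associated, then compares per-disease edge sets by Jaccard and
reports per-disease and unique-edge counts.

## Pathway functional similarity

A pathway's edge universe is the set of FIN edges with *both* endpoints in
the pathway — requiring both ends prevents hub proteins from dragging a
pathway across the network. Within that universe an edge belongs to a
disease when at least one endpoint does; FSim is the Jaccard index of the
per-disease edge sets (pair or triad). Edges, not nodes, carry the signal:
two diseases touching the same proteins through different interactions
perturb the pathway differently.

Only pathways with more than 2 edges in the network are eligible;
ineligible pathways return an explicit flagged result. An eligible pathway
untouched by every disease scores 0 with an "uncovered" flag (not NaN);
tabular output rounds FSim to 2 decimals while full precision is kept
internally.

Significance reuses the binned node-swap null: one replicate stream per
disease combination, every eligible pathway evaluated on every replicate.
The one-sided z-test p-values are Benjamini–Hochberg adjusted across the
eligible pathways *within* each disease combination (each combination is
its own test family, matching how per-combination significance columns are
read); when a pathway's null is degenerate the empirical p substitutes. The
empirical p is always reported alongside. Note the swap null can reach
FSim = 1 in one jump — a single randomized shared protein landing inside a
small pathway makes all per-disease edge sets identical — so the null is
zero-inflated with rare spikes; the z-test tolerates this at the reported
R, and the empirical p is the robust cross-check.

## Propagation-based prediction

The scorer follows the NetZcore idea: seed proteins start at 1, all others
at 0, on the real network and on R rewired networks with the identical
degree sequence. Each iteration every node's raw value is the mean of its
neighbors' current scores (mean rather than sum: robust to degree), and
every network's scores are then standardized per node by the mean and
standard deviation of the raw values across the random ensemble. Applying
the *same* transform to the real and the random networks keeps all scores
on one scale across iterations — standardizing only the real network while
the ensemble keeps raw scores lets the z magnitudes grow without bound with
iteration count — and makes the real network exchangeable with the ensemble
under the null. Five iterations by default (scores stabilize and the
neighborhood horizon matches the network diameter scale); equivalence to
the original GUILD binary is not claimed.

Degeneracy (a node whose null sd is zero, e.g. when every node is a seed)
is detected with a relative tolerance sd ≤ 1e-9·max(1, |mean|), because an
exactly-constant ensemble acquires ~1e-16 float noise; degenerate nodes are
scored 0 and flagged rather than dropped, keeping the score map total.

Rewiring attempts `swaps_per_edge × |E|` double-edge swaps
((a,b),(c,d) → (a,d),(c,b)), skipping any proposal that would create a
self-loop or duplicate edge — a graph admitting no valid swap (a triangle)
is returned unchanged. The hot loop is a numba kernel over integer-encoded
edges; node order is the sorted identifier order, so results are
deterministic per seed.

Candidates: z > 2.31 (one-sided P < 0.01), strict. The candidate table
shows "exp" for experimentally known proteins (no z), the z-score when
above threshold, blank otherwise; rows are ranked by the mean of the shown
z-scores (known entries carry no score and are excluded from the mean), and
proteins with ≥ 2 non-blank entries are multimorbidity candidates.

## Literature association

Predictions for a disease combination (proteins newly called or known for
every disease in it, minus those known for all of them) are crossed against
a literature gene list over a background of all FIN nodes minus the
all-known proteins. The background choice moves the odds-ratio magnitude,
so it is explicit and configurable. Reported: two-sided Fisher exact p,
conditional-MLE odds ratio with exact 95% CI, and the sample cross-product
ratio. Zero-margin tables return p = 1 with a degenerate flag. Literature
tables (gene, n, n_pos, FDR) support an FDR cutoff on read.

## The synthetic-data generator

`generate_study` emulates the statistical structure the pipeline assumes:

- **Interactome**: preferential attachment by default — 9,847 nodes with
  m = 16 (≈ 154k edges, mean degree ≈ 31, heavy-tailed degrees), matching
  the scale and density of the real FIN; Erdős–Rényi and configuration
  models are available for calibration runs.
- **Disease modules**: three sets of sizes 196/49/40 whose intersection
  cells (11 in the first two only, 30 in first and third, 0 in second and
  third, 5 in all three) are realized exactly; within each module every
  node pair receives an extra edge with probability `module_cohesion`
  (default 0.3), planting the connectivity signal.
- **Pathways**: dense subgraphs (size 5–20, internal edge probability 0.6)
  of three classes — *core* (disease-drawn members from the multimorbidity
  core, i.e. nodes in ≥ 2 modules; these are the pathways all diseases
  co-perturb), *shifted* (members from the whole disease union, hence
  dominated by the largest disease), and *background* (disjoint from the
  modules; the built-in nulls). Roughly a quarter each core/shifted, half
  background.
- **Catalogue**: 30 decoy diseases of size 10–200; with probability 0.3 a
  decoy is a subset of an earlier one and records it as parent, exercising
  the subtype-exclusion rule.
- **Literature list**: true multimorbidity nodes included with probability
  `lit_enrichment` (default 0.8) plus an equal count of uniform noise.

What the generator does **not** emulate: identifier noise and mapping
ambiguity, evidence-strength heterogeneity, database ascertainment bias,
directedness or sign of interactions, and the community structure of real
interactomes beyond degree heterogeneity. Passing tests therefore show the
statistics behave correctly under the assumed generative structure, not
that real curated data satisfies that structure.

## Problem sizes and determinism

Default replicate counts are R = 1000 for the overlap/connectivity/pathway
nulls and R = 1000 rewired networks for propagation, with R = 100 the
standard reduced setting for desk-scale propagation runs. The test suite
and the acceptance script use: full-scale (9,847-node) studies for the
planted-significance and connectivity checks (~2.5 s per seed), 2,000-node
studies for the end-to-end pathway/prediction/literature stages, 300-node
planted-module graphs at R = 100 for propagation recovery, and 20 seeds
for any rate estimated over seeds. All randomness flows from explicit
integer seeds through `numpy.random.default_rng` (spawned per stage or
replicate); re-running any stage with the same config and seed reproduces
byte-identical outputs.

## Known limitations

- The deposited tables of the originating study are not bundled; the
  replication test runs only when they are converted to TSV under
  `data/deposited/`.
- The printed per-disease unique-protein counts in the originating study
  (150/44/38) are arithmetically inconsistent with its own totals and
  pairwise counts for two diseases; `paper_tables_fixture` follows the set
  algebra (150/33/5 unique placeholders) so that totals and every
  intersection cell are exact.
- The propagation scorer is a reimplementation of the published scheme,
  not a bit-for-bit port of GUILD; rankings agree in the planted-module
  regime but individual z-values need not.
- The binned swap null conditions on the observed overlap structure; it
  tests connectivity given the overlap, not the overlap itself (that is
  the proteome/catalogue nulls' job).
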