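# Methods

This note documents the models, rules and numerical conventions implemented
in `mirnet`, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the design choices made where the problem was
genuinely open.

## Network model

A regulatory network is a simple directed graph whose nodes carry one of
four roles — `core_tf` (a TF with genome-wide binding data), `tf`, `mirna`,
`target_gene` — and whose edges belong to one of three classes with role
constraints enforced at insertion:

| class | source role | target role |
|-------|-------------|-------------|
| TMI   | tf / core_tf | mirna |
| TTI   | tf / core_tf | any non-miRNA |
| MTI   | mirna        | unconstrained |

Edges are unique by (source, target, class). Self-loops are stored and
flagged but excluded from degrees, topology metrics, hub/layer rules and
the motif census: the triad patterns analysed here are loop-free, and
excluding loops from degrees keeps the connectivity identity below exact.

**Degree statistics.** The out/total ratio O/T = D_out/(D_in + D_out) is
undefined for isolated nodes (reported as missing, excluded from averages).
Network-level O/T — sum of out-degrees over sum of total degrees — is 0.5
exactly for any graph with an edge, since every edge contributes one
in-degree and one out-degree; this is used as an analytic self-check.
**Mean connectivity** is defined as mean(total degree)/2, so the
whole-network value equals |E|/|N| exactly; a raw mean-degree variant is
exposed (`halved=False`) because the per-subset statistic can reasonably be
defined either way and published subset values do not disambiguate it.

**Topology metrics.** Clustering coefficients are computed on the
undirected simple projection (parallel/antiparallel edges collapsed); a
directed clustering variant is deliberately not used. Betweenness and
closeness centralities are computed on the directed graph (networkx, with
its standard normalisations). The shortest-path-length histogram covers
reachable ordered pairs; unreachable pairs are counted separately rather
than folded into the histogram. The degree distribution exponent is a
least-squares slope on the log–log degree histogram with zero-count bins
dropped — adequate for describing the distribution's tail, not a rigorous
maximum-likelihood power-law fit.

## Peak-to-gene assignment

Coordinates are 0-based half-open internally; BED input is native and GFF3
(1-based inclusive) is converted on read. The binding window of a coding
gene runs from 2000 bp upstream to 300 bp downstream of the TSS; for a
miRNA locus it covers the 2000 bp upstream of the first base of the
pre-miRNA (downstream extent 0). Windows are strand-aware and clipped at
coordinate 0. Two conventions are fixed for reproducibility where the rule
itself is silent: window boundaries are **inclusive on both ends** (closed
interval), and the midpoint of an even-length peak is the **lower median**,
floor((start + end)/2). A peak is assigned to every locus whose window
contains its midpoint — no nearest-gene tie-breaking — and associations are
additionally rolled up to unique (TF, gene) pairs with supporting peak
counts for edge construction.

Genomic-context classification of a peak midpoint uses the priority
5'UTR > 3'UTR > exon > intron > intergenic when features overlap (UTRs are
subintervals of exons in standard annotation, so UTRs must outrank exons to
be reportable at all); the priority order is configurable. Metagene
profiles histogram strand-oriented midpoint offsets (negative = upstream)
and count peak–anchor pairs; with anchors spaced more widely than the
profiling window this equals the number of in-window midpoints.

## MTI compilation

Candidate miRNA–target pairs from two alignment penalty-score predictors
(typical cutoffs 2.2/2.5 for program A, 2.5/3.0 for program B; a score at
or below the cutoff passes, applied at read time and configurable) are
merged as

```
result = (A ∩ B) ∪ ((A ∪ B) ∩ D)
```

where D is the degradome-supported pair set. Degradome compatibility is
reduced to a boolean per pair (an optional cleavage-category tag is carried
through but never re-derived). Each pair records its provenance
(`both_programs`, `both`, `degradome_supported`); curated/validated pairs
are unioned in afterwards with provenance `curated`, so the final count is
|pipeline| + |curated \ pipeline|. Benchmark evaluation reports
|candidate ∩ benchmark|/|benchmark| per candidate set, sorted by recovery
then size; choosing the operating point is left to the user. Pair identity
is at gene level (transcript isoforms collapsed). Binding-site positions
within a transcript are mapped to the containing 5'UTR/CDS/3'UTR segment
with position normalised to [0, 1] inside the segment (0 at the first base,
1 at the last; a single-base segment maps to 0).

## Motif census and permutation null

An FFL is an ordered triple (X, Y, Z) of distinct nodes with edges X→Y,
Y→Z, X→Z; an FBL is the directed 3-cycle. FFLs are counted per role
assignment (the three roles are distinguishable); FBLs once per directed
cycle, i.e. rotations are identified but the two opposite orientations of
one node set count separately. Two census modes:

* `induced` (default, the Mfinder-style subgraph census): a triple counts
  only if no edges beyond the defining pattern exist among the three nodes.
  The full 16-type triad census (networkx) is attached as a cross-reference
  (FFL = 030T, FBL = 030C).
* `match`: pure pattern matching, extra edges tolerated. Match counts
  dominate induced counts class-wise; per-hub FFL fans are counted in this
  mode since generalized multi-output loops share edges.

**Null model.** The default permutation draws, for each replicate, a
uniform simple digraph with the same node set and edge count (`size_only` —
the literal "preserve nodes and edges, randomise connections" rule). A
`role_preserving` option additionally keeps per-class edge counts inside
role-compatible pair spaces, and a `degree_preserving` edge-swap option is
provided for sensitivity analysis; neither is the default because the
method being reproduced specifies only node/edge preservation.
Z = (observed − null mean)/null sd with the sample standard deviation
(ddof = 1). Degenerate nulls (sd = 0) yield Z = 0 when the observation
equals the constant and signed infinity with a warning otherwise. Results
are bit-for-bit reproducible under a fixed seed and permutation count.

**Position statistics.** miRNA-position tallies are computed over FFL
instances with denominators equal to the miRNA-containing instance count;
an FFL with miRNAs at several positions contributes to each position and is
flagged (`n_multi_position`). A conserved-only switch restricts the miRNA
definition to a supplied conserved set.

**Signs.** Coherence multiplies the indirect-path signs (activating = +1,
repressing = −1): coherent iff sign(X→Y)·sign(Y→Z) = sign(X→Z); any unknown
sign yields `unclassified`. Two-proportion comparisons use the chi-square
test without Yates continuity correction by default (configurable; R's 2×2
default applies the correction, and the convention used for the published
comparisons is not stated).

## Hubs and hierarchy

Hub rules use loop-free degrees and full-network clustering: in hubs have
D_in > 10, out hubs D_out > 10 (strict), and party/date candidates have
D_out > 5 and CC > CC_a (the network-average clustering coefficient,
computed once). Candidates split by the mean pairwise Jaccard index over
their targets' GO term sets — party when similarity ≥ 0.3, date below. The
similarity metric and its threshold stand in for manual curation of GO-term
similarity; the threshold is exposed, and the planted test cases sit at the
extremes (1.0 vs 0.0) where any sensible threshold agrees. Hubs with fewer
than two annotated targets are reported unclassifiable. Topological
generalization of a hub Y counts its output FFLs (instances with the hub as
Y) and the distinct input (i) and output (o) nodes among them.

The core network is the induced subgraph on TF and miRNA nodes. Layers are
assigned on the core: CC > CC_a → **middle**; otherwise D_out ≥ 10 and
D_in < 10 → **top**; everything else → **bottom** (covering in-heavy nodes
and nodes matching neither degree sub-rule, which the stated rules leave
uncovered — published layer sizes make bottom by far the largest layer, so
it is the natural completion). The high-CC group maps to the middle layer
because that layer is the smallest in the published decomposition and
high-CC nodes are rare in sparse digraphs; the mapping is configurable in
the sense that the assignment returns labels that can be permuted
downstream. CC ties (CC = CC_a) fall to the degree rules (strict ">" for
middle). CC_a defaults to the core-network average but a pan-network value
can be passed. FFL layer orientation tallies layer(X) >, =, < layer(Z)
(top > middle > bottom), reports the strict-above fraction, counts
instances with unlabelled endpoints separately, and repeats the tally for
the miRNA-containing subset.

Module connectivity of a node counts distinct functional-module labels
reached via incoming TMIs from labelled TFs or via outgoing MTIs to genes
regulated by labelled TFs. Expression overlays compare disjoint gene groups
per condition with Mann-Whitney rank-sum tests (summaries: mean, median,
quartiles; groups under 3 members are summarised but not tested). Rank-sum
is used because the compared quantity is a continuous relative expression
level; the chi-square test cited for the corresponding published panels is
not applicable to continuous data.

## Synthetic data generator

The generator produces the study conditions for the test suite: a typed
network of 302 nodes (12 core TFs, 40 TFs, 100 miRNAs, 150 targets) with

* 30 planted Y-position FFLs (TF → miRNA → target, each loop with a unique
  Y miRNA) drawn over a pool of 6 input TFs and 15 output genes —
  uniqueness of Y guarantees that with zero background the census finds
  exactly the planted loops; X- and Z-position planting is available for
  position-statistics tests;
* one party hub and one date hub (miRNAs with 2 upstream TFs and 6 MTI
  targets, upstream TFs cross-wired to all targets so the hub's clustering
  coefficient is 12/28 ≈ 0.43, far above the network average); party
  targets share one GO term set, date targets carry pairwise disjoint sets,
  and date-hub TFs belong to distinct functional modules;
* a three-layer core scaffold: 6 top core TFs each fanning out to 10
  dedicated bottom miRNAs, plus 3 middle miRNAs each closed into a triangle
  with one connected pair of top TFs (middle CC = 1; top CC = 1/66 stays
  below the core average, which the three middle nodes alone hold above
  3/N_core);
* Bernoulli background edges per class (TTI 0.005, TMI 0.01, MTI 0.01)
  drawn **only among nodes unused by planted structures**, and background
  TTIs/MTIs directed at target genes only.

Because planted wiring is deterministic and background randomness cannot
touch the clustering neighbourhoods of scaffold or hub nodes, recovery of
planted hub types and layer labels by the analysis rules is a structural
property of the construction — the corresponding tests assert it at 100%
over seeds. The optional layer wiring probabilities (top→middle,
top→bottom, within-layer) default to 0 for the same reason: nonzero values
can create triangles that legitimately blur the planted hierarchy
(middle→bottom defaults to 0.05, which is safe because those MTI targets
lie outside the core).

Genomic fixtures place 30 coding genes and 10 miRNA loci at 12 kb spacing
on 2 chromosomes of 400 kb — far enough apart that binding windows never
overlap, making peak-assignment truth unambiguous — with random strands and
a fixed exon/UTR architecture. 200 peaks of 151 bp (odd length, so the
lower-median midpoint is exactly strand-mirror symmetric) are placed with
70% of midpoints uniform inside a random window and 30% rejected-sampled
strictly outside all windows. Prediction fixtures compose 40 both-program
pairs, 40 + 40 single-program pairs (30% degradome-supported), 10
degradome-only decoys and 15 curated pairs; the benchmark (40 pairs) is
drawn from the validated pool. Expression tables give every non-miRNA gene
Gaussian noise (sd 0.3 log-units) in three conditions and add a +1 log-unit
shift for MTI targets in the *ago1*-like condition only, mimicking the loss
of miRNA-mediated repression when ARGONAUTE1 is defective but not in the
siRNA-pathway control.

**What the generator does not emulate:** scale-free degree structure (the
background is Bernoulli, not preferential-attachment), the real network's
size and counts, overlapping promoter windows, sequence-level signal
(no FASTA/reads), predictor score distributions with informative structure,
or correlated expression noise. Passing tests therefore demonstrate that
the implemented rules are applied exactly and recover what they are defined
to recover — not that the rules are robust to the messiness of real ChIP or
degradome data.

## Numerical conventions and degenerate inputs

* Z-scores use the sample sd; sd = 0 → Z = 0 (observation equals constant)
  or ±∞ with a warning.
* O/T of an isolated node, proportions over empty denominators, and the
  power-law exponent of a near-empty degree histogram are NaN/None, never
  silently 0.
* Chi-square with any zero margin raises; empty benchmark, empty network,
  removal of all nodes, and a bin size that does not divide the metagene
  window are errors.
* Permutation sampling decodes ordered-pair indices drawn without
  replacement, so replicates are uniform over simple digraphs with the
  exact edge count.
* All randomness flows from `numpy.random.default_rng(seed)`; generator
  outputs are byte-identical for identical configuration and seed, and all
  emitted tables carry the seed in a header comment.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script each
run in seconds on a single CPU: 302-node networks, 200–1000 permutations,
20-seed recovery sweeps, 200 random graphs (≤ 15 nodes) for the census
oracle, and 50-replicate null calibrations. These sizes are the package's
chosen study conditions; all of them scale up linearly in the obvious knobs
(`SimulationConfig`, `n_perm`).

## Known limitations

* The permutation null ignores degree sequence by design (the
  degree-preserving option exists but is not the default); Z-scores against
  it overstate enrichment for hub-heavy graphs, which is inherent to the
  reproduced procedure.
* GO similarity is plain term-set overlap; no ontology-aware semantic
  similarity.
* The power-law exponent is a descriptive least-squares fit.
* `match`-mode FBL counting reports each orientation of a doubly-cyclic
  triple separately; other conventions exist.
* Peak assignment assumes shared chromosome naming; mismatches are logged,
  not reconciled.

## Appendix: worked-example print statements

The README's output block is produced by:

```python
print(net)
print(f"FFL: observed={census.n_ffl}  Z={enrich['FFL'].z_score:.1f}")
print(f"FBL: observed={census.n_fbl}  Z={enrich['FBL'].z_score:.1f}")
print(f"miRNA-containing FFLs: {stats.n_with_mirna}/{stats.n_instances} "
      f"({100 * stats.fraction_with_mirna:.1f}%), "
      f"Y position: {100 * stats.proportions['Y']:.1f}%")
for rec in hubs.values():
    if rec.hub_type != "none":
        print(f"{rec.node}: {rec.hub_type} hub  D_out={rec.d_out} "
              f"CC={rec.cc:.2f}  GO similarity={rec.go_similarity:.2f}  "
              f"output FFLs={rec.n_output_ffls}")
counts = {k: v["count"] for k, v in layers.summary().items()}
print(f"core: {report.n_tf} TFs + {report.n_mirna} miRNAs, layers {counts}")
```
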