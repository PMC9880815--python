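# mirnet

Integrated TF–miRNA regulatory network analysis: network assembly from three
interaction classes, ChIP-peak-to-gene assignment, miRNA-target compilation,
3-node motif census with permutation enrichment, party/date hub
classification, and hierarchical-layer decomposition.

## The problem

Plant gene expression programs are steered jointly by transcription factors
(TFs), which act on promoters, and microRNAs (miRNAs), which silence
transcripts post-transcriptionally. Understanding their joint logic requires
an integrated directed network built from three interaction classes:

* **TMI** (TF → miRNA): a TF binds the promoter of a miRNA locus,
* **TTI** (TF → gene): a TF binds the promoter of a protein-coding gene,
* **MTI** (miRNA → gene): a miRNA guides cleavage/repression of a target.

In such networks the central structural unit is the **feed-forward loop**
(FFL): X regulates Z both directly and indirectly through an intermediate Y
(edges X→Y, Y→Z, X→Z). Its topological isomer, the **feedback loop** (FBL),
is the directed 3-cycle. Plant miRNAs preferentially occupy the intermediate
(Y) position of FFLs, and miRNAs whose FFLs fan out over many outputs act as
**date hubs** bridging several functional modules, while **party hubs** act
within one module. `mirnet` implements this entire analysis chain as a
tested, reusable library plus CLI, together with a synthetic-data generator
that plants known FFLs, hubs, layers, peak-window memberships and
predictor-merge outcomes, so every stage can be verified against ground
truth.

## Methods at a glance

* **Assembly** — typed, role-checked directed graph; edges unique by
  (source, target, class); per-node out/total degree ratio O/T (network-wide
  O/T ≡ 0.5), mean connectivity = mean(degree)/2 (network value = |E|/|N|),
  clustering, betweenness/closeness, path-length histogram, power-law fit.
* **Peak assignment** — a peak is assigned to a locus when its midpoint lies
  in the strand-aware binding window: TSS −2000/+300 bp for coding genes,
  −2000/0 bp from the first pre-miRNA base for miRNA loci.
* **MTI compilation** — pairs called by both target predictors, or by one
  predictor with degradome (PARE) support, plus curated interactions;
  candidate sets are scored by benchmark recovery.
* **Motif census** — FFL/FBL counts (induced or pattern-match mode) with
  instance lists; enrichment as Z = (N_real − mean(N_rand))/sd(N_rand)
  against permutations preserving node and edge counts; coherent/incoherent
  FFL calls from edge signs.
* **Hubs and hierarchy** — in/out hubs (degree > 10), party/date candidates
  (out-degree > 5 and CC > CC_a), party vs date split by mean pairwise
  Jaccard similarity of target GO sets; TF–miRNA core network layered into
  top/middle/bottom from CC and degrees; FFL X-above-Z orientation scoring.

See `docs/methods.md` for the full model description and design rationale.

## Worked example

```python
from mirnet import (SimulationConfig, simulate_network, census_triads,
                    permutation_zscore, mirna_position_stats,
                    classify_hub_types, extract_core, assign_layers)

cfg = SimulationConfig(seed=42)
sim = simulate_network(cfg)          # typed network + planted ground truth
net = sim.network

census = census_triads(net, mode="induced")
enrich = permutation_zscore(net, n_perm=1000, seed=42)
stats = mirna_position_stats(census.ffl_instances, net.roles)
hubs = classify_hub_types(net, sim.truth.go_annotations,
                          ffl_instances=census.ffl_instances)
core, report = extract_core(net)
layers = assign_layers(core)
```

prints (via the `print` statements shown in `docs/methods.md`):

```text
RegulatoryNetwork(nodes=302 {'core_tf': 12, 'tf': 40, 'mirna': 100, 'target_gene': 150}, edges=256 {'TMI': 100, 'TTI': 81, 'MTI': 75})
FFL: observed=57  Z=72.8
FBL: observed=0  Z=-0.4
miRNA-containing FFLs: 57/57 (100.0%), Y position: 94.7%
MIR0093: party hub  D_out=6 CC=0.43  GO similarity=1.00  output FFLs=12
MIR0094: date hub  D_out=6 CC=0.43  GO similarity=0.00  output FFLs=12
core: 52 TFs + 100 miRNAs, layers {'top': 6, 'middle': 3, 'bottom': 143}
```

Reading this: the generator planted 30 Y-position FFLs and wired two miRNA
hubs (each fed by 2 TFs and silencing 6 targets, which adds 12 FFLs per
hub); the sparse background contributed the remainder. FFLs are massively
enriched over the size-preserving permutation null (Z ≈ 73 ≫ 2) while FBLs
are not; almost all miRNA-containing FFLs carry the miRNA at the
intermediate Y position; the GO-similarity split correctly separates the
party hub (identically annotated targets, similarity 1.0) from the date hub
(disjoint annotations, similarity 0.0); and the core-network layering
recovers the planted 6 top / 3 middle scaffold.

The same pipeline is scriptable from the shell:

```bash
mirnet simulate --outdir fixtures --seed 42
mirnet assemble --mti fixtures/edges_mti.tsv --tmi fixtures/edges_tmi.tsv \
       --tti fixtures/edges_tti.tsv --roles fixtures/roles.tsv --out net.tsv
mirnet motifs --net net.tsv --n-perm 1000 --seed 42
mirnet hubs --net net.tsv --go fixtures/go_annotations.tsv --out hubs.tsv
mirnet layers --net net.tsv --out layers.tsv
mirnet annotate-peaks --bed fixtures/peaks.bed --gff fixtures/genome.gff3 --out assign.tsv
mirnet compile-mti --pred-a fixtures/predictions_a.tsv --pred-b fixtures/predictions_b.tsv \
       --degradome fixtures/degradome.tsv --curated fixtures/curated.tsv --out mti.tsv
```

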