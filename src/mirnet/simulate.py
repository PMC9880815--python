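"""Synthetic fixtures with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes —
FFL enrichment over a sparse background, output-heavy miRNA hubs bridging
functional modules, a three-layer TF-miRNA core wired downward, promoter
windows containing a known fraction of ChIP peaks, predictor tables with a
known merge outcome, and miRNA-target up-shifts confined to an *ago1*-like
condition — without attempting to mimic any real network's exact counts.

Planted structures are wired deterministically on reserved nodes and
Bernoulli background edges are drawn only among the remaining background
nodes.  Recovery of the planted labels by the analysis rules is therefore a
structural property of the construction, not a statistical one (see the
methods note for the argument).  All randomness flows from one
``numpy.random.default_rng(seed)`` stream, so identical configurations give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import GeneAnchor, Peak, WindowParams, compute_window, write_anchors_gff3, write_peaks_bed
from .mti import Pair
from .network import InteractionEdge, NodeRecord, RegulatoryNetwork

MODULE_LABELS = (
    "aba_response", "floral_development", "light_signaling", "circadian_rhythm",
    "polarity_identity", "trichome", "embryogenesis", "other",
)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeCounts:
    core_tf: int = 12
    tf: int = 40
    mirna: int = 100
    target_gene: int = 150


@dataclass(frozen=True)
class BackgroundRates:
    """Bernoulli edge probabilities per class among background nodes."""

    tti: float = 0.005
    tmi: float = 0.01
    mti: float = 0.01


@dataclass(frozen=True)
class FFLSpec:
    """Planted feed-forward loops by miRNA position.

    Y-position loops (the canonical TF -> miRNA -> target configuration) use
    a unique miRNA per loop, which guarantees that with zero background the
    census finds exactly the planted instances.
    """

    n_y: int = 30
    n_x: int = 0
    n_z: int = 0
    input_pool: int = 6
    output_pool: int = 15


@dataclass(frozen=True)
class HubSpec:
    n_targets: int = 6
    n_upstream: int = 2


@dataclass(frozen=True)
class LayerSpec:
    """Core-network scaffold: top regulators, high-CC middle, bottom rest.

    Each top TF fans out to ``fanout`` dedicated bottom miRNAs; middle
    miRNAs sit in a triangle with one connected pair of top TFs.  The wiring
    probabilities add optional random downward edges; top->middle,
    top->bottom and within-layer default to 0 because such edges can create
    triangles that blur the planted layer labels.
    """

    n_top: int = 6
    n_middle: int = 3
    fanout: int = 10
    p_top_middle: float = 0.0
    p_top_bottom: float = 0.0
    p_middle_bottom: float = 0.05
    p_within_layer: float = 0.0


@dataclass(frozen=True)
class GenomeSpec:
    n_chromosomes: int = 2
    chrom_length: int = 400_000
    n_coding_genes: int = 30
    n_mirna_loci: int = 10
    n_peaks: int = 200
    frac_in_window: float = 0.7
    n_tfs: int = 5
    spacing: int = 12_000
    peak_halfwidth: int = 75  # peaks are 2*hw + 1 bp so midpoints mirror exactly


@dataclass(frozen=True)
class PredictionSpec:
    n_both: int = 40
    n_single_a: int = 40
    n_single_b: int = 40
    degradome_frac: float = 0.3
    both_degradome_frac: float = 0.25
    n_degradome_only: int = 10
    n_curated: int = 15
    benchmark_size: int = 40
    n_mirnas: int = 30


@dataclass(frozen=True)
class ExpressionSpec:
    effect: float = 1.0
    noise_sd: float = 0.3
    conditions: tuple[str, ...] = ("wt", "ago1_like", "rdr6_like")
    effect_condition: str = "ago1_like"


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    nodes: NodeCounts = field(default_factory=NodeCounts)
    background: BackgroundRates = field(default_factory=BackgroundRates)
    ffls: FFLSpec = field(default_factory=FFLSpec)
    party_hub: HubSpec | None = field(default_factory=HubSpec)
    date_hub: HubSpec | None = field(default_factory=HubSpec)
    layers: LayerSpec | None = field(default_factory=LayerSpec)
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    predictions: PredictionSpec = field(default_factory=PredictionSpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    conserved_fraction: float = 0.5

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        kwargs = dict(d)
        for key, sub in (("nodes", NodeCounts), ("background", BackgroundRates),
                         ("ffls", FFLSpec), ("party_hub", HubSpec), ("date_hub", HubSpec),
                         ("layers", LayerSpec), ("genome", GenomeSpec),
                         ("predictions", PredictionSpec), ("expression", ExpressionSpec)):
            if key in kwargs and isinstance(kwargs[key], Mapping):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted structures against which recovery is asserted."""

    planted_ffls: list[tuple[str, str, str]] = field(default_factory=list)
    hub_types: dict[str, str] = field(default_factory=dict)
    layers: dict[str, str] = field(default_factory=dict)
    peak_assignments: dict[str, tuple[str, ...]] = field(default_factory=dict)
    merge_result: dict[Pair, str] = field(default_factory=dict)
    expression_effects: dict[str, float] = field(default_factory=dict)
    modules: dict[str, str] = field(default_factory=dict)
    go_annotations: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "planted_ffls": [list(t) for t in self.planted_ffls],
            "hub_types": self.hub_types,
            "layers": self.layers,
            "peak_assignments": {k: list(v) for k, v in sorted(self.peak_assignments.items())},
            "merge_result": [[m, g, prov] for (m, g), prov in sorted(self.merge_result.items())],
            "expression_effects": dict(sorted(self.expression_effects.items())),
            "modules": self.modules,
            "go_annotations": {k: sorted(v) for k, v in sorted(self.go_annotations.items())},
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class NetworkSimulation:
    network: RegulatoryNetwork
    truth: GroundTruth
    config: SimulationConfig


@dataclass
class GenomeSimulation:
    anchors: list[GeneAnchor]
    peaks: list[Peak]
    truth: dict[str, tuple[str, ...]]


@dataclass
class PredictionSimulation:
    pred_a: pd.DataFrame
    pred_b: pd.DataFrame
    degradome: pd.DataFrame
    curated: set[Pair]
    benchmark: set[Pair]
    truth_merge: dict[Pair, str]


# ---------------------------------------------------------------------------
# network generator
# ---------------------------------------------------------------------------

def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(n)]


def simulate_network(config: SimulationConfig) -> NetworkSimulation:
    """Typed network with planted FFLs, party/date hubs and a layered core.

    Background Bernoulli edges (per edge class, honouring role constraints)
    are confined to nodes not used by any planted structure.
    """
    rng = np.random.default_rng(config.seed)
    nc, ffls = config.nodes, config.ffls
    lay = config.layers

    core_tf = _ids("CTF", nc.core_tf)
    tf = _ids("TF", nc.tf)
    mirna = _ids("MIR", nc.mirna)
    target = _ids("GENE", nc.target_gene)

    # --- reserve nodes for the planted structures -------------------------
    def take(pool: list[str], k: int, what: str) -> list[str]:
        if len(pool) < k:
            raise ValueError(f"not enough nodes to plant {what} (need {k} more)")
        chunk, pool[:] = pool[:k], pool[k:]
        return chunk

    free_ctf, free_tf = list(core_tf), list(tf)
    free_mir, free_tg = list(mirna), list(target)

    tops = take(free_ctf, lay.n_top, "top layer") if lay else []
    ffl_inputs = take(free_ctf, ffls.input_pool if ffls.n_y else 0, "FFL inputs")
    middles = take(free_mir, lay.n_middle, "middle layer") if lay else []
    ffl_y_mirnas = take(free_mir, ffls.n_y, "Y-position FFLs")
    ffl_x_mirnas = take(free_mir, ffls.n_x, "X-position FFLs")
    ffl_z_mirnas = take(free_mir, ffls.n_z, "Z-position FFLs")
    scaffold_bottom = take(free_mir, lay.n_top * lay.fanout, "layer scaffold") if lay else []
    party = take(free_mir, 1, "party hub")[0] if config.party_hub else None
    date = take(free_mir, 1, "date hub")[0] if config.date_hub else None
    ffl_outputs = take(free_tg, ffls.output_pool if (ffls.n_y or ffls.n_x) else 0,
                       "FFL outputs")
    party_targets = take(free_tg, config.party_hub.n_targets, "party hub") if party else []
    date_targets = take(free_tg, config.date_hub.n_targets, "date hub") if date else []
    party_tfs = take(free_tf, config.party_hub.n_upstream, "party hub TFs") if party else []
    date_tfs = take(free_tf, config.date_hub.n_upstream, "date hub TFs") if date else []
    # pools used by X/Z-position loops (vertex-disjoint pairs for Z planting)
    ffl_aux_tfs = take(free_tf, ffls.n_x + 2 * ffls.n_z, "X/Z-position FFLs")
    if lay and lay.n_middle > lay.n_top // 2:
        raise ValueError("need n_top >= 2 * n_middle for the layer scaffold")

    net = RegulatoryNetwork()
    conserved = set(m for m in mirna if rng.random() < config.conserved_fraction)
    modules: dict[str, str] = {}
    if party:
        for t in party_tfs:
            modules[t] = "floral_development"
    if date:
        for i, t in enumerate(date_tfs):
            modules[t] = MODULE_LABELS[i % len(MODULE_LABELS)]
    for nid in core_tf:
        net.add_node(NodeRecord(nid, "core_tf", module_label=modules.get(nid)))
    for nid in tf:
        net.add_node(NodeRecord(nid, "tf", module_label=modules.get(nid)))
    for nid in mirna:
        net.add_node(NodeRecord(nid, "mirna", conserved=nid in conserved))
    for nid in target:
        net.add_node(NodeRecord(nid, "target_gene"))

    truth = GroundTruth(modules=dict(modules))
    signs = ("activating", "repressing")

    def add(source: str, tgt: str, cls: str, evidence: str, sign: str | None = None) -> None:
        if sign is None:
            sign = "repressing" if cls == "MTI" else str(rng.choice(signs))
        net.add_edge(InteractionEdge(source, tgt, cls, sign, evidence), validate=True)

    # --- layer scaffold ----------------------------------------------------
    if lay:
        for i, t in enumerate(tops):
            for b in scaffold_bottom[i * lay.fanout:(i + 1) * lay.fanout]:
                add(t, b, "TMI", "scaffold")
        for i, m in enumerate(middles):
            t_even, t_odd = tops[2 * i], tops[2 * i + 1]
            add(t_even, t_odd, "TTI", "scaffold")
            add(t_even, m, "TMI", "scaffold")
            add(t_odd, m, "TMI", "scaffold")
        for t in tops:
            for m in middles:
                if rng.random() < lay.p_top_middle:
                    add(t, m, "TMI", "scaffold-extra")
            for b in scaffold_bottom:
                if rng.random() < lay.p_top_bottom:
                    add(t, b, "TMI", "scaffold-extra")
            for t2 in tops:
                if t2 != t and rng.random() < lay.p_within_layer:
                    add(t, t2, "TTI", "scaffold-extra")
        for m in middles:
            for g in free_tg:
                if rng.random() < lay.p_middle_bottom:
                    add(m, g, "MTI", "scaffold-extra")
        core_roles = {"core_tf", "tf", "mirna"}
        truth.layers = {n: "bottom" for n, rec in net.nodes.items() if rec.role in core_roles}
        truth.layers.update({t: "top" for t in tops})
        truth.layers.update({m: "middle" for m in middles})

    # --- planted FFLs -------------------------------------------------------
    for i, y in enumerate(ffl_y_mirnas):
        x = ffl_inputs[i % len(ffl_inputs)]
        z = ffl_outputs[int(rng.integers(len(ffl_outputs)))]
        add(x, y, "TMI", "planted-ffl")
        add(y, z, "MTI", "planted-ffl")
        add(x, z, "TTI", "planted-ffl")
        truth.planted_ffls.append((x, y, z))
    for i, x in enumerate(ffl_x_mirnas):
        y = ffl_aux_tfs[i]
        z = ffl_outputs[int(rng.integers(len(ffl_outputs)))]
        add(x, y, "MTI", "planted-ffl")
        add(y, z, "TTI", "planted-ffl")
        add(x, z, "MTI", "planted-ffl")
        truth.planted_ffls.append((x, y, z))
    for i, z in enumerate(ffl_z_mirnas):
        x = ffl_aux_tfs[ffls.n_x + 2 * i]
        y = ffl_aux_tfs[ffls.n_x + 2 * i + 1]
        add(x, y, "TTI", "planted-ffl")
        add(y, z, "TMI", "planted-ffl")
        add(x, z, "TMI", "planted-ffl")
        truth.planted_ffls.append((x, y, z))

    # --- planted hubs -------------------------------------------------------
    for hub, hub_tfs, hub_targets, hub_type in (
        (party, party_tfs, party_targets, "party"),
        (date, date_tfs, date_targets, "date"),
    ):
        if hub is None:
            continue
        for t in hub_tfs:
            add(t, hub, "TMI", f"planted-{hub_type}-hub")
            for g in hub_targets:
                add(t, g, "TTI", f"planted-{hub_type}-hub")
        for g in hub_targets:
            add(hub, g, "MTI", f"planted-{hub_type}-hub")
        truth.hub_types[hub] = hub_type
    party_terms = ("GO:P0001", "GO:P0002", "GO:P0003")
    for g in party_targets:
        truth.go_annotations[g] = party_terms
    for i, g in enumerate(date_targets):
        truth.go_annotations[g] = (f"GO:D{i:04d}",)
    go_pool = [f"GO:B{i:04d}" for i in range(60)]
    for g in free_tg:
        if rng.random() < 0.7:
            k = int(rng.integers(1, 4))
            picks = rng.choice(len(go_pool), size=k, replace=False)
            truth.go_annotations[g] = tuple(sorted(go_pool[j] for j in picks))

    # --- background ---------------------------------------------------------
    bg = config.background
    for pool_src, pool_tgt, cls, p in (
        (free_tf, free_tg, "TTI", bg.tti),
        (free_tf, free_mir, "TMI", bg.tmi),
        (free_mir, free_tg, "MTI", bg.mti),
    ):
        if p <= 0 or not pool_src or not pool_tgt:
            continue
        mask = rng.random((len(pool_src), len(pool_tgt))) < p
        for i, j in zip(*np.nonzero(mask)):
            add(pool_src[i], pool_tgt[j], cls, "background")

    return NetworkSimulation(network=net, truth=truth, config=config)


# ---------------------------------------------------------------------------
# genome generator
# ---------------------------------------------------------------------------

_PLUS_STRUCTURE = (
    ("five_prime_utr", 0, 300), ("exon", 0, 1000),
    ("exon", 1800, 3000), ("three_prime_utr", 2700, 3000),
)
_GENE_SPAN = 3000
_MIRNA_SPAN = 200


def _coding_structure(gstart: int, strand: str) -> tuple[tuple[str, int, int], ...]:
    out = []
    for label, s, e in _PLUS_STRUCTURE:
        if strand == "-":
            s, e = _GENE_SPAN - e, _GENE_SPAN - s
        out.append((label, gstart + s, gstart + e))
    return tuple(sorted(out, key=lambda t: (t[1], t[2], t[0])))


def simulate_genome(config: SimulationConfig,
                    params: WindowParams = WindowParams()) -> GenomeSimulation:
    """Gene/pre-miRNA anchors plus peaks with known window membership.

    Loci are spaced so their binding windows never overlap; the configured
    fraction of peaks is placed with the midpoint inside a known window and
    the rest strictly outside every window.  Peaks are an odd number of
    bases long so the lower-median midpoint is exact under strand mirroring.
    """
    gs = config.genome
    rng = np.random.default_rng(config.seed + 1)
    per_chrom = -(-(gs.n_coding_genes + gs.n_mirna_loci) // gs.n_chromosomes)
    if 5000 + per_chrom * gs.spacing + 5000 > gs.chrom_length:
        raise ValueError("chromosomes too short for the requested locus count")

    anchors: list[GeneAnchor] = []
    slots = [(f"chr{c + 1}", 5000 + k * gs.spacing)
             for k in range(per_chrom) for c in range(gs.n_chromosomes)]
    for i in range(gs.n_coding_genes + gs.n_mirna_loci):
        chrom, pos = slots[i]
        strand = "+" if rng.random() < 0.5 else "-"
        if i < gs.n_coding_genes:
            span = (pos, pos + _GENE_SPAN)
            anchors.append(GeneAnchor(
                gene_id=f"SGENE{i:04d}", chrom=chrom, strand=strand,
                anchor=pos if strand == "+" else pos + _GENE_SPAN - 1,
                gene_class="coding", span=span,
                structure=_coding_structure(pos, strand)))
        else:
            span = (pos, pos + _MIRNA_SPAN)
            anchors.append(GeneAnchor(
                gene_id=f"SMIR{i - gs.n_coding_genes:04d}", chrom=chrom, strand=strand,
                anchor=pos if strand == "+" else pos + _MIRNA_SPAN - 1,
                gene_class="mirna", span=span, structure=None))

    windows: dict[str, list[tuple[int, int, str]]] = {}
    for a in anchors:
        lo, hi = compute_window(a, params)
        windows.setdefault(a.chrom, []).append((lo, hi, a.gene_id))

    def genes_at(chrom: str, mid: int) -> tuple[str, ...]:
        return tuple(sorted(g for lo, hi, g in windows.get(chrom, ()) if lo <= mid <= hi))

    tf_ids = [f"STF{i:02d}" for i in range(gs.n_tfs)]
    hw = gs.peak_halfwidth
    n_in = int(round(gs.frac_in_window * gs.n_peaks))
    peaks, truth = [], {}
    for i in range(gs.n_peaks):
        if i < n_in:
            a = anchors[int(rng.integers(len(anchors)))]
            lo, hi = compute_window(a, params)
            mid = int(rng.integers(lo, hi + 1))
            chrom = a.chrom
        else:
            while True:
                chrom = f"chr{int(rng.integers(gs.n_chromosomes)) + 1}"
                mid = int(rng.integers(hw, gs.chrom_length - hw - 1))
                if not genes_at(chrom, mid):
                    break
        pid = f"peak{i:06d}"
        peaks.append(Peak(chrom=chrom, start=mid - hw, end=mid + hw + 1,
                          tf_id=tf_ids[int(rng.integers(len(tf_ids)))], peak_id=pid))
        truth[pid] = genes_at(chrom, mid)
    return GenomeSimulation(anchors=anchors, peaks=peaks, truth=truth)


# ---------------------------------------------------------------------------
# prediction-table generator
# ---------------------------------------------------------------------------

def simulate_predictions(config: SimulationConfig) -> PredictionSimulation:
    """Two predictor tables, degradome support, curated and benchmark lists.

    The intended merge result is known by construction: pairs predicted by
    both programs, plus single-program pairs with degradome support; decoys
    are single-program pairs without support and degradome-only pairs.
    """
    ps = config.predictions
    rng = np.random.default_rng(config.seed + 2)
    n_pairs = ps.n_both + ps.n_single_a + ps.n_single_b + ps.n_degradome_only + ps.n_curated
    mirnas = [f"sim-miR{i:03d}" for i in range(ps.n_mirnas)]
    pairs = [(mirnas[k % ps.n_mirnas], f"T{k:05d}") for k in range(n_pairs)]

    cut1 = ps.n_both
    cut2 = cut1 + ps.n_single_a
    cut3 = cut2 + ps.n_single_b
    cut4 = cut3 + ps.n_degradome_only
    both, only_a = pairs[:cut1], pairs[cut1:cut2]
    only_b, deg_only = pairs[cut2:cut3], pairs[cut3:cut4]
    curated = set(pairs[cut4:])

    n_both_deg = int(round(ps.both_degradome_frac * len(both)))
    n_a_deg = int(round(ps.degradome_frac * len(only_a)))
    n_b_deg = int(round(ps.degradome_frac * len(only_b)))
    supported = set(both[:n_both_deg]) | set(only_a[:n_a_deg]) | set(only_b[:n_b_deg])
    supported |= set(deg_only)

    truth = {}
    for p in both:
        truth[p] = "both" if p in supported else "both_programs"
    for p in only_a[:n_a_deg] + only_b[:n_b_deg]:
        truth[p] = "degradome_supported"

    def table(pair_list: Sequence[Pair], program: str) -> pd.DataFrame:
        rows = sorted(pair_list)
        return pd.DataFrame({
            "mirna": [m for m, _ in rows],
            "gene": [g for _, g in rows],
            "program": program,
            "score": np.round(rng.uniform(0.2, 2.4, size=len(rows)), 2),
        })

    pred_a = table(both + only_a, "A")
    pred_b = table(both + only_b, "B")
    deg_rows = sorted(supported) + sorted(set(only_a[n_a_deg:]) | set(only_b[n_b_deg:]))
    degradome = pd.DataFrame({
        "mirna": [m for m, _ in deg_rows],
        "gene": [g for _, g in deg_rows],
        "supported": [p in supported for p in deg_rows],
        "category": ["middle_three" if p in supported else "none" for p in deg_rows],
    })

    eligible = sorted(set(truth) | curated)
    if ps.benchmark_size > len(eligible):
        raise ValueError("benchmark larger than the validated pool")
    picks = rng.choice(len(eligible), size=ps.benchmark_size, replace=False)
    benchmark = {eligible[i] for i in picks}
    return PredictionSimulation(pred_a=pred_a, pred_b=pred_b, degradome=degradome,
                                curated=curated, benchmark=benchmark, truth_merge=truth)


# ---------------------------------------------------------------------------
# expression generator
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig,
    network: RegulatoryNetwork,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Relative expression per gene and condition, shifted for miRNA targets.

    Genes that receive an MTI edge get the configured effect (log-units)
    added in the effect condition only, on top of Gaussian noise; the wild
    type and the control condition stay centred at zero.
    """
    es = config.expression
    rng = np.random.default_rng(config.seed + 3)
    targets = sorted({e.target for e in network.edges.values()
                      if e.edge_class == "MTI" and not e.is_self_loop})
    if not targets:
        raise ValueError("network has no MTI targets to shift")
    genes = sorted(n for n, rec in network.nodes.items() if rec.role != "mirna")
    target_set = set(targets)
    rows = []
    effects = {}
    for g in genes:
        effects[g] = es.effect if g in target_set else 0.0
        for cond in es.conditions:
            level = float(rng.normal(0.0, es.noise_sd)) if es.noise_sd > 0 else 0.0
            if cond == es.effect_condition:
                level += effects[g]
            rows.append((g, cond, level))
    return pd.DataFrame(rows, columns=["gene", "condition", "rel_level"]), effects


# ---------------------------------------------------------------------------
# bundle writer
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# mirnet-sim seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def network_tables(network: RegulatoryNetwork) -> dict[str, pd.DataFrame]:
    """Role table plus one edge table per interaction class."""
    roles = pd.DataFrame(
        [(r.id, r.role, r.conserved, r.module_label or "")
         for r in sorted(network.nodes.values(), key=lambda r: r.id)],
        columns=["id", "role", "conserved", "module_label"])
    out = {"roles": roles}
    for cls in ("MTI", "TMI", "TTI"):
        rows = [(e.source, e.target, e.edge_class, e.sign, e.evidence)
                for e in sorted(network.edges.values(), key=lambda e: e.key)
                if e.edge_class == cls]
        out[cls.lower()] = pd.DataFrame(
            rows, columns=["source", "target", "edge_class", "sign", "evidence"])
    return out


def simulate_all(config: SimulationConfig, outdir: str | Path) -> GroundTruth:
    """Run every generator and write the full fixture bundle to ``outdir``.

    Emits role/edge TSVs, GO and module tables, GFF3 + BED genomic fixtures,
    prediction/degradome/curated/benchmark tables, the expression table, and
    ``ground_truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    sim = simulate_network(config)
    truth = sim.truth
    for name, df in network_tables(sim.network).items():
        _write_tsv(df, outdir / f"{'edges_' + name if name != 'roles' else 'roles'}.tsv", seed)

    go_df = pd.DataFrame(
        [(g, ",".join(sorted(terms))) for g, terms in sorted(truth.go_annotations.items())],
        columns=["gene", "go_terms"])
    _write_tsv(go_df, outdir / "go_annotations.tsv", seed)
    mod_df = pd.DataFrame(sorted(truth.modules.items()), columns=["tf", "module"])
    _write_tsv(mod_df, outdir / "modules.tsv", seed)

    genome = simulate_genome(config)
    write_anchors_gff3(genome.anchors, outdir / "genome.gff3")
    write_peaks_bed(genome.peaks, outdir / "peaks.bed")
    truth.peak_assignments = genome.truth

    preds = simulate_predictions(config)
    _write_tsv(preds.pred_a, outdir / "predictions_a.tsv", seed)
    _write_tsv(preds.pred_b, outdir / "predictions_b.tsv", seed)
    _write_tsv(preds.degradome, outdir / "degradome.tsv", seed)
    _write_tsv(pd.DataFrame(sorted(preds.curated), columns=["mirna", "gene"]),
               outdir / "curated.tsv", seed)
    _write_tsv(pd.DataFrame(sorted(preds.benchmark), columns=["mirna", "gene"]),
               outdir / "benchmark.tsv", seed)
    truth.merge_result = preds.truth_merge

    expr, effects = simulate_expression(config, sim.network)
    _write_tsv(expr, outdir / "expression.tsv", seed)
    truth.expression_effects = effects

    (outdir / "ground_truth.json").write_text(truth.to_json(), encoding="utf-8")
    return truth
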