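"""Hub classification, core-network hierarchy, and expression overlays.

Hubs are high-degree nodes: in hubs (in-degree > 10), out hubs (out-degree
> 10), and party/date hub candidates (out-degree > 5 with clustering
coefficient above the network average CC_a).  Candidates split into party
hubs, whose targets share similar functional (GO) annotation and act inside
one module, and date hubs, whose targets are functionally dissimilar and
bridge modules.  GO similarity is the mean pairwise Jaccard index over the
targets' GO term sets.

The TF-miRNA core network (induced on TF and miRNA nodes) is decomposed into
three hierarchical layers from clustering coefficients and degrees; FFLs are
then scored for whether their input node X sits in a higher layer than their
output node Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import FFLInstance
from .network import TF_ROLES, RegulatoryNetwork

LAYERS = ("top", "middle", "bottom")
_LAYER_RANK = {"top": 2, "middle": 1, "bottom": 0}


@dataclass(frozen=True)
class HubThresholds:
    """Degree cutoffs for hub calls (all strict inequalities)."""

    in_degree: int = 10
    out_degree: int = 10
    party_out: int = 5


@dataclass
class HubRecord:
    node: str
    role: str
    d_in: int
    d_out: int
    cc: float
    is_in_hub: bool
    is_out_hub: bool
    hub_candidate: bool
    hub_type: str = "none"
    go_similarity: float = float("nan")
    i_generalization: int = 0
    o_generalization: int = 0
    n_output_ffls: int = 0


def classify_hubs(
    network: RegulatoryNetwork,
    thresholds: HubThresholds = HubThresholds(),
) -> dict[str, HubRecord]:
    """Flag in/out hubs and party/date hub candidates for every node.

    Degrees exclude self-loops; CC is computed on the undirected simple
    projection and CC_a once over the full network.  A candidate needs
    out-degree strictly above ``party_out`` and CC strictly above CC_a.
    """
    succ, pred = network.adjacency()
    import networkx as nx

    clustering = nx.clustering(network.to_undirected_simple())
    cc_a = float(np.mean(list(clustering.values()))) if clustering else 0.0
    records = {}
    for nid, rec in network.nodes.items():
        d_in, d_out = len(pred[nid]), len(succ[nid])
        cc = float(clustering.get(nid, 0.0))
        records[nid] = HubRecord(
            node=nid, role=rec.role, d_in=d_in, d_out=d_out, cc=cc,
            is_in_hub=d_in > thresholds.in_degree,
            is_out_hub=d_out > thresholds.out_degree,
            hub_candidate=d_out > thresholds.party_out and cc > cc_a,
        )
    return records


@dataclass
class GoPartition:
    """Party/date call for one hub from the GO similarity of its targets."""

    hub_type: str | None  # 'party', 'date', or None when unclassifiable
    go_similarity: float
    n_annotated: int
    n_unannotated: int


def go_partition(
    targets: Iterable[str],
    go: Mapping[str, Iterable[str]],
    threshold: float = 0.3,
) -> GoPartition:
    """Split a hub into party vs date from its targets' GO term sets.

    Similarity is the mean pairwise Jaccard index over targets that carry at
    least one GO term; a hub is a party hub when similarity >= ``threshold``.
    Fewer than two annotated targets -> unclassifiable (hub_type None).
    """
    term_sets = []
    n_unannotated = 0
    for t in sorted(set(targets)):
        terms = frozenset(go.get(t, ()))
        if terms:
            term_sets.append(terms)
        else:
            n_unannotated += 1
    if len(term_sets) < 2:
        return GoPartition(None, float("nan"), len(term_sets), n_unannotated)
    sims = [len(s & t) / len(s | t) for s, t in combinations(term_sets, 2)]
    sim = float(np.mean(sims))
    return GoPartition("party" if sim >= threshold else "date", sim,
                       len(term_sets), n_unannotated)


def classify_hub_types(
    network: RegulatoryNetwork,
    go: Mapping[str, Iterable[str]],
    thresholds: HubThresholds = HubThresholds(),
    similarity_threshold: float = 0.3,
    ffl_instances: Sequence[FFLInstance] | None = None,
) -> dict[str, HubRecord]:
    """Full hub report: flags plus party/date calls for miRNA hub candidates.

    Targets are the MTI out-neighbours of each candidate miRNA.  When FFL
    instances are supplied, topological-generalization counts are attached.
    """
    records = classify_hubs(network, thresholds)
    succ_mti: dict[str, set] = {}
    for e in network.edges.values():
        if e.edge_class == "MTI" and not e.is_self_loop:
            succ_mti.setdefault(e.source, set()).add(e.target)
    for nid, rec in records.items():
        if rec.role == "mirna" and rec.hub_candidate:
            part = go_partition(succ_mti.get(nid, ()), go, similarity_threshold)
            rec.go_similarity = part.go_similarity
            rec.hub_type = part.hub_type or "none"
        if ffl_instances is not None:
            i_gen, o_gen, n_out = count_generalization(nid, ffl_instances)
            rec.i_generalization, rec.o_generalization, rec.n_output_ffls = i_gen, o_gen, n_out
    return records


def count_generalization(
    hub: str,
    ffl_instances: Sequence[FFLInstance],
) -> tuple[int, int, int]:
    """Topological-generalization degree of a hub used as the FFL Y node.

    Returns ``(i, o, n_output_ffls)``: the number of distinct input nodes X,
    distinct output nodes Z, and FFL instances in which ``hub`` is the
    intermediate node.
    """
    xs, zs, n = set(), set(), 0
    for inst in ffl_instances:
        if inst.y == hub:
            n += 1
            xs.add(inst.x)
            zs.add(inst.z)
    return len(xs), len(zs), n


# ---------------------------------------------------------------------------
# core network and hierarchical layers
# ---------------------------------------------------------------------------

@dataclass
class CoreReport:
    n_tf: int
    n_mirna: int
    n_nodes: int
    n_edges: int


def extract_core(network: RegulatoryNetwork) -> tuple[RegulatoryNetwork, CoreReport]:
    """Induced TF-miRNA core network (target genes dropped)."""
    keep = [n for n, rec in network.nodes.items() if rec.role in TF_ROLES | {"mirna"}]
    core = network.subgraph(keep)
    counts = core.role_counts()
    report = CoreReport(
        n_tf=counts.get("tf", 0) + counts.get("core_tf", 0),
        n_mirna=counts.get("mirna", 0),
        n_nodes=core.n_nodes,
        n_edges=core.n_edges,
    )
    if core.n_nodes == 0:
        import warnings

        warnings.warn("core network is empty (no TF or miRNA nodes)")
    return core, report


@dataclass
class LayerAssignment:
    """Top/middle/bottom layer labels over the core network."""

    layers: dict[str, str]
    cc_a: float
    degree_threshold: int

    def summary(self) -> dict[str, dict[str, float]]:
        """Counts and fractions per layer."""
        n = len(self.layers)
        out = {}
        for layer in LAYERS:
            k = sum(1 for v in self.layers.values() if v == layer)
            out[layer] = {"count": k, "fraction": k / n if n else float("nan")}
        return out


def assign_layers(
    core: RegulatoryNetwork,
    degree_threshold: int = 10,
    cc_a: float | None = None,
) -> LayerAssignment:
    """Partition core-network nodes into three hierarchical layers.

    Nodes with CC strictly above the average CC_a form the middle layer.
    Among the rest, out-heavy regulators (D_out >= threshold, D_in <
    threshold) are the top layer and everything else the bottom layer
    (including in-heavy nodes and nodes matching neither degree sub-rule).
    CC, degrees and (by default) CC_a are computed on the core network;
    pass ``cc_a`` to reuse a pan-network average instead.
    """
    import networkx as nx

    succ, pred = core.adjacency()
    clustering = nx.clustering(core.to_undirected_simple())
    if cc_a is None:
        cc_a = float(np.mean(list(clustering.values()))) if clustering else 0.0
    layers = {}
    for nid in core.nodes:
        cc = clustering.get(nid, 0.0)
        d_in, d_out = len(pred[nid]), len(succ[nid])
        if cc > cc_a:
            layers[nid] = "middle"
        elif d_out >= degree_threshold and d_in < degree_threshold:
            layers[nid] = "top"
        else:
            layers[nid] = "bottom"
    return LayerAssignment(layers=layers, cc_a=cc_a, degree_threshold=degree_threshold)


@dataclass
class OrientationReport:
    """Three-way tally of layer(X) vs layer(Z) over FFL instances."""

    n_higher: int
    n_equal: int
    n_lower: int
    n_skipped: int
    fraction_higher: float
    mirna_subset: "OrientationReport | None" = None

    @property
    def n_classified(self) -> int:
        return self.n_higher + self.n_equal + self.n_lower


def layer_orientation(
    ffl_instances: Sequence[FFLInstance],
    layers: LayerAssignment | Mapping[str, str],
) -> OrientationReport:
    """Fraction of FFLs whose input X sits strictly above output Z.

    Layer order is top > middle > bottom.  Instances whose X or Z lacks a
    layer label are skipped (counted).  The miRNA-containing subset (per the
    instances' ``contains_mirna`` flags) is reported separately.
    """
    lay = layers.layers if isinstance(layers, LayerAssignment) else dict(layers)

    def _tally(insts: Sequence[FFLInstance]) -> tuple[int, int, int, int]:
        hi = eq = lo = skipped = 0
        for inst in insts:
            lx, lz = lay.get(inst.x), lay.get(inst.z)
            if lx is None or lz is None:
                skipped += 1
            elif _LAYER_RANK[lx] > _LAYER_RANK[lz]:
                hi += 1
            elif _LAYER_RANK[lx] == _LAYER_RANK[lz]:
                eq += 1
            else:
                lo += 1
        return hi, eq, lo, skipped

    hi, eq, lo, skipped = _tally(ffl_instances)
    total = hi + eq + lo
    sub = [i for i in ffl_instances if i.contains_mirna]
    mirna_report = None
    if sub:
        shi, seq, slo, ssk = _tally(sub)
        stot = shi + seq + slo
        mirna_report = OrientationReport(shi, seq, slo, ssk,
                                         shi / stot if stot else float("nan"))
    return OrientationReport(hi, eq, lo, skipped,
                             hi / total if total else float("nan"),
                             mirna_subset=mirna_report)


# ---------------------------------------------------------------------------
# module crosstalk and expression overlay
# ---------------------------------------------------------------------------

@dataclass
class ModuleConnectivity:
    modules: set[str]
    n_unlabeled_neighbors: int

    @property
    def n_modules(self) -> int:
        return len(self.modules)


def module_connectivity(
    network: RegulatoryNetwork,
    modules: Mapping[str, str],
    node: str,
) -> ModuleConnectivity:
    """Functional modules a node touches (a date-hub crosstalk measure).

    A module is reached through an incoming TMI from a labelled TF, or
    through an outgoing MTI to a gene that is itself regulated (TTI/TMI) by a
    labelled TF.  Unlabelled TF neighbours are ignored but counted.
    """
    if node not in network.nodes:
        raise KeyError(f"unknown node {node!r}")
    touched: set[str] = set()
    unlabeled = 0
    regulators_of: dict[str, set] = {}
    for e in network.edges.values():
        if e.is_self_loop:
            continue
        if e.edge_class in ("TTI", "TMI"):
            regulators_of.setdefault(e.target, set()).add(e.source)
    for e in network.edges.values():
        if e.is_self_loop:
            continue
        if e.edge_class == "TMI" and e.target == node:
            label = modules.get(e.source)
            if label is None:
                unlabeled += 1
            else:
                touched.add(label)
        elif e.edge_class == "MTI" and e.source == node:
            for tf in regulators_of.get(e.target, ()):
                label = modules.get(tf)
                if label is None:
                    unlabeled += 1
                else:
                    touched.add(label)
    return ModuleConnectivity(modules=touched, n_unlabeled_neighbors=unlabeled)


def mirna_target_share(network: RegulatoryNetwork, nodes: Iterable[str]) -> float:
    """Fraction of the given nodes that receive at least one MTI in-edge."""
    nodes = list(nodes)
    if not nodes:
        raise ValueError("need at least one node")
    targets = {e.target for e in network.edges.values()
               if e.edge_class == "MTI" and not e.is_self_loop}
    return sum(1 for n in nodes if n in targets) / len(nodes)


@dataclass
class ExpressionOverlay:
    """Group-wise expression summaries and pairwise rank-sum tests."""

    summary: pd.DataFrame
    tests: pd.DataFrame
    skipped_groups: list[str] = field(default_factory=list)


def expression_overlay(
    groups: Mapping[str, Iterable[str]],
    expression: pd.DataFrame,
    alternative: str = "two-sided",
    min_group_size: int = 3,
) -> ExpressionOverlay:
    """Compare relative expression between disjoint gene groups per condition.

    ``expression`` is a long table with columns ``gene, condition,
    rel_level`` holding relative (e.g. mutant vs wild type) log-ratios.
    Each group gets mean/median/quartile summaries per condition; each group
    pair gets a Mann-Whitney rank-sum test per condition.  Groups smaller
    than ``min_group_size`` in a condition are summarised but not tested.
    The ``alternative`` refers to the first-named group of each pair.
    """
    required = {"gene", "condition", "rel_level"}
    if not required <= set(expression.columns):
        raise ValueError(f"expression table needs columns {sorted(required)}")
    sets = {name: set(members) for name, members in groups.items()}
    names = list(sets)
    for g1, g2 in combinations(names, 2):
        if sets[g1] & sets[g2]:
            raise ValueError(f"groups {g1!r} and {g2!r} overlap")

    summary_rows, test_rows, skipped = [], [], set()
    for condition, sub in expression.groupby("condition"):
        values = {name: sub.loc[sub["gene"].isin(members), "rel_level"].to_numpy(float)
                  for name, members in sets.items()}
        for name, v in values.items():
            if v.size == 0:
                skipped.add(name)
                continue
            summary_rows.append((name, condition, v.size, float(np.mean(v)),
                                 float(np.median(v)), float(np.percentile(v, 25)),
                                 float(np.percentile(v, 75))))
        for g1, g2 in combinations(names, 2):
            v1, v2 = values[g1], values[g2]
            if v1.size < min_group_size or v2.size < min_group_size:
                skipped.update(n for n, v in ((g1, v1), (g2, v2))
                               if v.size < min_group_size)
                continue
            u, p = stats.mannwhitneyu(v1, v2, alternative=alternative)
            test_rows.append((condition, g1, g2, float(u), float(p),
                              "mannwhitneyu", alternative))

    summary = pd.DataFrame(summary_rows, columns=["group", "condition", "n", "mean",
                                                  "median", "q1", "q3"])
    tests = pd.DataFrame(test_rows, columns=["condition", "group1", "group2",
                                             "statistic", "pvalue", "test", "alternative"])
    return ExpressionOverlay(summary=summary, tests=tests, skipped_groups=sorted(skipped))
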