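"""Typed directed TF–miRNA regulatory network: assembly, topology, import/export.

The central object is :class:`RegulatoryNetwork`, a directed graph whose nodes
carry a regulatory role (``core_tf``, ``tf``, ``mirna``, ``target_gene``) and
whose edges belong to one of three interaction classes:

* ``TMI`` — a TF binds the promoter of a miRNA locus (TF -> miRNA),
* ``TTI`` — a TF binds the promoter of a non-miRNA gene (TF -> gene),
* ``MTI`` — a miRNA silences a target transcript (miRNA -> gene).

Role constraints are enforced at edge insertion so that downstream analyses
(motif census, hub classification, layer decomposition) can rely on them.
Self-loops are stored and flagged but excluded from degrees, topology metrics
and the motif census, whose triad definitions are loop-free.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

ROLES = ("core_tf", "tf", "mirna", "target_gene")
TF_ROLES = frozenset({"core_tf", "tf"})
EDGE_CLASSES = ("TTI", "TMI", "MTI")
SIGNS = ("activating", "repressing", "unknown")

EDGE_TABLE_COLUMNS = ["source", "target", "edge_class", "sign", "evidence"]
ROLE_TABLE_COLUMNS = ["id", "role", "conserved", "module_label"]


class NetworkValidationError(ValueError):
    """Raised when nodes or edges violate role/class constraints.

    Carries a list of human-readable problems, each referencing the offending
    row or identifier.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        preview = "; ".join(self.problems[:5])
        more = "" if len(self.problems) <= 5 else f" (+{len(self.problems) - 5} more)"
        super().__init__(f"{len(self.problems)} validation problem(s): {preview}{more}")


@dataclass(frozen=True)
class NodeRecord:
    """A network node: gene, miRNA locus, or transcription factor."""

    id: str
    role: str
    conserved: bool = False
    module_label: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise NetworkValidationError([f"node {self.id!r}: unknown role {self.role!r}"])
        if self.conserved and self.role != "mirna":
            raise NetworkValidationError(
                [f"node {self.id!r}: conserved flag is only meaningful for miRNAs"]
            )


@dataclass(frozen=True)
class InteractionEdge:
    """A directed regulatory interaction of class TTI, TMI, or MTI."""

    source: str
    target: str
    edge_class: str
    sign: str = "unknown"
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.edge_class not in EDGE_CLASSES:
            raise NetworkValidationError(
                [f"edge {self.source}->{self.target}: unknown class {self.edge_class!r}"]
            )
        if self.sign not in SIGNS:
            raise NetworkValidationError(
                [f"edge {self.source}->{self.target}: unknown sign {self.sign!r}"]
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.edge_class)

    @property
    def is_self_loop(self) -> bool:
        return self.source == self.target


def _edge_role_problem(edge: InteractionEdge, roles: Mapping[str, str]) -> str | None:
    """Return a description of the role incompatibility of ``edge``, if any."""
    src_role = roles.get(edge.source)
    tgt_role = roles.get(edge.target)
    if src_role is None or tgt_role is None:
        missing = [n for n, r in ((edge.source, src_role), (edge.target, tgt_role)) if r is None]
        return f"edge {edge.source}->{edge.target} ({edge.edge_class}): unknown endpoint(s) {missing}"
    if edge.edge_class == "TMI":
        if src_role not in TF_ROLES:
            return f"TMI {edge.source}->{edge.target}: source role {src_role!r} is not a TF"
        if tgt_role != "mirna":
            return f"TMI {edge.source}->{edge.target}: target role {tgt_role!r} is not mirna"
    elif edge.edge_class == "MTI":
        if src_role != "mirna":
            return f"MTI {edge.source}->{edge.target}: source role {src_role!r} is not mirna"
    elif edge.edge_class == "TTI":
        if src_role not in TF_ROLES:
            return f"TTI {edge.source}->{edge.target}: source role {src_role!r} is not a TF"
        if tgt_role == "mirna":
            return f"TTI {edge.source}->{edge.target}: target must not be a miRNA"
    return None


class RegulatoryNetwork:
    """Set of :class:`NodeRecord` plus deduplicated :class:`InteractionEdge`.

    Edges are unique by ``(source, target, edge_class)``. Endpoints must exist
    as nodes before an edge is added.
    """

    def __init__(self) -> None:
        self._nodes: dict[str, NodeRecord] = {}
        self._edges: dict[tuple[str, str, str], InteractionEdge] = {}

    # -- construction -------------------------------------------------------

    def add_node(self, node: NodeRecord) -> None:
        existing = self._nodes.get(node.id)
        if existing is not None and existing != node:
            raise NetworkValidationError(
                [f"node {node.id!r} already present with different attributes"]
            )
        self._nodes[node.id] = node

    def add_edge(self, edge: InteractionEdge, validate: bool = True) -> bool:
        """Insert ``edge``; returns False if an identical key already exists."""
        if validate:
            problem = _edge_role_problem(edge, self.roles)
            if problem is not None:
                raise NetworkValidationError([problem])
        if edge.key in self._edges:
            return False
        self._edges[edge.key] = edge
        return True

    # -- views ---------------------------------------------------------------

    @property
    def nodes(self) -> Mapping[str, NodeRecord]:
        return self._nodes

    @property
    def edges(self) -> Mapping[tuple[str, str, str], InteractionEdge]:
        return self._edges

    @property
    def roles(self) -> dict[str, str]:
        return {n: rec.role for n, rec in self._nodes.items()}

    @property
    def conserved_mirnas(self) -> set[str]:
        return {n for n, rec in self._nodes.items() if rec.role == "mirna" and rec.conserved}

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        """Number of stored edges, self-loops included."""
        return len(self._edges)

    @property
    def self_loops(self) -> list[InteractionEdge]:
        return [e for e in self._edges.values() if e.is_self_loop]

    @property
    def n_structural_edges(self) -> int:
        """Distinct loop-free (source, target) pairs used by topology metrics."""
        return len({(e.source, e.target) for e in self._edges.values() if not e.is_self_loop})

    def role_counts(self) -> Counter:
        return Counter(rec.role for rec in self._nodes.values())

    def class_counts(self) -> Counter:
        return Counter(e.edge_class for e in self._edges.values())

    def edge_sign(self, source: str, target: str) -> str:
        """Sign of the (unique) interaction between two nodes, 'unknown' if absent."""
        for cls in EDGE_CLASSES:
            e = self._edges.get((source, target, cls))
            if e is not None:
                return e.sign
        return "unknown"

    # -- derived graphs ------------------------------------------------------

    def subgraph(self, node_ids: Iterable[str]) -> "RegulatoryNetwork":
        keep = set(node_ids)
        unknown = keep - set(self._nodes)
        if unknown:
            raise KeyError(f"unknown node ids: {sorted(unknown)[:5]}")
        sub = RegulatoryNetwork()
        for nid in keep:
            sub.add_node(self._nodes[nid])
        for edge in self._edges.values():
            if edge.source in keep and edge.target in keep:
                sub.add_edge(edge, validate=False)
        return sub

    def to_digraph(self, include_self_loops: bool = False) -> nx.DiGraph:
        """Simple directed projection with node/edge attributes."""
        g = nx.DiGraph()
        for nid, rec in self._nodes.items():
            g.add_node(nid, role=rec.role, conserved=rec.conserved,
                       module_label=rec.module_label or "")
        for edge in self._edges.values():
            if edge.is_self_loop and not include_self_loops:
                continue
            g.add_edge(edge.source, edge.target, edge_class=edge.edge_class,
                       sign=edge.sign, evidence=edge.evidence)
        return g

    def to_undirected_simple(self) -> nx.Graph:
        """Loop-free undirected projection (antiparallel edges collapsed)."""
        return nx.Graph(self.to_digraph(include_self_loops=False))

    def adjacency(self) -> tuple[dict[str, set], dict[str, set]]:
        """Loop-free successor and predecessor sets for every node."""
        succ: dict[str, set] = {n: set() for n in self._nodes}
        pred: dict[str, set] = {n: set() for n in self._nodes}
        for edge in self._edges.values():
            if edge.is_self_loop:
                continue
            succ[edge.source].add(edge.target)
            pred[edge.target].add(edge.source)
        return succ, pred

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __repr__(self) -> str:
        rc = dict(self.role_counts())
        cc = dict(self.class_counts())
        return f"RegulatoryNetwork(nodes={self.n_nodes} {rc}, edges={self.n_edges} {cc})"


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclass
class AssemblyReport:
    """Node/edge accounting produced by :func:`assemble_network`."""

    nodes_by_role: dict[str, int]
    edges_by_class: dict[str, int]
    n_nodes: int
    n_edges: int
    n_duplicate_rows: int
    n_self_loops: int
    inferred_roles: dict[str, str] = field(default_factory=dict)


def _normalise_edge_table(df: pd.DataFrame, expected_class: str, label: str) -> pd.DataFrame:
    df = df.copy()
    if df.empty and "source" not in df.columns:
        df = pd.DataFrame(columns=EDGE_TABLE_COLUMNS)
    for col, default in (("edge_class", expected_class), ("sign", "unknown"), ("evidence", "")):
        if col not in df.columns:
            df[col] = default
    df["sign"] = df["sign"].fillna("unknown")
    df["evidence"] = df["evidence"].fillna("")
    bad = df.index[df["edge_class"] != expected_class]
    if len(bad):
        raise NetworkValidationError(
            [f"{label} row {i}: edge_class {df.at[i, 'edge_class']!r} != {expected_class}"
             for i in bad]
        )
    return df[EDGE_TABLE_COLUMNS]


def _infer_roles(tables: Mapping[str, pd.DataFrame], known: Mapping[str, str]) -> dict[str, str]:
    """Infer roles of endpoints absent from the role table.

    Only unambiguous inferences are made: the source of an MTI and the target
    of a TMI must be a miRNA.  Any endpoint whose role candidates cannot be
    narrowed to a single role raises, listing the offending ids.
    """
    all_roles = set(ROLES)
    candidates: dict[str, set] = defaultdict(lambda: set(all_roles))
    constraint = {
        ("MTI", "source"): {"mirna"},
        ("MTI", "target"): all_roles,
        ("TMI", "source"): set(TF_ROLES),
        ("TMI", "target"): {"mirna"},
        ("TTI", "source"): set(TF_ROLES),
        ("TTI", "target"): all_roles - {"mirna"},
    }
    for cls, df in tables.items():
        for endpoint in ("source", "target"):
            for nid in df[endpoint].astype(str):
                if nid not in known:
                    candidates[nid] &= constraint[(cls, endpoint)]
    inferred, ambiguous = {}, []
    for nid, cand in candidates.items():
        if len(cand) == 1:
            inferred[nid] = next(iter(cand))
        else:
            ambiguous.append(nid)
    if ambiguous:
        raise NetworkValidationError(
            [f"endpoint {nid!r} absent from role table and role-ambiguous"
             for nid in sorted(ambiguous)]
        )
    return inferred


def assemble_network(
    mti_edges: pd.DataFrame,
    tmi_edges: pd.DataFrame,
    tti_edges: pd.DataFrame,
    node_roles: pd.DataFrame,
) -> tuple[RegulatoryNetwork, AssemblyReport]:
    """Integrate the three interaction classes into one regulatory network.

    Parameters are edge tables (columns ``source target [edge_class sign
    evidence]``) and a role table (``id role [conserved module_label]``).
    Edges are deduplicated by (source, target, class); the node set is the
    union of all endpoints.  Role-incompatible rows raise
    :class:`NetworkValidationError` with row references.
    """
    tables = {
        "MTI": _normalise_edge_table(mti_edges, "MTI", "mti_edges"),
        "TMI": _normalise_edge_table(tmi_edges, "TMI", "tmi_edges"),
        "TTI": _normalise_edge_table(tti_edges, "TTI", "tti_edges"),
    }

    roles_df = node_roles.copy()
    if roles_df.empty and "id" not in roles_df.columns:
        roles_df = pd.DataFrame(columns=ROLE_TABLE_COLUMNS)
    if "conserved" not in roles_df.columns:
        roles_df["conserved"] = False
    if "module_label" not in roles_df.columns:
        roles_df["module_label"] = None

    network = RegulatoryNetwork()
    problems: list[str] = []
    for i, row in roles_df.iterrows():
        try:
            conserved = bool(row["conserved"]) and not pd.isna(row["conserved"])
            label = row["module_label"]
            label = None if (label is None or (isinstance(label, float) and math.isnan(label))
                             or label == "") else str(label)
            network.add_node(NodeRecord(str(row["id"]), str(row["role"]),
                                        conserved=conserved, module_label=label))
        except NetworkValidationError as exc:
            problems.extend(f"role table row {i}: {p}" for p in exc.problems)
    if problems:
        raise NetworkValidationError(problems)

    inferred = _infer_roles(tables, network.roles)
    for nid, role in inferred.items():
        network.add_node(NodeRecord(nid, role))

    roles = network.roles
    n_dup = 0
    for label, df in tables.items():
        for i, row in df.iterrows():
            edge = InteractionEdge(str(row["source"]), str(row["target"]),
                                   row["edge_class"], row["sign"], str(row["evidence"]))
            problem = _edge_role_problem(edge, roles)
            if problem is not None:
                problems.append(f"{label} table row {i}: {problem}")
                continue
            if not network.add_edge(edge, validate=False):
                n_dup += 1
    if problems:
        raise NetworkValidationError(problems)

    report = AssemblyReport(
        nodes_by_role=dict(network.role_counts()),
        edges_by_class=dict(network.class_counts()),
        n_nodes=network.n_nodes,
        n_edges=network.n_edges,
        n_duplicate_rows=n_dup,
        n_self_loops=len(network.self_loops),
        inferred_roles=inferred,
    )
    return network, report


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass
class DegreeProfile:
    """Per-node degrees and O/T ratios plus subset/network aggregates.

    ``per_node`` has columns ``role, d_in, d_out, degree, ot_ratio``; the O/T
    ratio is NaN for isolated nodes, which are excluded from ``mean_ot``.
    ``network_ot`` is sum(out-degree)/sum(total degree) over the whole
    network and equals 0.5 exactly whenever at least one edge exists.
    """

    per_node: pd.DataFrame
    subset: list[str] | None
    mean_ot: float
    network_ot: float
    n_degree_zero: int


def degree_profile(network: RegulatoryNetwork, subset: Iterable[str] | None = None) -> DegreeProfile:
    """Loop-free in/out/total degrees and out-over-total (O/T) ratios."""
    succ, pred = network.adjacency()
    # degrees count distinct structural pairs, mirroring n_structural_edges
    rows = []
    for nid in network.nodes:
        d_out, d_in = len(succ[nid]), len(pred[nid])
        deg = d_in + d_out
        rows.append((nid, network.nodes[nid].role, d_in, d_out, deg,
                     (d_out / deg) if deg else np.nan))
    per_node = pd.DataFrame(rows, columns=["id", "role", "d_in", "d_out", "degree", "ot_ratio"])
    per_node = per_node.set_index("id")

    if subset is not None:
        subset = sorted(set(subset))
        unknown = [s for s in subset if s not in network.nodes]
        if unknown:
            raise KeyError(f"subset ids not in network: {unknown[:5]}")
        sel = per_node.loc[subset]
    else:
        sel = per_node

    total_deg = int(per_node["degree"].sum())
    total_out = int(per_node["d_out"].sum())
    network_ot = total_out / total_deg if total_deg else np.nan
    mean_ot = float(sel["ot_ratio"].dropna().mean()) if len(sel) else np.nan
    return DegreeProfile(per_node=per_node, subset=subset, mean_ot=mean_ot,
                         network_ot=network_ot,
                         n_degree_zero=int((sel["degree"] == 0).sum()))


def mean_connectivity(network: RegulatoryNetwork, subset: Iterable[str] | None = None,
                      halved: bool = True) -> float:
    """Mean per-node connectivity, defined as mean(total degree)/2.

    With this definition the whole-network value equals |E|/|N| exactly
    (each loop-free edge contributes one in- plus one out-degree).  Set
    ``halved=False`` for the raw mean total degree variant.
    """
    if network.n_nodes == 0:
        raise ValueError("mean connectivity of an empty network is undefined")
    prof = degree_profile(network, subset)
    sel = prof.per_node if subset is None else prof.per_node.loc[prof.subset]
    if len(sel) == 0:
        raise ValueError("subset must be nonempty")
    m = float(sel["degree"].mean())
    return m / 2 if halved else m


@dataclass
class TopologySummary:
    """Network-level topology metrics on the loop-free projection."""

    n_nodes: int
    n_edges: int
    degrees: pd.DataFrame
    clustering: dict[str, float]
    cc_a: float
    betweenness: dict[str, float]
    closeness: dict[str, float]
    path_length_hist: dict[int, int]
    n_unreachable_pairs: int
    powerlaw_exponent: float


def fit_powerlaw_exponent(degrees: Sequence[int]) -> float:
    """Least-squares slope of the log-log degree histogram (zero bins dropped).

    Returns the positive exponent gamma of P(k) ~ k^-gamma, or NaN when fewer
    than two distinct nonzero-degree bins exist.
    """
    ks = np.asarray([d for d in degrees if d > 0], dtype=int)
    if ks.size == 0:
        return float("nan")
    counts = np.bincount(ks)
    k = np.nonzero(counts)[0]
    k = k[k > 0]
    if k.size < 2:
        return float("nan")
    slope, _ = np.polyfit(np.log10(k), np.log10(counts[k]), 1)
    return float(-slope)


def topology_metrics(network: RegulatoryNetwork) -> TopologySummary:
    """Clustering, centralities, path-length histogram and power-law fit.

    Clustering coefficients use the undirected simple projection; betweenness
    and closeness are computed on the directed graph; the shortest-path-length
    histogram covers reachable ordered pairs (u != v), with unreachable pairs
    counted separately.
    """
    if network.n_nodes < 2:
        raise ValueError("topology metrics require at least 2 nodes")
    g = network.to_digraph(include_self_loops=False)
    und = nx.Graph(g)
    clustering = nx.clustering(und)
    cc_a = float(np.mean(list(clustering.values())))
    betweenness = nx.betweenness_centrality(g)
    closeness = nx.closeness_centrality(g)

    hist: Counter = Counter()
    reachable = 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for dist in lengths.values():
            if dist > 0:
                hist[dist] += 1
                reachable += 1
    n = network.n_nodes
    unreachable = n * (n - 1) - reachable

    prof = degree_profile(network)
    gamma = fit_powerlaw_exponent(prof.per_node["degree"].tolist())
    return TopologySummary(
        n_nodes=n,
        n_edges=network.n_structural_edges,
        degrees=prof.per_node,
        clustering=dict(clustering),
        cc_a=cc_a,
        betweenness=dict(betweenness),
        closeness=dict(closeness),
        path_length_hist=dict(sorted(hist.items())),
        n_unreachable_pairs=unreachable,
        powerlaw_exponent=gamma,
    )


@dataclass
class RemovalImpact:
    before: TopologySummary
    after: TopologySummary
    removed: list[str]
    deltas: dict[str, float]


def node_removal_impact(network: RegulatoryNetwork, removed: Iterable[str]) -> RemovalImpact:
    """Recompute topology on the induced subgraph after deleting ``removed``."""
    removed = sorted(set(removed))
    unknown = [r for r in removed if r not in network.nodes]
    if unknown:
        raise KeyError(f"cannot remove unknown nodes: {unknown[:5]}")
    keep = [n for n in network.nodes if n not in set(removed)]
    if not keep:
        raise ValueError("cannot remove every node")
    before = topology_metrics(network)
    after = topology_metrics(network.subgraph(keep))
    deltas = {
        "cc_a": after.cc_a - before.cc_a,
        "mean_betweenness": float(np.mean(list(after.betweenness.values())))
        - float(np.mean(list(before.betweenness.values()))),
        "mean_closeness": float(np.mean(list(after.closeness.values())))
        - float(np.mean(list(before.closeness.values()))),
        "n_nodes": after.n_nodes - before.n_nodes,
        "n_edges": after.n_edges - before.n_edges,
    }
    return RemovalImpact(before=before, after=after, removed=removed, deltas=deltas)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_edge_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    missing = [c for c in ("source", "target") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: edge table lacks columns {missing}")
    return df


def read_role_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    if "conserved" in df.columns:
        df["conserved"] = df["conserved"].str.lower().isin(("1", "true", "yes"))
    return df


def _nodes_sidecar(path: Path) -> Path:
    return path.with_name(path.stem + ".nodes.tsv")


def export_network(network: RegulatoryNetwork, path: str | Path, format: str = "tsv") -> Path:
    """Write the network as TSV (+ node side-car), SIF, or GraphML.

    TSV and GraphML round-trip losslessly through :func:`read_network_tsv` /
    :func:`read_network_graphml`; SIF is a Cytoscape-loadable edge list.
    """
    path = Path(path)
    if format == "tsv":
        edges = pd.DataFrame(
            [(e.source, e.target, e.edge_class, e.sign, e.evidence)
             for e in sorted(network.edges.values(), key=lambda e: e.key)],
            columns=EDGE_TABLE_COLUMNS,
        )
        edges.to_csv(path, sep="\t", index=False)
        nodes = pd.DataFrame(
            [(r.id, r.role, r.conserved, r.module_label or "")
             for r in sorted(network.nodes.values(), key=lambda r: r.id)],
            columns=ROLE_TABLE_COLUMNS,
        )
        nodes.to_csv(_nodes_sidecar(path), sep="\t", index=False)
    elif format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            isolated = set(network.nodes)
            for e in sorted(network.edges.values(), key=lambda e: e.key):
                fh.write(f"{e.source}\t{e.edge_class}\t{e.target}\n")
                isolated.discard(e.source)
                isolated.discard(e.target)
            for nid in sorted(isolated):
                fh.write(f"{nid}\n")
    elif format == "graphml":
        nx.write_graphml(network.to_digraph(include_self_loops=True), path,
                         encoding="utf-8")
    else:
        raise ValueError(f"unknown export format {format!r} (expected tsv, sif, or graphml)")
    return path


def read_network_tsv(edge_path: str | Path, node_path: str | Path | None = None) -> RegulatoryNetwork:
    edge_path = Path(edge_path)
    node_path = Path(node_path) if node_path else _nodes_sidecar(edge_path)
    roles = read_role_table(node_path)
    edges = read_edge_table(edge_path)
    by_class = {cls: edges[edges["edge_class"] == cls] for cls in EDGE_CLASSES}
    net, _ = assemble_network(by_class["MTI"], by_class["TMI"], by_class["TTI"], roles)
    return net


def read_network_graphml(path: str | Path) -> RegulatoryNetwork:
    g = nx.read_graphml(path)
    net = RegulatoryNetwork()
    for nid, data in g.nodes(data=True):
        net.add_node(NodeRecord(str(nid), data["role"],
                                conserved=bool(data.get("conserved", False)),
                                module_label=data.get("module_label") or None))
    for u, v, data in g.edges(data=True):
        net.add_edge(InteractionEdge(str(u), str(v), data["edge_class"],
                                     data.get("sign", "unknown"),
                                     data.get("evidence", "")), validate=False)
    return net
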