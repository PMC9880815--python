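"""3-node motif census, permutation-null enrichment, and FFL attribution.

Two three-node, three-edge subgraphs are distinguished:

* the feed-forward loop (FFL): X -> Y, Y -> Z plus the direct edge X -> Z;
* the feedback loop (FBL): the directed 3-cycle X -> Y -> Z -> X, the
  topological isomer of the FFL that differs only in the direction of the
  direct path.

FFLs are counted per role assignment (X, Y, Z are distinguishable), FBLs once
per unordered node set (a 3-cycle has three equivalent rotations).  Two census
modes are offered: ``induced`` (the Mfinder-style subgraph-type census, which
requires that no further edges exist among the three nodes) and ``match``
(pure pattern matching, extra edges tolerated).  Enrichment is assessed
against a permutation null that preserves the number of nodes and edges while
randomising connections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .network import EDGE_CLASSES, TF_ROLES, RegulatoryNetwork

POSITIONS = ("X", "Y", "Z")


@dataclass(frozen=True)
class FFLInstance:
    """One feed-forward loop: x regulates y and z, y regulates z."""

    x: str
    y: str
    z: str
    contains_mirna: bool = False
    mirna_positions: tuple[str, ...] = ()
    coherence: str | None = None

    @property
    def mirna_position(self) -> str | None:
        """The miRNA position when exactly one node is a miRNA, else None."""
        return self.mirna_positions[0] if len(self.mirna_positions) == 1 else None

    @property
    def nodes(self) -> tuple[str, str, str]:
        return (self.x, self.y, self.z)


@dataclass
class TriadCensus:
    mode: str
    n_ffl: int
    n_fbl: int
    ffl_instances: list[FFLInstance]
    fbl_cycles: list[tuple[str, str, str]]
    triad_census: dict[str, int] | None = None

    @property
    def counts(self) -> dict[str, int]:
        return {"FFL": self.n_ffl, "FBL": self.n_fbl}


def _iter_ffl(succ: Mapping[str, set], induced: bool) -> Iterator[tuple[str, str, str]]:
    for x, x_succ in succ.items():
        for y in x_succ:
            zs = succ[y] & x_succ
            for z in zs:
                if z == x:
                    continue
                if induced and (x in succ[y] or x in succ[z] or y in succ[z]):
                    continue
                yield (x, y, z)


def _iter_fbl(succ: Mapping[str, set], pred: Mapping[str, set],
              induced: bool) -> Iterator[tuple[str, str, str]]:
    # canonical rotation: first node is the smallest of the cycle
    for a, a_succ in succ.items():
        for b in a_succ:
            if b <= a:
                continue
            for c in succ[b] & pred[a]:
                if c <= a:
                    continue
                if induced and (a in succ[b] or b in succ[c] or c in a_succ):
                    continue
                yield (a, b, c)


def _count_motifs(succ: Mapping[str, set], pred: Mapping[str, set], mode: str,
                  classes: Sequence[str]) -> dict[str, int]:
    induced = mode == "induced"
    out = {}
    if "FFL" in classes:
        out["FFL"] = sum(1 for _ in _iter_ffl(succ, induced))
    if "FBL" in classes:
        out["FBL"] = sum(1 for _ in _iter_fbl(succ, pred, induced))
    return out


def annotate_instance(inst: FFLInstance, roles: Mapping[str, str]) -> FFLInstance:
    positions = tuple(p for p, n in zip(POSITIONS, inst.nodes) if roles.get(n) == "mirna")
    return replace(inst, contains_mirna=bool(positions), mirna_positions=positions)


def census_triads(network: RegulatoryNetwork, mode: str = "induced") -> TriadCensus:
    """Enumerate FFL and FBL instances (self-loops excluded).

    In ``induced`` mode a node triple counts for a class only if no edges
    beyond the defining pattern exist among the three nodes; ``match`` mode
    counts every role assignment that satisfies the edge pattern.  For
    induced mode the full 16-type triad census of the loop-free digraph is
    attached as a cross-reference (FFL = type 030T, FBL = type 030C).
    """
    if mode not in ("induced", "match"):
        raise ValueError(f"unknown census mode {mode!r}")
    succ, pred = network.adjacency()
    roles = network.roles
    instances = [annotate_instance(FFLInstance(x, y, z), roles)
                 for x, y, z in _iter_ffl(succ, mode == "induced")]
    cycles = list(_iter_fbl(succ, pred, mode == "induced"))
    triad16 = None
    if mode == "induced" and network.n_nodes >= 3:
        triad16 = dict(nx.triadic_census(network.to_digraph(include_self_loops=False)))
    return TriadCensus(mode=mode, n_ffl=len(instances), n_fbl=len(cycles),
                       ffl_instances=instances, fbl_cycles=cycles, triad_census=triad16)


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

@dataclass
class MotifEnrichment:
    """Observed count vs a permutation null for one motif class."""

    motif_class: str
    observed: int
    null_mean: float
    null_sd: float
    z_score: float
    n_permutations: int
    seed: int
    constraint: str
    mode: str
    null_counts: np.ndarray = field(repr=False, default=None)


def _decode_pairs(idx: np.ndarray, nodes: Sequence[str]) -> Iterable[tuple[str, str]]:
    n = len(nodes)
    s = idx // (n - 1)
    r = idx % (n - 1)
    t = r + (r >= s)
    return ((nodes[i], nodes[j]) for i, j in zip(s, t))


def _sample_size_only(rng: np.random.Generator, nodes: Sequence[str],
                      m: int) -> list[tuple[str, str]]:
    """A uniform simple digraph with the given node set and edge count."""
    n = len(nodes)
    space = n * (n - 1)
    if m > space:
        raise ValueError("more edges requested than ordered pairs available")
    idx = rng.choice(space, size=m, replace=False)
    return list(_decode_pairs(idx, nodes))


_CLASS_ROLE_SPACE = {
    "TMI": (TF_ROLES, frozenset({"mirna"})),
    "MTI": (frozenset({"mirna"}), frozenset({"core_tf", "tf", "mirna", "target_gene"})),
    "TTI": (TF_ROLES, frozenset({"core_tf", "tf", "target_gene"})),
}


def _sample_role_preserving(rng: np.random.Generator, network: RegulatoryNetwork
                            ) -> list[tuple[str, str]]:
    """Randomise each edge class within its role-compatible pair space."""
    by_role: dict[str, list[str]] = {}
    for nid, rec in sorted(network.nodes.items()):
        by_role.setdefault(rec.role, []).append(nid)
    class_counts = network.class_counts()
    pairs: list[tuple[str, str]] = []
    for cls in EDGE_CLASSES:
        m = class_counts.get(cls, 0)
        if m == 0:
            continue
        src_roles, tgt_roles = _CLASS_ROLE_SPACE[cls]
        src = [n for r in sorted(src_roles) for n in by_role.get(r, [])]
        tgt = [n for r in sorted(tgt_roles) for n in by_role.get(r, [])]
        chosen: set[tuple[str, str]] = set()
        n_pair = len(src) * len(tgt)
        if n_pair < m:
            raise ValueError(f"{cls}: pair space smaller than edge count")
        while len(chosen) < m:
            draw = rng.integers(0, n_pair, size=m - len(chosen))
            for k in draw:
                s, t = src[k // len(tgt)], tgt[k % len(tgt)]
                if s != t:
                    chosen.add((s, t))
        pairs.extend(sorted(chosen))
    return pairs


def permutation_zscore(
    network: RegulatoryNetwork,
    n_perm: int = 1000,
    seed: int = 0,
    constraint: str = "size_only",
    mode: str = "induced",
    classes: Sequence[str] = ("FFL", "FBL"),
) -> dict[str, MotifEnrichment]:
    """Z-score of each motif count against randomised networks.

    ``size_only`` (the default) draws simple digraphs preserving only the node
    set and edge count; ``role_preserving`` additionally keeps per-class edge
    counts inside role-compatible pair spaces; ``degree_preserving`` rewires
    by directed edge swaps.  Z = (observed - mean)/sd with the sample standard
    deviation; a degenerate null (sd = 0) yields Z = 0 when the observation
    equals the constant and signed infinity with a warning otherwise.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    if constraint not in ("size_only", "role_preserving", "degree_preserving"):
        raise ValueError(f"unknown constraint {constraint!r}")
    rng = np.random.default_rng(seed)
    succ, pred = network.adjacency()
    observed = _count_motifs(succ, pred, mode, classes)
    nodes = sorted(network.nodes)
    m = network.n_structural_edges

    null = {c: np.empty(n_perm) for c in classes}
    base = network.to_digraph(include_self_loops=False) if constraint == "degree_preserving" else None
    for p in range(n_perm):
        if constraint == "size_only":
            pairs = _sample_size_only(rng, nodes, m)
        elif constraint == "role_preserving":
            pairs = _sample_role_preserving(rng, network)
        else:
            g = base.copy()
            if m >= 2:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    try:
                        nx.directed_edge_swap(g, nswap=3 * m, max_tries=100 * m,
                                              seed=int(rng.integers(2**31 - 1)))
                    except nx.NetworkXError:
                        pass  # too few swappable edges; keep partial rewiring
            pairs = list(g.edges())
        s: dict[str, set] = {n: set() for n in nodes}
        t: dict[str, set] = {n: set() for n in nodes}
        for u, v in pairs:
            s[u].add(v)
            t[v].add(u)
        counts = _count_motifs(s, t, mode, classes)
        for c in classes:
            null[c][p] = counts[c]

    out = {}
    for c in classes:
        mean = float(null[c].mean())
        sd = float(null[c].std(ddof=1))
        obs = observed[c]
        if sd > 0:
            z = (obs - mean) / sd
        elif obs == mean:
            z = 0.0
        else:
            z = float("inf") if obs > mean else float("-inf")
            warnings.warn(f"{c}: degenerate permutation null (sd = 0), Z reported as {z}")
        out[c] = MotifEnrichment(motif_class=c, observed=obs, null_mean=mean, null_sd=sd,
                                 z_score=z, n_permutations=n_perm, seed=seed,
                                 constraint=constraint, mode=mode, null_counts=null[c])
    return out


# ---------------------------------------------------------------------------
# miRNA positioning within FFLs
# ---------------------------------------------------------------------------

@dataclass
class PositionStats:
    """How often FFLs contain a miRNA and where the miRNA sits (X/Y/Z).

    ``proportions`` are relative to miRNA-containing FFLs; ``share_of_all``
    relative to all FFL instances.  An FFL with miRNAs at several positions
    contributes to each position and is tallied in ``n_multi_position``.
    """

    n_instances: int
    n_with_mirna: int
    counts: dict[str, int]
    proportions: dict[str, float] | None
    share_of_all: dict[str, float] | None
    fraction_with_mirna: float | None
    n_multi_position: int
    conserved_only: bool


def mirna_position_stats(
    instances: Sequence[FFLInstance],
    roles: Mapping[str, str],
    conserved: Iterable[str] | None = None,
    conserved_only: bool = False,
) -> PositionStats:
    """Tally miRNA-containing FFLs by miRNA position.

    ``roles`` maps node id -> role; with ``conserved_only`` a node counts as a
    miRNA only when it also belongs to ``conserved``.
    """
    conserved = set(conserved or ())

    def is_mirna(n: str) -> bool:
        if roles.get(n) != "mirna":
            return False
        return n in conserved if conserved_only else True

    counts = {p: 0 for p in POSITIONS}
    n_with, n_multi = 0, 0
    for inst in instances:
        positions = [p for p, n in zip(POSITIONS, inst.nodes) if is_mirna(n)]
        if positions:
            n_with += 1
            if len(positions) > 1:
                n_multi += 1
            for p in positions:
                counts[p] += 1
    n = len(instances)
    return PositionStats(
        n_instances=n,
        n_with_mirna=n_with,
        counts=counts,
        proportions={p: counts[p] / n_with for p in POSITIONS} if n_with else None,
        share_of_all={p: counts[p] / n for p in POSITIONS} if n else None,
        fraction_with_mirna=n_with / n if n else None,
        n_multi_position=n_multi,
        conserved_only=conserved_only,
    )


# ---------------------------------------------------------------------------
# statistics and sign logic
# ---------------------------------------------------------------------------

def proportion_test(k1: int, n1: int, k2: int, n2: int,
                    correction: bool = False) -> tuple[float, float]:
    """Chi-square test comparing two proportions k1/n1 vs k2/n2.

    Yates continuity correction is off by default; pass ``correction=True``
    to match R's 2x2 default.  Raises on a zero margin.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or k < 0 or k > n:
            raise ValueError("need 0 <= k <= n with n > 0")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square test undefined for a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


_SIGN_VALUE = {"activating": 1, "repressing": -1}


def coherence_classify(instance: FFLInstance,
                       signs: Mapping[tuple[str, str], str] | RegulatoryNetwork) -> str:
    """Classify an FFL as coherent or incoherent from its edge signs.

    The indirect path sign is the product of sign(x->y) and sign(y->z)
    (activating = +1, repressing = -1); the loop is coherent when it matches
    the direct edge's sign, and unclassified if any sign is unknown.
    """
    if isinstance(signs, RegulatoryNetwork):
        lookup = signs.edge_sign
    else:
        lookup = lambda s, t: signs.get((s, t), "unknown")  # noqa: E731
    sxy = lookup(instance.x, instance.y)
    syz = lookup(instance.y, instance.z)
    sxz = lookup(instance.x, instance.z)
    if any(s not in _SIGN_VALUE for s in (sxy, syz, sxz)):
        return "unclassified"
    indirect = _SIGN_VALUE[sxy] * _SIGN_VALUE[syz]
    return "coherent" if indirect == _SIGN_VALUE[sxz] else "incoherent"


def classify_instances(instances: Sequence[FFLInstance],
                       network: RegulatoryNetwork) -> list[FFLInstance]:
    """Return instances with the coherence field filled from network signs."""
    return [replace(inst, coherence=coherence_classify(inst, network)) for inst in instances]
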