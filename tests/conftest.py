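"""Shared builders for small typed networks used across the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mirnet import InteractionEdge, NodeRecord, RegulatoryNetwork


def build_network(roles, edges, conserved=(), modules=None, signs=None):
    """Construct a RegulatoryNetwork from a role dict and (s, t, class) triples."""
    net = RegulatoryNetwork()
    modules = modules or {}
    signs = signs or {}
    for nid, role in roles.items():
        net.add_node(NodeRecord(nid, role, conserved=nid in conserved,
                                module_label=modules.get(nid)))
    for s, t, cls in edges:
        net.add_edge(InteractionEdge(s, t, cls, signs.get((s, t), "unknown")),
                     validate=True)
    return net


def random_typed_network(rng: np.random.Generator, n_tf=6, n_mirna=6, n_target=8,
                         p=0.15) -> RegulatoryNetwork:
    """Random role-consistent digraph: Bernoulli edges per interaction class."""
    roles = {f"T{i}": "tf" for i in range(n_tf)}
    roles.update({f"M{i}": "mirna" for i in range(n_mirna)})
    roles.update({f"G{i}": "target_gene" for i in range(n_target)})
    tfs = [f"T{i}" for i in range(n_tf)]
    mirs = [f"M{i}" for i in range(n_mirna)]
    genes = [f"G{i}" for i in range(n_target)]
    edges = []
    for cls, srcs, tgts in (("TMI", tfs, mirs), ("MTI", mirs, genes + tfs),
                            ("TTI", tfs, genes + tfs)):
        for s in srcs:
            for t in tgts:
                if s != t and rng.random() < p:
                    edges.append((s, t, cls))
    return build_network(roles, edges)


def random_digraph_network(rng: np.random.Generator, n: int, p: float) -> RegulatoryNetwork:
    """Plain random simple digraph (all nodes TFs, edges TTI)."""
    roles = {f"N{i}": "tf" for i in range(n)}
    edges = [(f"N{i}", f"N{j}", "TTI")
             for i in range(n) for j in range(n)
             if i != j and rng.random() < p]
    return build_network(roles, edges)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_ffl_network():
    """One FFL: TF X -> miRNA Y -> gene Z with the direct TTI X -> Z."""
    return build_network(
        {"X": "tf", "Y": "mirna", "Z": "target_gene"},
        [("X", "Y", "TMI"), ("Y", "Z", "MTI"), ("X", "Z", "TTI")],
    )
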