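"""Network assembly, degree/connectivity statistics, topology, and I/O."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirnet import (
    NetworkValidationError,
    assemble_network,
    degree_profile,
    export_network,
    mean_connectivity,
    node_removal_impact,
    read_network_graphml,
    read_network_tsv,
    topology_metrics,
)
from conftest import build_network, random_digraph_network, random_typed_network


def _edge_df(rows):
    return pd.DataFrame(rows, columns=["source", "target", "edge_class"])


def _roles_df(mapping):
    return pd.DataFrame({"id": list(mapping), "role": list(mapping.values())})


EMPTY = pd.DataFrame(columns=["source", "target", "edge_class"])


class TestAssembly:
    def test_empty_tables_give_empty_network(self):
        net, report = assemble_network(EMPTY, EMPTY, EMPTY, pd.DataFrame(columns=["id", "role"]))
        assert net.n_nodes == 0 and net.n_edges == 0
        assert report.nodes_by_role == {} and report.edges_by_class == {}

    def test_duplicates_and_counts_match_set_algebra(self, rng):
        """Node count = endpoint union; edge count = distinct (s,t,class) triples."""
        tfs = [f"T{i}" for i in range(8)]
        mirs = [f"M{i}" for i in range(6)]
        genes = [f"G{i}" for i in range(10)]
        rows = {"MTI": [], "TMI": [], "TTI": []}
        for _ in range(50):
            cls = rng.choice(["MTI", "TMI", "TTI"])
            if cls == "MTI":
                e = (rng.choice(mirs), rng.choice(genes), cls)
            elif cls == "TMI":
                e = (rng.choice(tfs), rng.choice(mirs), cls)
            else:
                e = (rng.choice(tfs), rng.choice(genes), cls)
            rows[cls].append(e)
            if rng.random() < 0.3:  # inject duplicates
                rows[cls].append(e)
        roles = {**{t: "tf" for t in tfs}, **{m: "mirna" for m in mirs},
                 **{g: "target_gene" for g in genes}}
        net, report = assemble_network(_edge_df(rows["MTI"]), _edge_df(rows["TMI"]),
                                       _edge_df(rows["TTI"]), _roles_df(roles))
        all_rows = rows["MTI"] + rows["TMI"] + rows["TTI"]
        expected_nodes = {s for s, _, _ in all_rows} | {t for _, t, _ in all_rows}
        assert net.n_nodes == len(expected_nodes)
        assert net.n_edges == len(set(all_rows))
        assert report.n_duplicate_rows == len(all_rows) - len(set(all_rows))

    def test_role_incompatible_edge_rejected_with_row_reference(self):
        bad = _edge_df([("T0", "G0", "MTI")])  # MTI source must be a miRNA
        with pytest.raises(NetworkValidationError, match="row 0"):
            assemble_network(bad, EMPTY, EMPTY, _roles_df({"T0": "tf", "G0": "target_gene"}))

    def test_ambiguous_unknown_endpoint_is_an_error_listing_the_id(self):
        mti = _edge_df([("M0", "mystery", "MTI")])  # MTI target role is unconstrained
        with pytest.raises(NetworkValidationError, match="mystery"):
            assemble_network(mti, EMPTY, EMPTY, _roles_df({"M0": "mirna"}))

    def test_unambiguous_roles_are_inferred(self):
        tmi = _edge_df([("T0", "M0", "TMI")])  # TMI target must be a miRNA
        net, report = assemble_network(EMPTY, tmi, EMPTY, _roles_df({"T0": "tf"}))
        assert net.nodes["M0"].role == "mirna"
        assert report.inferred_roles == {"M0": "mirna"}

    def test_reassembly_from_export_is_idempotent(self, rng, tmp_path):
        net = random_typed_network(rng)
        path = tmp_path / "net.tsv"
        export_network(net, path, format="tsv")
        assert read_network_tsv(path) == net


class TestDegreesAndConnectivity:
    def test_single_edge_ot_ratios(self):
        net = build_network({"A": "tf", "B": "target_gene"}, [("A", "B", "TTI")])
        prof = degree_profile(net)
        assert prof.per_node.loc["A", "ot_ratio"] == 1.0
        assert prof.per_node.loc["B", "ot_ratio"] == 0.0
        assert prof.network_ot == 0.5

    def test_isolated_node_excluded_from_averages(self):
        net = build_network({"A": "tf", "B": "target_gene", "C": "tf"},
                            [("A", "B", "TTI")])
        prof = degree_profile(net)
        assert math.isnan(prof.per_node.loc["C", "ot_ratio"])
        assert prof.n_degree_zero == 1
        assert prof.mean_ot == pytest.approx(0.5)  # mean of {1.0, 0.0}

    def test_degrees_match_exhaustive_edge_scan(self, rng):
        net = random_digraph_network(rng, 20, 0.2)
        prof = degree_profile(net)
        pairs = {(e.source, e.target) for e in net.edges.values()}
        for nid in net.nodes:
            assert prof.per_node.loc[nid, "d_out"] == sum(1 for s, _ in pairs if s == nid)
            assert prof.per_node.loc[nid, "d_in"] == sum(1 for _, t in pairs if t == nid)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 12), st.integers(0, 12)),
                    min_size=1, max_size=60).filter(lambda l: any(a != b for a, b in l)))
    def test_network_ot_is_exactly_half(self, pairs):
        roles = {f"N{i}": "tf" for i in range(13)}
        edges = list({(f"N{a}", f"N{b}", "TTI") for a, b in pairs})
        net = build_network(roles, edges)
        assert degree_profile(net).network_ot == 0.5

    def test_mean_connectivity_single_edge(self):
        net = build_network({"A": "tf", "B": "target_gene"}, [("A", "B", "TTI")])
        assert mean_connectivity(net) == 0.5

    def test_mean_connectivity_equals_edges_over_nodes(self, rng):
        net = random_typed_network(rng, p=0.2)
        assert mean_connectivity(net) == pytest.approx(net.n_structural_edges / net.n_nodes)
        # raw-degree variant is exactly twice the halved one
        assert mean_connectivity(net, halved=False) == pytest.approx(2 * mean_connectivity(net))

    def test_empty_network_is_an_error(self):
        from mirnet import RegulatoryNetwork

        with pytest.raises(ValueError):
            mean_connectivity(RegulatoryNetwork())


def _fw_oracle(net):
    """Floyd-Warshall distances, path counts, and centralities (brute force)."""
    nodes = sorted(net.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    inf = float("inf")
    dist = [[0 if i == j else inf for j in range(n)] for i in range(n)]
    pairs = {(e.source, e.target) for e in net.edges.values() if e.source != e.target}
    for s, t in pairs:
        dist[idx[s]][idx[t]] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    # shortest-path counts by DP over increasing distance
    sigma = [[0] * n for _ in range(n)]
    for s in range(n):
        sigma[s][s] = 1
        order = sorted((d, t) for t, d in enumerate(dist[s]) if d < inf)
        for d, t in order:
            if d == 0:
                continue
            sigma[s][t] = sum(sigma[s][idx[u]] for u, v in pairs
                              if idx[v] == t and dist[s][idx[u]] == d - 1)
    betweenness = {}
    for v in range(n):
        acc = 0.0
        for s in range(n):
            for t in range(n):
                if len({s, t, v}) < 3 or dist[s][t] == inf or sigma[s][t] == 0:
                    continue
                if dist[s][v] + dist[v][t] == dist[s][t]:
                    acc += sigma[s][v] * sigma[v][t] / sigma[s][t]
        betweenness[nodes[v]] = acc / ((n - 1) * (n - 2)) if n > 2 else 0.0
    closeness = {}
    for v in range(n):
        reach = [dist[u][v] for u in range(n) if u != v and dist[u][v] < inf]
        if reach:
            closeness[nodes[v]] = (len(reach) / sum(reach)) * (len(reach) / (n - 1))
        else:
            closeness[nodes[v]] = 0.0
    return betweenness, closeness


class TestTopology:
    def test_directed_three_cycle_is_a_triangle(self):
        net = build_network({"A": "tf", "B": "tf", "C": "tf"},
                            [("A", "B", "TTI"), ("B", "C", "TTI"), ("C", "A", "TTI")])
        summary = topology_metrics(net)
        assert all(cc == 1.0 for cc in summary.clustering.values())
        assert summary.cc_a == 1.0

    def test_out_star_has_zero_clustering_and_unit_paths(self):
        roles = {"H": "tf", **{f"L{i}": "target_gene" for i in range(5)}}
        net = build_network(roles, [("H", f"L{i}", "TTI") for i in range(5)])
        summary = topology_metrics(net)
        assert all(cc == 0.0 for cc in summary.clustering.values())
        assert summary.path_length_hist == {1: 5}

    def test_centralities_match_floyd_warshall_oracle(self, rng):
        net = random_digraph_network(rng, 15, 0.18)
        summary = topology_metrics(net)
        bet, clo = _fw_oracle(net)
        for nid in net.nodes:
            assert summary.betweenness[nid] == pytest.approx(bet[nid], abs=1e-12)
            assert summary.closeness[nid] == pytest.approx(clo[nid], abs=1e-12)

    def test_requires_two_nodes(self):
        net = build_network({"A": "tf"}, [])
        with pytest.raises(ValueError):
            topology_metrics(net)


class TestNodeRemoval:
    def test_removing_nothing_changes_nothing(self, rng):
        net = random_typed_network(rng)
        impact = node_removal_impact(net, [])
        assert all(v == pytest.approx(0, abs=1e-12) for v in impact.deltas.values())

    def test_removing_the_cut_node_of_a_path(self):
        net = build_network({"A": "tf", "B": "tf", "C": "target_gene"},
                            [("A", "B", "TTI"), ("B", "C", "TTI")])
        impact = node_removal_impact(net, ["B"])
        assert impact.before.betweenness["B"] > 0
        assert all(b == 0 for b in impact.after.betweenness.values())

    def test_matches_recomputation_on_induced_subgraph(self, rng):
        net = random_typed_network(rng, p=0.2)
        removed = sorted(net.nodes)[:3]
        impact = node_removal_impact(net, removed)
        fresh = topology_metrics(net.subgraph([n for n in net.nodes if n not in removed]))
        assert impact.after.cc_a == fresh.cc_a
        assert impact.after.betweenness == fresh.betweenness

    def test_cannot_remove_all_nodes(self, tiny_ffl_network):
        with pytest.raises(ValueError):
            node_removal_impact(tiny_ffl_network, list(tiny_ffl_network.nodes))


class TestExport:
    def test_tsv_and_graphml_round_trip(self, rng, tmp_path):
        net = random_typed_network(rng)
        for fmt, reader in (("tsv", read_network_tsv), ("graphml", read_network_graphml)):
            path = tmp_path / f"net.{fmt}"
            export_network(net, path, format=fmt)
            assert reader(path) == net

    def test_unicode_ids_survive_round_trip(self, tmp_path):
        net = build_network({"TFα": "tf", "miR-βγ": "mirna"}, [("TFα", "miR-βγ", "TMI")])
        for fmt, reader in (("tsv", read_network_tsv), ("graphml", read_network_graphml)):
            path = tmp_path / f"uni.{fmt}"
            export_network(net, path, format=fmt)
            assert reader(path) == net

    def test_empty_network_gives_header_only_tsv(self, tmp_path):
        from mirnet import RegulatoryNetwork

        path = export_network(RegulatoryNetwork(), tmp_path / "empty.tsv")
        lines = path.read_text().strip().splitlines()
        assert lines == ["source\ttarget\tedge_class\tsign\tevidence"]

    def test_sif_layout(self, tiny_ffl_network, tmp_path):
        path = export_network(tiny_ffl_network, tmp_path / "net.sif", format="sif")
        assert "X\tTMI\tY" in path.read_text()

    def test_unknown_format_rejected(self, tiny_ffl_network, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_network(tiny_ffl_network, tmp_path / "x", format="dot")
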