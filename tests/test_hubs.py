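"""Hub rules, GO partition, core extraction, layers, orientation, expression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mirnet import (
    FFLInstance,
    HubThresholds,
    assign_layers,
    census_triads,
    classify_hubs,
    count_generalization,
    expression_overlay,
    extract_core,
    go_partition,
    layer_orientation,
    mirna_target_share,
    module_connectivity,
)
from conftest import build_network, random_typed_network


class TestHubFlags:
    def test_in_hub_only(self):
        roles = {"hub": "target_gene", **{f"T{i}": "tf" for i in range(11)}}
        net = build_network(roles, [(f"T{i}", "hub", "TTI") for i in range(11)])
        rec = classify_hubs(net)["hub"]
        assert rec.is_in_hub and not rec.is_out_hub and not rec.hub_candidate

    def test_party_candidate_needs_strictly_more_than_five_out(self):
        # out-degree exactly 5 with perfect clustering is still not a candidate
        roles = {"m": "mirna", **{f"G{i}": "target_gene" for i in range(5)}, "T": "tf"}
        edges = [("m", f"G{i}", "MTI") for i in range(5)] + [("T", "m", "TMI")]
        edges += [("T", f"G{i}", "TTI") for i in range(5)]
        net = build_network(roles, edges)
        rec = classify_hubs(net)["m"]
        assert rec.d_out == 5 and rec.cc > 0 and not rec.hub_candidate

    def test_flags_equal_brute_force_threshold_evaluation(self, rng):
        import networkx as nx

        net = random_typed_network(rng, p=0.3)
        records = classify_hubs(net, HubThresholds(in_degree=3, out_degree=3, party_out=2))
        clustering = nx.clustering(nx.Graph(net.to_digraph()))
        cc_a = float(np.mean(list(clustering.values())))
        pairs = {(e.source, e.target) for e in net.edges.values() if e.source != e.target}
        for nid, rec in records.items():
            d_in = sum(1 for _, t in pairs if t == nid)
            d_out = sum(1 for s, _ in pairs if s == nid)
            assert rec.is_in_hub == (d_in > 3)
            assert rec.is_out_hub == (d_out > 3)
            assert rec.hub_candidate == (d_out > 2 and clustering[nid] > cc_a)


class TestGoPartition:
    def test_identical_annotation_is_a_party_hub(self):
        go = {f"g{i}": {"GO:1", "GO:2"} for i in range(4)}
        part = go_partition(go.keys(), go)
        assert part.hub_type == "party" and part.go_similarity == 1.0

    def test_disjoint_annotation_is_a_date_hub(self):
        go = {f"g{i}": {f"GO:{i}"} for i in range(4)}
        part = go_partition(go.keys(), go)
        assert part.hub_type == "date" and part.go_similarity == 0.0

    def test_similarity_equals_mean_pairwise_jaccard(self, rng):
        terms = [f"GO:{i}" for i in range(12)]
        go = {f"g{i}": set(rng.choice(terms, size=int(rng.integers(1, 5)), replace=False))
              for i in range(6)}
        part = go_partition(go.keys(), go)
        sims = [len(a & b) / len(a | b)
                for a, b in itertools.combinations(go.values(), 2)]
        assert part.go_similarity == pytest.approx(np.mean(sims))

    def test_order_invariance(self, rng):
        go = {f"g{i}": {f"GO:{i}", "GO:x"} for i in range(5)}
        forward = go_partition(list(go), go)
        backward = go_partition(list(reversed(list(go))), go)
        assert forward.go_similarity == backward.go_similarity

    def test_fewer_than_two_annotated_targets_unclassifiable(self):
        part = go_partition(["a", "b"], {"a": {"GO:1"}})
        assert part.hub_type is None and part.n_unannotated == 1


class TestGeneralization:
    def test_two_output_ffls_from_one_input(self):
        roles = {"X": "tf", "h": "mirna", "Z1": "target_gene", "Z2": "target_gene"}
        net = build_network(roles, [("X", "h", "TMI"), ("h", "Z1", "MTI"), ("h", "Z2", "MTI"),
                                    ("X", "Z1", "TTI"), ("X", "Z2", "TTI")])
        insts = census_triads(net, mode="match").ffl_instances
        assert count_generalization("h", insts) == (1, 2, 2)

    def test_no_upstream_regulator_means_no_output_ffls(self):
        roles = {"h": "mirna", "Z": "target_gene"}
        net = build_network(roles, [("h", "Z", "MTI")])
        insts = census_triads(net).ffl_instances
        assert count_generalization("h", insts) == (0, 0, 0)

    def test_matches_brute_force_instance_scan(self, rng):
        net = random_typed_network(rng, p=0.3)
        insts = census_triads(net, mode="match").ffl_instances
        for hub in list(net.nodes)[:10]:
            mine = [i for i in insts if i.y == hub]
            assert count_generalization(hub, insts) == (
                len({i.x for i in mine}), len({i.z for i in mine}), len(mine))


class TestCore:
    def test_no_tf_or_mirna_gives_empty_core(self):
        net = build_network({"G0": "target_gene", "G1": "target_gene"}, [])
        with pytest.warns(UserWarning):
            core, report = extract_core(net)
        assert report.n_nodes == 0

    def test_node_counts_by_role(self):
        roles = {**{f"T{i}": "tf" for i in range(249)},
                 **{f"M{i}": "mirna" for i in range(275)},
                 **{f"G{i}": "target_gene" for i in range(30)}}
        core, report = extract_core(build_network(roles, []))
        assert (report.n_tf, report.n_mirna, report.n_nodes) == (249, 275, 524)

    def test_equals_brute_force_induced_subgraph(self, rng):
        net = random_typed_network(rng, p=0.25)
        core, _ = extract_core(net)
        keep = {n for n, r in net.roles.items() if r in ("tf", "core_tf", "mirna")}
        assert set(core.nodes) == keep
        expected = {k for k, e in net.edges.items() if e.source in keep and e.target in keep}
        assert set(core.edges) == expected


class TestLayers:
    def test_out_heavy_low_cc_node_is_top_with_inclusive_threshold(self):
        roles = {"t": "core_tf", **{f"M{i}": "mirna" for i in range(10)}}
        net = build_network(roles, [("t", f"M{i}", "TMI") for i in range(10)])
        lay = assign_layers(net)
        assert lay.layers["t"] == "top"  # D_out exactly 10, "no less than 10"

    def test_high_cc_node_is_middle_regardless_of_degrees(self):
        roles = {"a": "tf", "b": "tf", "m": "mirna"}
        net = build_network(roles, [("a", "b", "TTI"), ("a", "m", "TMI"), ("b", "m", "TMI")])
        lay = assign_layers(net, cc_a=0.5)
        assert lay.layers["m"] == "middle"  # CC = 1 > supplied CC_a

    def test_partition_is_exhaustive_and_matches_rule_evaluation(self, rng):
        import networkx as nx

        net = random_typed_network(rng, n_tf=20, n_mirna=20, n_target=0, p=0.15)
        lay = assign_layers(net, degree_threshold=3)
        assert set(lay.layers) == set(net.nodes)
        clustering = nx.clustering(nx.Graph(net.to_digraph()))
        cc_a = float(np.mean(list(clustering.values())))
        pairs = {(e.source, e.target) for e in net.edges.values() if e.source != e.target}
        for nid, layer in lay.layers.items():
            d_in = sum(1 for _, t in pairs if t == nid)
            d_out = sum(1 for s, _ in pairs if s == nid)
            if clustering[nid] > cc_a:
                expected = "middle"
            elif d_out >= 3 and d_in < 3:
                expected = "top"
            else:
                expected = "bottom"
            assert layer == expected

    def test_cc_tie_goes_to_the_degree_rules(self):
        # regular digraph where every CC equals CC_a: nobody is middle
        roles = {f"N{i}": "tf" for i in range(4)}
        edges = [(f"N{i}", f"N{(i + 1) % 4}", "TTI") for i in range(4)]
        lay = assign_layers(build_network(roles, edges))
        assert all(v != "middle" for v in lay.layers.values())


class TestOrientation:
    def test_all_top_to_bottom_gives_fraction_one(self):
        insts = [FFLInstance(f"x{i}", "y", f"z{i}") for i in range(5)]
        layers = {**{f"x{i}": "top" for i in range(5)}, "y": "middle",
                  **{f"z{i}": "bottom" for i in range(5)}}
        rep = layer_orientation(insts, layers)
        assert rep.fraction_higher == 1.0 and rep.n_equal == 0

    def test_same_layer_everywhere_gives_zero_fraction(self):
        insts = [FFLInstance("a", "b", "c")]
        rep = layer_orientation(insts, {"a": "bottom", "b": "bottom", "c": "bottom"})
        assert rep.fraction_higher == 0.0 and rep.n_equal == 1

    def test_unassigned_nodes_are_skipped_and_counted(self):
        insts = [FFLInstance("a", "b", "q"), FFLInstance("a", "b", "c")]
        rep = layer_orientation(insts, {"a": "top", "b": "middle", "c": "bottom"})
        assert rep.n_skipped == 1 and rep.n_higher == 1

    def test_tallies_match_per_instance_comparison(self, rng):
        rank = {"top": 2, "middle": 1, "bottom": 0}
        names = [f"n{i}" for i in range(30)]
        layers = {n: ["top", "middle", "bottom"][int(rng.integers(3))] for n in names}
        insts = []
        for _ in range(100):
            x, y, z = rng.choice(names, size=3, replace=False)
            mir = rng.random() < 0.4
            insts.append(FFLInstance(x, y, z, contains_mirna=mir,
                                     mirna_positions=("Y",) if mir else ()))
        rep = layer_orientation(insts, layers)
        hi = sum(1 for i in insts if rank[layers[i.x]] > rank[layers[i.z]])
        eq = sum(1 for i in insts if rank[layers[i.x]] == rank[layers[i.z]])
        assert (rep.n_higher, rep.n_equal, rep.n_lower) == (hi, eq, 100 - hi - eq)
        sub = [i for i in insts if i.contains_mirna]
        shi = sum(1 for i in sub if rank[layers[i.x]] > rank[layers[i.z]])
        assert rep.mirna_subset.n_higher == shi


class TestModulesAndTargets:
    def test_in_edges_from_three_modules(self):
        roles = {"m": "mirna", "A": "tf", "B": "tf", "C": "tf"}
        net = build_network(roles, [(t, "m", "TMI") for t in "ABC"])
        mc = module_connectivity(net, {"A": "light", "B": "aba", "C": "floral"}, "m")
        assert mc.modules == {"light", "aba", "floral"} and mc.n_modules == 3

    def test_mti_reaches_modules_through_target_regulators(self):
        roles = {"m": "mirna", "A": "tf", "G": "target_gene"}
        net = build_network(roles, [("m", "G", "MTI"), ("A", "G", "TTI")])
        mc = module_connectivity(net, {"A": "trichome"}, "m")
        assert mc.modules == {"trichome"}

    def test_isolated_node_touches_nothing(self):
        net = build_network({"m": "mirna", "A": "tf"}, [])
        assert module_connectivity(net, {"A": "light"}, "m").modules == set()

    def test_unlabeled_neighbors_ignored_but_counted(self):
        roles = {"m": "mirna", "A": "tf", "B": "tf"}
        net = build_network(roles, [("A", "m", "TMI"), ("B", "m", "TMI")])
        mc = module_connectivity(net, {"A": "light"}, "m")
        assert mc.modules == {"light"} and mc.n_unlabeled_neighbors == 1

    def test_mirna_target_share_counts_mti_in_edges(self):
        roles = {"m": "mirna", "T1": "tf", "T2": "tf"}
        net = build_network(roles, [("m", "T1", "MTI")])
        assert mirna_target_share(net, ["T1", "T2"]) == 0.5


class TestExpressionOverlay:
    @staticmethod
    def _table(rng, n1=40, n2=40, shift=0.0):
        rows = []
        for i in range(n1):
            rows.append((f"a{i}", "c1", rng.normal(shift, 1.0)))
        for i in range(n2):
            rows.append((f"b{i}", "c1", rng.normal(0.0, 1.0)))
        return pd.DataFrame(rows, columns=["gene", "condition", "rel_level"])

    def test_identical_distributions_are_not_called(self, rng):
        expr = self._table(rng)
        ov = expression_overlay({"g1": [f"a{i}" for i in range(40)],
                                 "g2": [f"b{i}" for i in range(40)]}, expr)
        assert ov.tests.loc[0, "pvalue"] > 0.05

    def test_statistic_equals_brute_force_rank_computation(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=5)
        rows = [(f"a{i}", "c", v) for i, v in enumerate(x)]
        rows += [(f"b{i}", "c", v) for i, v in enumerate(y)]
        expr = pd.DataFrame(rows, columns=["gene", "condition", "rel_level"])
        ov = expression_overlay({"g1": [f"a{i}" for i in range(6)],
                                 "g2": [f"b{i}" for i in range(5)]}, expr)
        u_brute = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
        assert ov.tests.loc[0, "statistic"] == pytest.approx(u_brute)
        assert ov.tests.loc[0, "pvalue"] == pytest.approx(
            sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)

    def test_small_groups_summarised_but_not_tested(self, rng):
        expr = self._table(rng, n1=2, n2=10)
        ov = expression_overlay({"small": ["a0", "a1"],
                                 "big": [f"b{i}" for i in range(10)]}, expr)
        assert ov.tests.empty and "small" in ov.skipped_groups

    def test_overlapping_groups_rejected(self, rng):
        expr = self._table(rng)
        with pytest.raises(ValueError):
            expression_overlay({"g1": ["a0"], "g2": ["a0", "b0", "b1"]}, expr)
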