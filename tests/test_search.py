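import itertools

import networkx as nx
import numpy as np
import pytest

from btsnet import (
    BISPARSE,
    COHESIVE,
    InteractionNetwork,
    Module,
    Thresholds,
    bts_search,
    build_bridges,
    default_thresholds,
    edn,
    error_e,
    fit_image_graph,
    grow_bisparse,
    grow_cohesive,
    refine_cohesive,
    regulate_bisparse,
    threshold_sweep,
)

from conftest import random_network


def clique_plus_sparse() -> InteractionNetwork:
    """A 6-clique c0..c5 embedded in a sparse 6-node background."""
    edges = [(f"c{i}", f"c{j}") for i in range(6) for j in range(i + 1, 6)]
    edges += [("c0", "s0"), ("s0", "s1"), ("s2", "s3"), ("s4", "s5")]
    return InteractionNetwork.from_edges(edges)


class TestThresholds:
    def test_ordering_invariant(self):
        with pytest.raises(ValueError, match="a1 > a3 > a2"):
            Thresholds(a1=0.1, a2=0.05, a3=0.2)
        with pytest.raises(ValueError, match="a1"):
            Thresholds(a1=1.0, a2=0.01, a3=0.1)
        with pytest.raises(ValueError, match="a2"):
            Thresholds(a1=0.5, a2=0.0, a3=0.1)

    @pytest.mark.parametrize(
        "density, expected",
        [(0.02, (0.2, 0.002, 0.02)), (0.1, (0.5, 0.01, 0.1))],
    )
    def test_default_rule(self, density, expected):
        rng = np.random.default_rng(0)
        n = 200
        # build a graph with exactly the requested density
        total = n * (n - 1) // 2
        want = int(round(density * total))
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        chosen = rng.choice(len(pairs), size=want, replace=False)
        net = InteractionNetwork.from_edges(
            ((f"v{pairs[c][0]:03d}", f"v{pairs[c][1]:03d}") for c in chosen),
            extra_nodes=(f"v{i:03d}" for i in range(n)),
        )
        th = default_thresholds(net)
        assert (th.a1, th.a2, th.a3) == pytest.approx(expected, rel=1e-6)
        assert th.a1 > th.a3 > th.a2

    def test_edgeless_needs_manual_thresholds(self):
        net = InteractionNetwork(["a", "b", "c"], np.zeros((3, 3), dtype=int))
        with pytest.raises(ValueError, match="edgeless"):
            default_thresholds(net)

    @pytest.mark.parametrize("seed", range(5))
    def test_defaults_always_ordered(self, seed):
        net = random_network(30, 0.1 + 0.15 * seed, seed=seed)
        th = default_thresholds(net)
        assert th.a1 > th.a3 > th.a2
        assert th.a1 < 1 and th.a2 > 0


class TestGrowth:
    def test_cohesive_growth_recovers_embedded_clique(self):
        net = clique_plus_sparse()
        mod = grow_cohesive(net, net.node_labels, "c3", a1=0.5)
        assert mod.members == {f"c{i}" for i in range(6)}
        assert mod.mtype == COHESIVE

    def test_isolated_seed_becomes_bisparse_singleton(self):
        net = InteractionNetwork.from_edges([("a", "b")], extra_nodes=["z"])
        mod = grow_cohesive(net, net.node_labels, "z", a1=0.5)
        assert mod.members == {"z"}
        assert mod.mtype == BISPARSE

    def test_complete_graph_fully_absorbed(self):
        net = random_network(7, 1.1, seed=0)
        mod = grow_cohesive(net, net.node_labels, net.node_labels[0], a1=0.5)
        assert mod.members == set(net.node_labels)

    def test_near_one_threshold_admits_only_cliques(self):
        # K6 minus one edge: at a1 = 0.99 the two non-adjacent nodes
        # can never both be members
        g = nx.complete_graph(6)
        g.remove_edge(0, 1)
        net = InteractionNetwork.from_networkx(
            nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes()})
        )
        mod = grow_cohesive(net, net.node_labels, "v2", a1=0.99)
        assert not {"v0", "v1"} <= mod.members
        sub_edm = 1.0  # whatever remains must be a clique
        from btsnet import edm as edm_fn

        assert edm_fn(net, mod.members) == sub_edm

    def test_bisparse_absorbs_edgeless_set(self):
        net = InteractionNetwork.from_edges(
            [("hub", f"p{i:02d}") for i in range(17)]
        )
        mod = grow_bisparse(net, [f"p{i:02d}" for i in range(17)], "p00", a2=0.05)
        assert mod.members == {f"p{i:02d}" for i in range(17)}
        assert mod.edm == 0.0
        assert mod.mtype == BISPARSE

    def test_bisparse_seed_in_clique_stays_singleton(self, two_cliques):
        mod = grow_bisparse(two_cliques, [f"a{i:02d}" for i in range(6)], "a00",
                            a2=0.01)
        assert mod.members == {"a00"}

    def test_bisparse_absorbs_one_side_of_bipartite_pair(self, bipartite_k88):
        mod = grow_bisparse(bipartite_k88, bipartite_k88.node_labels, "l0", a2=0.05)
        assert mod.members == {f"l{i}" for i in range(8)}

    def test_tiny_a2_only_builds_zero_density_modules(self):
        net = random_network(20, 0.3, seed=4)
        for seed_node in net.node_labels[:5]:
            mod = grow_bisparse(net, net.node_labels, seed_node, a2=1e-9)
            assert mod.edm == 0.0

    def test_seed_outside_residual_is_an_error(self, path4):
        with pytest.raises(ValueError, match="residual"):
            grow_cohesive(path4, ["a", "b"], "d", a1=0.5)


class TestBridgesAndRefinement:
    def test_bridge_between_bipartite_sides(self, bipartite_k88):
        left = Module(0, frozenset(f"l{i}" for i in range(8)), BISPARSE, 0.0)
        right = Module(1, frozenset(f"r{i}" for i in range(8)), BISPARSE, 0.0)
        bridges = build_bridges(bipartite_k88, left, [right], a3=0.1)
        assert len(bridges) == 1
        assert bridges[0].edbm == 1.0

    def test_no_bridge_between_disconnected_cliques(self, two_cliques):
        a = Module(0, frozenset(f"a{i:02d}" for i in range(6)), COHESIVE, 1.0)
        b = Module(1, frozenset(f"b{i:02d}" for i in range(6)), COHESIVE, 1.0)
        assert build_bridges(two_cliques, a, [b], a3=0.1) == []

    def test_bridge_at_threshold_recorded(self):
        edges = [("x0", "y0"), ("x0", "y1"), ("x1", "y2"), ("y0", "y3")]
        net = InteractionNetwork.from_edges(edges + [("y3", "y4")])
        x = Module(0, frozenset(["x0", "x1"]), COHESIVE, 1.0)
        y = Module(1, frozenset(f"y{j}" for j in range(5)), BISPARSE, 0.2)
        bridges = build_bridges(net, x, [y], a3=0.25)
        assert len(bridges) == 1
        assert bridges[0].edbm == pytest.approx(0.3)

    def test_refine_expels_pendant(self):
        edges = [(f"c{i}", f"c{j}") for i in range(5) for j in range(i + 1, 5)]
        edges.append(("c0", "pendant"))
        net = InteractionNetwork.from_edges(edges)
        mod = Module(0, frozenset(net.node_labels), COHESIVE, 0.0)
        refined, expelled = refine_cohesive(net, mod, a1=0.5)
        assert expelled == {"pendant"}
        assert refined.members == {f"c{i}" for i in range(5)}

    def test_refine_keeps_pure_clique(self, two_cliques):
        mod = Module(0, frozenset(f"a{i:02d}" for i in range(6)), COHESIVE, 1.0)
        refined, expelled = refine_cohesive(two_cliques, mod, a1=0.5)
        assert expelled == frozenset()
        assert refined.members == mod.members

    def test_refine_dissolves_sparse_module(self, path4):
        mod = Module(0, frozenset(["a", "c"]), COHESIVE, 0.0)
        refined, expelled = refine_cohesive(path4, mod, a1=0.5)
        assert refined is None
        assert expelled == {"a", "c"}

    def test_regulate_expels_stray_member(self, bipartite_k88):
        net = InteractionNetwork.from_edges(
            list(bipartite_k88.edge_set()) + [("stray", "l0")]
        )
        left = Module(0, frozenset([f"l{i}" for i in range(8)] + ["stray"]),
                      BISPARSE, 0.0)
        right = Module(1, frozenset(f"r{i}" for i in range(8)), BISPARSE, 0.0)
        regulated, expelled = regulate_bisparse(net, left, [right], a3=0.2)
        assert expelled == {"stray"}
        assert regulated.members == {f"l{i}" for i in range(8)}

    def test_regulate_keeps_fully_bridged_module(self, bipartite_k88):
        left = Module(0, frozenset(f"l{i}" for i in range(8)), BISPARSE, 0.0)
        right = Module(1, frozenset(f"r{i}" for i in range(8)), BISPARSE, 0.0)
        regulated, expelled = regulate_bisparse(bipartite_k88, left, [right], a3=0.2)
        assert expelled == frozenset()
        assert regulated.members == left.members

    def test_regulate_without_partners_is_vacuous(self, bipartite_k88):
        left = Module(0, frozenset(f"l{i}" for i in range(8)), BISPARSE, 0.0)
        regulated, expelled = regulate_bisparse(bipartite_k88, left, [], a3=0.2)
        assert expelled == frozenset()
        assert regulated.members == left.members


class TestBtsSearch:
    def test_two_disjoint_cliques(self, two_cliques):
        part = bts_search(two_cliques, Thresholds(a1=0.5, a2=0.01, a3=0.1))
        assert part.n_modules == 2
        assert all(m.mtype == COHESIVE for m in part.modules)
        assert part.modularity == pytest.approx(0.5)
        member_sets = {m.members for m in part.modules}
        assert member_sets == {
            frozenset(f"a{i:02d}" for i in range(6)),
            frozenset(f"b{i:02d}" for i in range(6)),
        }

    def test_edgeless_network_single_bisparse_module(self):
        net = InteractionNetwork([f"x{i}" for i in range(10)],
                                 np.zeros((10, 10), dtype=int))
        part = bts_search(net, Thresholds(a1=0.5, a2=0.01, a3=0.1))
        assert part.n_modules == 1
        assert part.modules[0].mtype == BISPARSE
        assert part.error == 0.0

    def test_invalid_thresholds_cite_rule(self, two_cliques):
        bad = object.__new__(Thresholds)  # bypass dataclass validation
        for name, value in (("a1", 0.1), ("a2", 0.05), ("a3", 0.2)):
            object.__setattr__(bad, name, value)
        with pytest.raises(ValueError, match="a1 > a3 > a2"):
            bts_search(two_cliques, bad)

    def test_partition_covers_every_node_exactly_once(self):
        for seed in range(5):
            net = random_network(25, 0.25, seed=seed)
            part = bts_search(net)
            assignment = part.assignment()
            assert set(assignment) == set(net.node_labels)
            sizes = sum(len(m.members) for m in part.modules)
            assert sizes == net.n_nodes

    def test_determinism_under_fixed_seed(self):
        net = random_network(30, 0.2, seed=9)
        p1 = bts_search(net, rng_seed=123)
        p2 = bts_search(net, rng_seed=123)
        assert [m.members for m in p1.modules] == [m.members for m in p2.modules]
        assert p1.error == p2.error

    def test_cohesive_priority_over_bisparse(self):
        """Clique members never end up in bi-sparse modules of the winner."""
        net = clique_plus_sparse()
        part = bts_search(net, Thresholds(a1=0.5, a2=0.05, a3=0.12))
        clique = {f"c{i}" for i in range(6)}
        for mod in part.modules:
            if mod.members & clique:
                overlap = mod.members & clique
                if mod.mtype == BISPARSE:
                    # a node qualifying for cohesive growth must not sit
                    # in a bi-sparse module
                    assert not overlap
        cohesive_members = set().union(
            *(m.members for m in part.modules if m.mtype == COHESIVE)
        )
        assert clique <= cohesive_members

    def test_permutation_equivariance(self, two_cliques):
        part = bts_search(two_cliques, Thresholds(a1=0.5, a2=0.01, a3=0.1))
        mapping = {v: f"z{ord(v[0])}{v[1:]}" for v in two_cliques.node_labels}
        relabeled = InteractionNetwork.from_edges(
            (mapping[u], mapping[v]) for u, v in two_cliques.edge_set()
        )
        part2 = bts_search(relabeled, Thresholds(a1=0.5, a2=0.01, a3=0.1))
        mapped = {frozenset(mapping[v] for v in m.members) for m in part.modules}
        assert mapped == {m.members for m in part2.modules}

    def test_matches_exhaustive_min_e_two_partition(self):
        """On two noisy cliques the search finds the brute-force best split."""
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        g.add_edge(0, 7)  # one noise edge across
        net = InteractionNetwork.from_networkx(
            nx.relabel_nodes(g, {i: f"v{i:02d}" for i in g.nodes()})
        )
        labels = net.node_labels
        best = None
        for bits in itertools.product((0, 1), repeat=len(labels) - 1):
            assignment = {labels[0]: 0}
            assignment.update(dict(zip(labels[1:], bits)))
            if len(set(assignment.values())) < 2:
                continue
            image = fit_image_graph(net, assignment)
            e = error_e(net, assignment, image)
            if best is None or e < best[0]:
                best = (e, assignment)
        part = bts_search(net, Thresholds(a1=0.5, a2=0.01, a3=0.2))
        found = {m.members for m in part.modules}
        expected = {
            frozenset(v for v in labels if best[1][v] == c) for c in (0, 1)
        }
        assert found == expected


class TestThresholdSweep:
    def test_grid_shape_and_determinism(self, two_cliques):
        a3 = edn(two_cliques)  # 30/66 ~ 0.4545
        grid1 = [0.6, 0.8]
        grid2 = [a3 / 10, a3 / 5]
        t1 = threshold_sweep(two_cliques, grid1, grid2, rng_seed=7)
        t2 = threshold_sweep(two_cliques, grid1, grid2, rng_seed=7)
        assert len(t1) == 4
        assert t1.equals(t2)

    def test_invalid_grid_points_skipped(self, two_cliques, caplog):
        a3 = edn(two_cliques)
        with caplog.at_level("WARNING"):
            table = threshold_sweep(two_cliques, [0.5, a3 / 2], [a3 / 10])
        assert len(table) == 1
        assert "skipping" in caplog.text
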