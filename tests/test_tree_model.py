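"""Tree structures, Newick I/O, statistics, suppression, generation."""

import pytest
from hypothesis import given, settings, strategies as st

import rfbound as rb
from rfbound.tree_model import shape_stats


class TestReadNewick:
    def test_quartet_with_toplevel_bifurcation_keeps_degree2_node(self):
        # the top-level binary clause becomes an ordinary degree-2 node,
        # kept and reported in k; the split content (m - k = 1) is that of
        # a plain quartet
        t = rb.read_newick("((A,B),(C,D));", "unrooted")
        s = shape_stats(t.topology)
        assert (s.n, s.m - s.k) == (4, 1)
        assert s.k == 1 and not s.proper
        assert len(rb.bipartitions(t)) == 1

    def test_star_parses_with_no_internal_edge(self):
        t = rb.read_newick("(A,B,C);", "unrooted")
        s = shape_stats(t.topology)
        assert (s.n, s.m, s.k, s.proper) == (3, 0, 0, True)

    def test_single_child_clause_becomes_degree2_node(self):
        t = rb.read_newick("((A)X,B,C);", "unrooted")
        assert shape_stats(t.topology).k == 1

    def test_labels_assigned_lexicographically(self):
        t = rb.read_newick("(c,a,b);", "unrooted")
        assert t.taxon_map == {1: "a", 2: "b", 3: "c"}

    @pytest.mark.parametrize(
        "text,mode",
        [
            ("((A,B),(C,D)", "unrooted"),  # unbalanced
            ("(A,A,B);", "unrooted"),  # duplicate names
            ("(A,B);", "unrooted"),  # < 3 leaves
            ("((A,B,C));", "rooted"),  # rooted: top-level degree 1
        ],
    )
    def test_rejects_malformed_input(self, text, mode):
        with pytest.raises(rb.NewickParseError):
            rb.read_newick(text, mode)

    def test_rooted_mode_sets_root(self):
        t = rb.read_newick("((A,B),C);", "rooted")
        assert t.topology.rooted
        assert t.topology.degree(t.topology.root) == 2


class TestWriteNewick:
    @pytest.mark.parametrize(
        "text,mode",
        [
            ("((A,B),(C,D));", "unrooted"),
            ("(A,B,C);", "unrooted"),
            ("((A)X,B,C);", "unrooted"),
            ("((A,B),C);", "rooted"),
            ("(((A,B),C),(D,E));", "rooted"),
        ],
    )
    def test_round_trip_preserves_shape_and_splits(self, text, mode):
        t = rb.read_newick(text, mode)
        t2 = rb.read_newick(rb.write_newick(t), mode)
        assert rb.canonical_form(t.topology) == rb.canonical_form(t2.topology)
        assert shape_stats(t.topology) == shape_stats(t2.topology)
        if mode == "rooted":
            assert rb.clusters(t) == rb.clusters(t2)
        else:
            assert rb.bipartitions(t) == rb.bipartitions(t2)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_round_trip_random_trees(self, seed):
        import random

        rng = random.Random(seed)
        n = rng.randint(3, 16)
        rooted = rng.random() < 0.5
        topo = rb.random_topology(
            n, rooted=rooted, resolution=rng.choice([0.4, 0.8, 1.0]),
            k=rng.randint(0, 2), seed=seed,
        )
        t = rb.label_canonically(topo)
        t2 = rb.read_newick(
            rb.write_newick(t), "rooted" if rooted else "unrooted"
        )
        assert rb.canonical_form(t.topology) == rb.canonical_form(t2.topology)
        if rooted:
            assert rb.clusters(t) == rb.clusters(t2)
        else:
            assert rb.bipartitions(t) == rb.bipartitions(t2)


class TestShapeStats:
    def test_fully_resolved_unrooted_has_n_minus_3_internal_edges(self):
        t = rb.read_newick("(((A,B),C),D,(E,F));", "unrooted")
        assert shape_stats(t.topology).m == 3

    def test_quartet_with_subdivided_internal_edge(self):
        topo = rb.read_newick("((1,2),(3,4));", "unrooted").topology
        topo, _ = rb.suppress_degree_two(topo)
        (e,) = [ie for ie in topo.internal_edges()]
        topo.subdivide_edge(*e)
        s = shape_stats(topo)
        assert (s.n, s.m, s.k, s.proper) == (4, 2, 1, False)

    def test_tree_invariant_edges_nodes(self):
        for seed in range(20):
            t = rb.random_topology(8, resolution=0.5, k=2, seed=seed)
            n_edges = sum(len(a) for a in t.adj.values()) // 2
            assert n_edges == len(t.adj) - 1
            t.validate()


class TestSuppressDegreeTwo:
    def test_identity_on_proper_tree(self, quartet_12_34):
        topo, _ = rb.suppress_degree_two(quartet_12_34.topology)
        t2, _ = rb.suppress_degree_two(topo)
        assert rb.canonical_form(topo) == rb.canonical_form(t2)

    def test_chain_of_three_collapses_to_one_edge(self):
        topo = rb.read_newick("((1,2),(3,4));", "unrooted").topology
        topo, _ = rb.suppress_degree_two(topo)
        (e,) = topo.internal_edges()
        w = topo.subdivide_edge(*e)
        w2 = topo.subdivide_edge(e[0], w)
        topo.subdivide_edge(w, w2)
        assert shape_stats(topo).k == 3
        out, corr = rb.suppress_degree_two(topo)
        s = shape_stats(out)
        assert (s.n, s.m, s.k) == (4, 1, 0)
        assert set(corr) == set(out.adj)

    def test_m_drops_by_k_and_splits_invariant(self):
        for seed in range(30):
            t = rb.label_canonically(
                rb.random_topology(7, resolution=0.6, k=3, seed=seed)
            )
            s_before = shape_stats(t.topology)
            out, _ = rb.suppress_degree_two(t)
            s_after = shape_stats(out.topology)
            assert s_after.k == 0
            assert s_after.m == s_before.m - s_before.k
            assert rb.bipartitions(out) == rb.bipartitions(t)

    def test_rooted_degree2_root_is_kept(self):
        t = rb.read_newick("((A,B),(C,D));", "rooted")
        out, _ = rb.suppress_degree_two(t)
        assert out.topology.root == t.topology.root
        assert out.topology.degree(out.topology.root) == 2
        assert rb.clusters(out) == rb.clusters(t)


class TestRootOnEdge:
    def test_quartet_rooted_on_internal_edge(self, quartet_12_34):
        t, _ = rb.suppress_degree_two(quartet_12_34)
        (e,) = t.topology.internal_edges()
        rt = rb.root_on_edge(t, e)
        assert rb.clusters(rt) == {frozenset({1, 2}), frozenset({3, 4})}

    def test_star_rooted_on_leaf_edge(self, star3):
        leaf1 = star3.leaf_with_label(1)
        (center,) = star3.topology.adj[leaf1]
        rt = rb.root_on_edge(star3, rb.tree_model.edge_key(leaf1, center))
        assert rb.clusters(rt) == {frozenset({2, 3})}

    def test_adds_one_node_and_one_edge(self, quartet_12_34):
        t = quartet_12_34
        before_nodes = len(t.topology.adj)
        before_edges = len(t.topology.edges())
        rt = rb.root_on_edge(t, t.topology.edges()[0])
        assert len(rt.topology.adj) == before_nodes + 1
        assert len(rt.topology.edges()) == before_edges + 1

    def test_rooting_internal_edge_of_proper_tree_adds_internal_edge(self):
        for seed in range(10):
            topo = rb.random_topology(7, seed=seed)
            t = rb.label_canonically(topo)
            m = shape_stats(topo).m
            for e in topo.internal_edges():
                rt = rb.root_on_edge(t, e)
                assert shape_stats(rt.topology).m == m + 1

    def test_missing_edge_rejected(self, quartet_12_34):
        with pytest.raises(rb.TreeStructureError):
            rb.root_on_edge(quartet_12_34, (998, 999))


class TestRandomTopology:
    def test_fully_resolved_counts(self):
        for n, rooted, m_expected in [(5, False, 2), (5, True, 3), (8, False, 5)]:
            t = rb.random_topology(n, rooted=rooted, seed=7)
            assert shape_stats(t).m == m_expected

    def test_n3_unrooted_is_the_star(self):
        t = rb.random_topology(3, resolution=0.3, seed=1)
        assert shape_stats(t).m == 0

    def test_deterministic_given_seed(self):
        a = rb.random_topology(12, resolution=0.5, k=2, seed=99)
        b = rb.random_topology(12, resolution=0.5, k=2, seed=99)
        assert rb.canonical_form(a) == rb.canonical_form(b)
        assert rb.canonical_form(a) != rb.canonical_form(
            rb.random_topology(12, resolution=0.5, k=2, seed=100)
        )

    def test_requested_k_is_delivered(self):
        for k in (0, 1, 3):
            t = rb.random_topology(9, k=k, seed=3)
            assert shape_stats(t).k == k

    def test_infeasible_inputs_rejected(self):
        with pytest.raises(rb.TreeStructureError):
            rb.random_topology(2, seed=0)
        with pytest.raises(ValueError):
            rb.random_topology(5, resolution=1.5, seed=0)


def _nx_proper_unrooted_count(n):
    """Independent enumeration oracle: filter networkx's nonisomorphic trees."""
    import networkx as nx

    count = 0
    for order in range(n + 1, 2 * n - 1):
        for g in nx.nonisomorphic_trees(order):
            degs = dict(g.degree())
            leaves = sum(1 for d in degs.values() if d == 1)
            if leaves == n and all(d >= 3 for d in degs.values() if d != 1):
                count += 1
    return count


def _nx_proper_rooted_count(n):
    import networkx as nx

    seen = set()
    for order in range(n + 1, 2 * n):
        for g in nx.nonisomorphic_trees(order):
            degs = dict(g.degree())
            leaves = {v for v, d in degs.items() if d == 1}
            if len(leaves) != n:
                continue
            for root in g:
                if root in leaves or degs[root] < 2:
                    continue
                if all(
                    degs[v] >= 3 for v in g if v not in leaves and v != root
                ):
                    t = rb.TopologicalTree(
                        adj={v: set(g[v]) for v in g}, rooted=True, root=root
                    )
                    seen.add(rb.canonical_form(t))
    return len(seen)


class TestEnumerateTopologies:
    @pytest.mark.parametrize("n,expected", [(3, 1), (4, 2)])
    def test_small_unrooted_counts(self, n, expected):
        assert len(rb.enumerate_topologies(n, rooted=False)) == expected

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_unrooted_counts_match_independent_oracle(self, n):
        got = len(rb.enumerate_topologies(n, rooted=False))
        assert got == _nx_proper_unrooted_count(n)

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_rooted_counts_match_independent_oracle(self, n):
        got = len(rb.enumerate_topologies(n, rooted=True))
        assert got == _nx_proper_rooted_count(n)

    def test_representatives_are_pairwise_nonisomorphic_and_valid(self):
        shapes = rb.enumerate_topologies(6, rooted=False)
        keys = {rb.canonical_form(t) for t in shapes}
        assert len(keys) == len(shapes)
        for t in shapes:
            t.validate()
            assert shape_stats(t).proper
            assert shape_stats(t).m <= 6 - 3

    def test_improper_variants_include_degree2_shapes(self):
        shapes = rb.enumerate_topologies(
            4, rooted=False, proper_only=False, max_unifurcations=2
        )
        ks = {shape_stats(t).k for t in shapes}
        assert ks == {0, 1, 2}

    def test_cap_enforced(self):
        with pytest.raises(rb.CapExceededError):
            rb.enumerate_topologies(8, rooted=False)
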