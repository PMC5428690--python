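"""Construction pipeline: contraction, refinement, projection, ModTop."""

import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp

from supernet import (
    ConsistencyError,
    ConstraintSet,
    Graph,
    InputError,
    NodeAssignment,
    Partition,
    build_supernodes,
    construct_supernetwork,
    init_super_adjacency,
    lift_constraints,
    modtop,
    project_labels,
    refine_with_cannot_links,
    resolve_inconsistency,
)

from conftest import IDX, random_graph


# ---------------------------------------------------------------------------
# inconsistency resolution: cannot-link wins, whole component demoted
# ---------------------------------------------------------------------------


class TestResolveInconsistency:
    def test_contradicted_component_fully_demoted(self):
        # must-links f-d and f-7 chained against a cannot-link 7-d:
        # both must-links drop to normal links, the cannot-link stays
        f, d, seven = 0, 1, 2
        cs = ConstraintSet(frozenset({(f, d), (f, seven)}), frozenset({(seven, d)}))
        resolved, demoted = resolve_inconsistency(cs)
        assert resolved.must_links == frozenset()
        assert resolved.cannot_links == frozenset({(d, seven)})
        assert sorted(demoted) == [(0, 1), (0, 2)]

    def test_empty_input_unchanged(self):
        resolved, demoted = resolve_inconsistency(ConstraintSet())
        assert resolved.n_constraints == 0 and demoted == []

    def test_consistent_constraints_untouched(self):
        cs = ConstraintSet(frozenset({(0, 1), (2, 3)}), frozenset({(0, 2)}))
        resolved, demoted = resolve_inconsistency(cs)
        assert resolved == cs and demoted == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reachability_oracle(self, seed):
        # oracle: a must-link is demoted iff breadth-first reachability in
        # the ML graph connects the endpoints of some cannot-link through
        # its component
        rng = np.random.default_rng(seed)
        n = 30
        ml = {tuple(sorted(rng.choice(n, 2, replace=False))) for _ in range(25)}
        cl = {tuple(sorted(rng.choice(n, 2, replace=False))) for _ in range(10)}
        cl -= ml
        g = nx.Graph(list(ml))
        bad_nodes = set()
        for i, j in cl:
            if i in g and j in g and nx.has_path(g, i, j):
                bad_nodes |= nx.node_connected_component(g, i)
        expected_demoted = {p for p in ml if p[0] in bad_nodes}
        resolved, demoted = resolve_inconsistency(ConstraintSet(ml, cl))
        assert set(demoted) == expected_demoted
        assert resolved.must_links == frozenset(ml) - expected_demoted
        assert resolved.cannot_links == frozenset(cl)


# ---------------------------------------------------------------------------
# super-node construction = ML connected components
# ---------------------------------------------------------------------------


class TestBuildSupernodes:
    def test_chained_mustlinks_merge(self):
        cs = ConstraintSet(frozenset({(IDX["f"], IDX["d"]), (IDX["d"], IDX["a"])}))
        assignment = build_supernodes(cs, 13)
        merged = assignment.assign[[IDX["a"], IDX["d"], IDX["f"]]]
        assert len(set(merged.tolist())) == 1
        assert assignment.n_super == 11  # 13 nodes, one 3-node merge
        sizes = np.bincount(assignment.assign)
        assert sorted(sizes.tolist()) == [1] * 10 + [3]

    def test_no_constraints_identity(self):
        assignment = build_supernodes(ConstraintSet(), 7)
        assert assignment.n_super == 7
        assert np.array_equal(assignment.assign, np.arange(7))

    def test_matches_component_oracle(self):
        rng = np.random.default_rng(42)
        pairs = {tuple(sorted(rng.choice(100, 2, replace=False))) for _ in range(200)}
        assignment = build_supernodes(ConstraintSet(pairs), 100)
        g = nx.Graph(list(pairs))
        g.add_nodes_from(range(100))
        expected = {frozenset(c) for c in nx.connected_components(g)}
        got = {frozenset(m.tolist()) for m in assignment.members()}
        assert got == expected

    def test_ordered_by_smallest_member(self):
        cs = ConstraintSet(frozenset({(5, 9), (1, 7)}))
        assignment = build_supernodes(cs, 10)
        firsts = [int(m.min()) for m in assignment.members()]
        assert firsts == sorted(firsts)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            build_supernodes(ConstraintSet(frozenset({(0, 99)})), 10)


# ---------------------------------------------------------------------------
# super-adjacency accumulation (B^T A B, zero diagonal)
# ---------------------------------------------------------------------------


def _brute_force_super_adjacency(a: np.ndarray, assign: np.ndarray, n_super: int):
    out = np.zeros((n_super, n_super))
    n = len(assign)
    for p in range(n):
        for q in range(n):
            if assign[p] != assign[q]:
                out[assign[p], assign[q]] += a[p, q]
    return out


class TestInitSuperAdjacency:
    def test_cross_edges_accumulate(self, walkthrough):
        graph, constraints = walkthrough
        assignment = build_supernodes(constraints, graph.n_nodes)
        sg = init_super_adjacency(graph, assignment)
        sn_adf = assignment.assign[IDX["a"]]
        sn_bc = assignment.assign[IDX["b"]]
        assert sg.weights[sn_adf, sn_bc] == 3  # edges a-b, b-d, c-d

    def test_identity_assignment_preserves_graph(self):
        rng = np.random.default_rng(0)
        graph = random_graph(rng, 15, weighted=True)
        sg = init_super_adjacency(graph, NodeAssignment.identity(15))
        assert np.allclose(sg.dense(), graph.dense())

    def test_diagonal_zeroed_despite_internal_edges(self):
        graph = Graph.from_edges(4, [(0, 1), (2, 3), (1, 2)])
        assignment = NodeAssignment(4, 2, np.array([0, 0, 1, 1]))
        sg = init_super_adjacency(graph, assignment)
        assert np.all(sg.weights.diagonal() == 0)
        assert sg.weights[0, 1] == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        graph = random_graph(rng, 40, weighted=True)
        assign = rng.integers(0, 8, size=40)
        assign[:8] = np.arange(8)  # every super-node nonempty
        assignment = NodeAssignment(40, 8, assign)
        sg = init_super_adjacency(graph, assignment)
        expected = _brute_force_super_adjacency(graph.dense(), assign, 8)
        assert np.allclose(sg.dense(), expected)

    def test_dimension_mismatch_rejected(self):
        graph = Graph.from_edges(5, [(0, 1)])
        with pytest.raises(InputError):
            init_super_adjacency(graph, NodeAssignment.identity(4))


# ---------------------------------------------------------------------------
# cannot-link lifting (B^T C B)
# ---------------------------------------------------------------------------


class TestLiftConstraints:
    def test_single_spanning_pair(self, walkthrough):
        graph, constraints = walkthrough
        assignment = build_supernodes(constraints, graph.n_nodes)
        c_s = lift_constraints(constraints.cannot_links, assignment)
        s6 = assignment.assign[IDX["6"]]
        sb = assignment.assign[IDX["b"]]
        assert c_s[s6, sb] == 1 and c_s[sb, s6] == 1
        assert c_s.sum() == 2

    def test_empty_is_all_zero(self):
        c_s = lift_constraints([], NodeAssignment.identity(5))
        assert c_s.nnz == 0 and c_s.shape == (5, 5)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(7)
        assign = rng.integers(0, 10, size=60)
        assign[:10] = np.arange(10)
        assignment = NodeAssignment(60, 10, assign)
        pairs = set()
        while len(pairs) < 50:
            i, j = rng.choice(60, 2, replace=False)
            if assign[i] != assign[j]:
                pairs.add((min(i, j), max(i, j)))
        c_s = lift_constraints(pairs, assignment)
        expected = np.zeros((10, 10))
        for i, j in pairs:
            expected[assign[i], assign[j]] += 1
            expected[assign[j], assign[i]] += 1
        assert np.allclose(c_s.toarray(), expected)

    def test_internal_cannot_link_signals_skipped_resolution(self):
        assignment = NodeAssignment(4, 2, np.array([0, 0, 1, 1]))
        with pytest.raises(ConsistencyError):
            lift_constraints([(0, 1)], assignment)


# ---------------------------------------------------------------------------
# refinement: A_s <- max(A_s - alpha C_s, 0)
# ---------------------------------------------------------------------------


class TestRefinement:
    def test_auto_alpha_removes_weighted_superedge(self):
        # a super-edge of weight 2 vanishes when any cannot-link spans it
        sg = Graph.from_edges(3, [(0, 1), (1, 2)], weights=[2.0, 5.0])
        c_s = sp.csr_array(np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=float))
        refined = refine_with_cannot_links(sg, c_s, alpha="auto")
        assert refined.weights[0, 1] == 0
        assert refined.weights[1, 2] == 5.0

    def test_zero_cl_is_identity(self):
        rng = np.random.default_rng(1)
        sg = random_graph(rng, 8, weighted=True)
        refined = refine_with_cannot_links(sg, sp.csr_array((8, 8)), alpha="auto")
        assert np.allclose(refined.dense(), sg.dense())

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(3)
        sg = random_graph(rng, 10, p=0.4, weighted=True)
        cmat = np.triu((rng.random((10, 10)) < 0.3) * rng.integers(1, 3, (10, 10)), 1)
        cmat = (cmat + cmat.T).astype(float)
        np.fill_diagonal(cmat, 0)
        refined = refine_with_cannot_links(sg, sp.csr_array(cmat), alpha=3.0)
        a = sg.dense()
        expected = np.zeros_like(a)
        for i in range(10):
            for j in range(10):
                expected[i, j] = max(a[i, j] - 3.0 * cmat[i, j], 0.0)
        assert np.allclose(refined.dense(), expected)

    def test_negative_alpha_rejected(self):
        sg = Graph.from_edges(2, [(0, 1)])
        with pytest.raises(InputError):
            refine_with_cannot_links(sg, sp.csr_array((2, 2)), alpha=-1.0)

    def test_idempotent_under_auto_alpha(self):
        rng = np.random.default_rng(5)
        sg = random_graph(rng, 12, weighted=True)
        cmat = np.zeros((12, 12))
        cmat[0, 1] = cmat[1, 0] = 1
        cmat[2, 5] = cmat[5, 2] = 2
        once = refine_with_cannot_links(sg, sp.csr_array(cmat), "auto")
        twice = refine_with_cannot_links(once, sp.csr_array(cmat), "auto")
        assert np.allclose(once.dense(), twice.dense())


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


class TestConstructSupernetwork:
    def test_no_constraints_is_identity(self):
        rng = np.random.default_rng(11)
        graph = random_graph(rng, 20)
        sn = construct_supernetwork(graph, ConstraintSet())
        assert sn.n_super == 20
        assert np.allclose(sn.super_graph.dense(), graph.dense())

    def test_spanning_tree_contracts_to_point(self):
        rng = np.random.default_rng(2)
        graph = random_graph(rng, 10, p=0.5)
        ml = frozenset((i, i + 1) for i in range(9))
        sn = construct_supernetwork(graph, ConstraintSet(ml))
        assert sn.n_super == 1
        assert sn.super_graph.dense().shape == (1, 1)
        assert sn.super_graph.weights.nnz == 0

    def test_walkthrough_narrative(self, walkthrough):
        graph, constraints = walkthrough
        sn = construct_supernetwork(graph, constraints)
        assert sn.n_super == 10  # 13 nodes, merges {a,d,f} and {b,c}
        a = sn.assignment.assign
        sn_adf, sn_bc, sn_6 = a[IDX["a"]], a[IDX["b"]], a[IDX["6"]]
        assert sn.unrefined_super_graph.weights[sn_adf, sn_bc] == 3
        # weight-2 super-edge {6}-{b,c} suppressed by the cannot-link
        assert sn.unrefined_super_graph.weights[sn_6, sn_bc] == 2
        assert sn.super_graph.weights[sn_6, sn_bc] == 0
        # untouched singletons keep their original unit edge
        s1, s7 = a[IDX["1"]], a[IDX["7"]]
        assert sn.super_graph.weights[s1, s7] == 1

    def test_demoted_mustlinks_become_unit_edges(self):
        # contradiction on nodes 0-1-2; pair (0,1) had no edge before
        graph = Graph.from_edges(4, [(1, 2), (2, 3)])
        cs = ConstraintSet(frozenset({(0, 1), (1, 2)}), frozenset({(0, 2)}))
        sn = construct_supernetwork(graph, cs)
        assert sn.n_super == 4  # everything demoted, no contraction
        assert set(sn.demoted_links) == {(0, 1), (1, 2)}
        assert sn.super_graph.weights[0, 1] == 1  # new normal link
        # edge (1,2) existed already and keeps weight 1
        assert sn.super_graph.weights[1, 2] == 1
        # the retained cannot-link removes the (0,2)-entry if present
        assert sn.super_graph.weights[0, 2] == 0

    def test_weight_conservation_before_refinement(self):
        rng = np.random.default_rng(23)
        graph = random_graph(rng, 30, weighted=True)
        ml = {tuple(sorted(rng.choice(30, 2, replace=False))) for _ in range(12)}
        sn = construct_supernetwork(graph, ConstraintSet(ml))
        assign = sn.assignment.assign
        a = graph.dense()
        expected = sum(
            a[p, q]
            for p in range(30)
            for q in range(30)
            if assign[p] != assign[q]
        )
        assert np.isclose(sn.unrefined_super_graph.weights.sum(), expected)

    def test_supernode_count_equals_forest_formula(self):
        rng = np.random.default_rng(29)
        for _ in range(5):
            ml = {tuple(sorted(rng.choice(40, 2, replace=False))) for _ in range(25)}
            g = nx.Graph(list(ml))
            forest_edges = sum(len(c) - 1 for c in nx.connected_components(g))
            assignment = build_supernodes(ConstraintSet(ml), 40)
            assert assignment.n_super == 40 - forest_edges


# ---------------------------------------------------------------------------
# label projection
# ---------------------------------------------------------------------------


class TestProjectLabels:
    def test_members_inherit_supernode_label(self):
        assignment = NodeAssignment(5, 2, np.array([0, 1, 0, 0, 1]))
        sp_labels = Partition(np.array(["circle", "square"], dtype=object))
        projected = project_labels(sp_labels, assignment)
        assert list(projected.labels) == ["circle", "square", "circle", "circle", "square"]

    def test_identity_assignment_is_noop(self):
        labels = Partition(np.array([2, 0, 1, 1]))
        out = project_labels(labels, NodeAssignment.identity(4))
        assert np.array_equal(out.labels, labels.labels)

    def test_every_mustlink_pair_shares_label(self):
        rng = np.random.default_rng(17)
        ml = {tuple(sorted(rng.choice(50, 2, replace=False))) for _ in range(30)}
        assignment = build_supernodes(ConstraintSet(ml), 50)
        super_labels = Partition(rng.integers(0, 4, size=assignment.n_super))
        projected = project_labels(super_labels, assignment)
        for i, j in ml:
            assert projected.labels[i] == projected.labels[j]

    def test_unlabeled_supernode_rejected(self):
        assignment = NodeAssignment(3, 3, np.arange(3))
        with pytest.raises(InputError):
            project_labels(Partition(np.array([0, 1])), assignment)


# ---------------------------------------------------------------------------
# ModTop baseline
# ---------------------------------------------------------------------------


class TestModTop:
    def test_empty_constraints_noop(self):
        rng = np.random.default_rng(4)
        graph = random_graph(rng, 12)
        out = modtop(graph, ConstraintSet())
        assert np.allclose(out.dense(), graph.dense())

    def test_mustlink_creates_unit_edge(self):
        graph = Graph.from_edges(3, [(1, 2)])
        out = modtop(graph, ConstraintSet(frozenset({(0, 1)})))
        assert out.weights[0, 1] == 1 and out.weights[1, 0] == 1

    def test_cannotlink_removes_edge(self):
        graph = Graph.from_edges(3, [(0, 1), (1, 2)])
        out = modtop(graph, ConstraintSet(cannot_links=frozenset({(0, 1)})))
        assert out.weights[0, 1] == 0 and out.weights[1, 2] == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_entrywise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        graph = random_graph(rng, 20, p=0.3)
        ml = {tuple(sorted(rng.choice(20, 2, replace=False))) for _ in range(8)}
        cl = {tuple(sorted(rng.choice(20, 2, replace=False))) for _ in range(8)} - ml
        out = modtop(graph, ConstraintSet(ml, cl))
        expected = graph.dense().copy()
        for i, j in ml:
            expected[i, j] = expected[j, i] = 1.0
        for i, j in cl:
            expected[i, j] = expected[j, i] = 0.0
        assert np.allclose(out.dense(), expected)


# ---------------------------------------------------------------------------
# Graph / ConstraintSet type invariants
# ---------------------------------------------------------------------------


class TestTypeInvariants:
    def test_asymmetric_adjacency_rejected(self):
        mat = sp.csr_array(np.array([[0.0, 1.0], [0.0, 0.0]]))
        with pytest.raises(InputError):
            Graph(mat)

    def test_self_pair_constraint_rejected(self):
        with pytest.raises(InputError):
            ConstraintSet(frozenset({(3, 3)}))

    def test_duplicate_edges_collapse_to_max(self):
        g = Graph.from_edges(2, [(0, 1), (1, 0)], weights=[2.0, 3.0])
        assert g.weights[0, 1] == 3.0

    def test_empty_supernode_rejected(self):
        with pytest.raises(InputError):
            NodeAssignment(3, 3, np.array([0, 0, 1]))
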