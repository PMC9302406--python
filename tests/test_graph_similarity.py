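"""Graphlet orbit counting and order-preserving alignment, vs brute force."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contactpfp.errors import DegenerateInputError, InputError
from contactpfp.graph_similarity import (
    ORBIT_WEIGHTS,
    AlignmentResult,
    align_graphs,
    count_orbits,
    node_similarity,
    similarity_matrix,
)
from contactpfp.synthetic import perturb_graph

from conftest import make_graph, random_contact_graph


def brute_force_orbits(graph):
    """Independent oracle: enumerate all 2-4 node subsets, keep connected
    induced subgraphs, classify each node's orbit from its induced degree."""
    L = graph.length
    g = graph.to_networkx()
    counts = np.zeros((L, 15), dtype=int)
    for k in (2, 3, 4):
        for sub in itertools.combinations(range(1, L + 1), k):
            h = g.subgraph(sub)
            if not nx.is_connected(h):
                continue
            m = h.number_of_edges()
            degs = dict(h.degree())
            dmax = max(degs.values())
            for v in sub:
                d = degs[v]
                if k == 2:
                    orbit = 0
                elif k == 3:
                    orbit = 3 if m == 3 else (2 if d == 2 else 1)
                elif m == 3:
                    orbit = (7 if d == 3 else 6) if dmax == 3 else (5 if d == 2 else 4)
                elif m == 4:
                    orbit = 8 if dmax == 2 else (9 if d == 1 else 10 if d == 2 else 11)
                elif m == 5:
                    orbit = 13 if d == 3 else 12
                else:
                    orbit = 14
                counts[v - 1, orbit] += 1
    return counts


def brute_force_alignment_score(g1, g2):
    """Maximum over all order-preserving partial matchings, by enumeration."""
    S = similarity_matrix(count_orbits(g1), count_orbits(g2))
    n1, n2 = S.shape
    best = 0.0
    for k in range(min(n1, n2) + 1):
        for rows in itertools.combinations(range(n1), k):
            for cols in itertools.combinations(range(n2), k):
                best = max(best, sum(S[r, c] for r, c in zip(rows, cols)))
    return best / max(n1, n2)


class TestOrbitCounts:
    def test_three_node_path(self):
        g = make_graph({(1, 2), (2, 3)}, 3)
        c = count_orbits(g)
        end = np.zeros(15, dtype=int)
        end[[0, 1]] = 1
        middle = np.zeros(15, dtype=int)
        middle[0], middle[2] = 2, 1
        assert (c[0] == end).all() and (c[2] == end).all()
        assert (c[1] == middle).all()

    def test_triangle(self):
        g = make_graph({(1, 2), (2, 3), (1, 3)}, 3)
        c = count_orbits(g)
        expected = np.zeros(15, dtype=int)
        expected[0], expected[3] = 2, 1
        assert (c == expected).all()

    def test_edgeless_graph_is_all_zero(self):
        assert not count_orbits(make_graph(set(), 6)).any()

    def test_orbit_zero_is_degree(self):
        rng = np.random.default_rng(0)
        g = random_contact_graph(rng, max_nodes=12)
        degrees = np.zeros(g.length, dtype=int)
        for i, j in g.edges:
            degrees[i - 1] += 1
            degrees[j - 1] += 1
        assert (count_orbits(g)[:, 0] == degrees).all()

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        g = random_contact_graph(rng)
        assert (count_orbits(g) == brute_force_orbits(g)).all()

    def test_invariant_under_relabeling(self):
        g = make_graph({(1, 2), (2, 3), (3, 4), (1, 4), (1, 3)}, 4)
        # reverse node order: relabel k -> 5 - k
        rel = make_graph({(5 - j, 5 - i) for i, j in g.edges}, 4)
        assert (count_orbits(g) == count_orbits(rel)[::-1]).all()


class TestNodeSimilarity:
    def test_identical_signatures_score_one(self):
        sig = np.array([3, 1, 0, 2, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        assert node_similarity(sig, sig) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            u = rng.integers(0, 50, size=15)
            v = rng.integers(0, 50, size=15)
            assert node_similarity(u, v) == pytest.approx(node_similarity(v, u))

    def test_single_orbit_difference_closed_form(self):
        u = np.zeros(15)
        v = np.zeros(15)
        v[0] = 5
        expected = 1.0 - ORBIT_WEIGHTS[0] * (math.log(6) / math.log(7)) / ORBIT_WEIGHTS.sum()
        assert node_similarity(u, v) == pytest.approx(expected)

    def test_wrong_length_rejected(self):
        with pytest.raises(InputError):
            node_similarity(np.zeros(14), np.zeros(15))

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            u = rng.integers(0, 1000, size=15)
            v = rng.integers(0, 1000, size=15)
            assert 0.0 <= node_similarity(u, v) <= 1.0


class TestAlignGraphs:
    def test_self_alignment_is_identity_with_score_one(self):
        rng = np.random.default_rng(3)
        g = random_contact_graph(rng, max_nodes=12)
        res = align_graphs(g, g)
        assert res.score == pytest.approx(1.0)
        assert res.mapping == tuple((i, i) for i in range(1, g.length + 1))

    def test_score_is_symmetric(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            g1 = random_contact_graph(rng, max_nodes=10, protein_id="a")
            g2 = random_contact_graph(rng, max_nodes=10, protein_id="b")
            assert align_graphs(g1, g2).score == pytest.approx(align_graphs(g2, g1).score)

    def test_mapping_is_strictly_increasing(self):
        rng = np.random.default_rng(5)
        g1 = random_contact_graph(rng, max_nodes=15)
        g2 = random_contact_graph(rng, max_nodes=15)
        mapping = align_graphs(g1, g2).mapping
        for (i1, j1), (i2, j2) in zip(mapping, mapping[1:]):
            assert i1 < i2 and j1 < j2

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_over_order_preserving_matchings(self, seed):
        rng = np.random.default_rng(seed)
        g1 = random_contact_graph(rng, max_nodes=6, protein_id="a")
        g2 = random_contact_graph(rng, max_nodes=6, protein_id="b")
        assert align_graphs(g1, g2).score == pytest.approx(
            brute_force_alignment_score(g1, g2), abs=1e-9
        )

    def test_empty_graph_rejected(self):
        # a node-less contact graph is rejected at construction time
        with pytest.raises(InputError):
            make_graph(set(), 0)

    def test_score_bounded(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            g1 = random_contact_graph(rng, max_nodes=12, protein_id="a")
            g2 = random_contact_graph(rng, max_nodes=12, protein_id="b")
            assert 0.0 <= align_graphs(g1, g2).score <= 1.0

    def test_perturbation_decreases_mean_score(self):
        """More edge flips -> lower mean similarity to the original (statistical)."""
        rng = np.random.default_rng(8)
        mean_scores = []
        for rate in (0.02, 0.15, 0.45):
            scores = []
            for t in range(50):
                g = random_contact_graph(rng, max_nodes=14, p=0.3, protein_id="g")
                h = perturb_graph(g, rate, seed=1000 + t)
                scores.append(align_graphs(g, h).score)
            mean_scores.append(np.mean(scores))
        assert mean_scores[0] > mean_scores[1] > mean_scores[2]
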