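"""Community detection: objectives, oracles, sweep, consensus, similarity."""

import math

import numpy as np
import pytest

from segtraj import (
    SyntheticDesign,
    build_population_covariance,
    consensus_partition,
    default_densities,
    density_sweep,
    detect_communities,
    generate_parcellation,
    map_equation_codelength,
    modularity,
    partition_similarity,
    threshold_by_density,
)

from conftest import make_matrix, make_partition


def set_partitions(items):
    """All set partitions of a sequence (Bell-number enumeration)."""
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[head] + part[i]] + part[i + 1 :]
        yield [[head]] + part


def brute_force_modularity(m):
    """Exhaustively maximize weighted modularity over all node partitions."""
    n = m.n_nodes
    best_q, best_labels = -np.inf, None
    for blocks in set_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for lab, block in enumerate(blocks, start=1):
            labels[block] = lab
        q = modularity(m, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, best_labels


def two_cliques(n_per=4, bridge=0.0):
    edges = {}
    for a in range(n_per):
        for b in range(a + 1, n_per):
            edges[(a, b)] = 1.0
            edges[(n_per + a, n_per + b)] = 1.0
    if bridge:
        edges[(0, n_per)] = bridge
    return make_matrix(edges, 2 * n_per)


def ring_of_triangles(n_tri=4, intra=1.0, bridge=0.1):
    edges = {}
    for t in range(n_tri):
        a, b, c = 3 * t, 3 * t + 1, 3 * t + 2
        edges[(a, b)] = edges[(a, c)] = edges[(b, c)] = intra
        edges[tuple(sorted((c, (3 * (t + 1)) % (3 * n_tri))))] = bridge
    return make_matrix(edges, 3 * n_tri)


class TestDetectCommunities:
    @pytest.mark.parametrize("method", ["map_equation", "modularity"])
    def test_disconnected_cliques_found_exactly(self, method):
        m = two_cliques()
        p = detect_communities(m, method=method, seed=1, n_restarts=5)
        assert p.n_communities == 2
        assert len(set(p.labels[:4])) == 1 and len(set(p.labels[4:])) == 1
        assert p.labels[0] != p.labels[4]

    @pytest.mark.parametrize("method", ["map_equation", "modularity"])
    def test_uniform_complete_graph_is_one_community(self, method):
        edges = {(i, j): 1.0 for i in range(6) for j in range(i + 1, 6)}
        p = detect_communities(make_matrix(edges, 6), method=method, seed=1, n_restarts=5)
        assert p.n_communities == 1

    def test_modularity_matches_exhaustive_optimum_small_graphs(self, rng):
        graphs = [
            two_cliques(3, bridge=0.2),  # 6 nodes
            two_cliques(4, bridge=0.5),  # 8 nodes
        ]
        # a seeded random weighted 7-node graph
        v = np.abs(rng.normal(size=(7, 7)))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        graphs.append(make_matrix({(i, j): v[i, j] for i in range(7) for j in range(i + 1, 7)}, 7))
        for m in graphs:
            best_q, _ = brute_force_modularity(m)
            p = detect_communities(m, method="modularity", seed=3, n_restarts=10)
            assert p.quality == pytest.approx(best_q, abs=1e-12)

    @pytest.mark.parametrize("method", ["map_equation", "modularity"])
    def test_ring_of_triangles_recovers_planted_blocks(self, method):
        m = ring_of_triangles()
        p = detect_communities(m, method=method, seed=2, n_restarts=10)
        planted = make_partition(np.repeat(np.arange(1, 5), 3))
        assert partition_similarity(p, planted)["ari"] == 1.0
        if method == "modularity":
            assert p.quality >= modularity(m, planted.labels) - 1e-12

    @pytest.mark.parametrize("method", ["map_equation", "modularity"])
    def test_seeded_determinism(self, method):
        m = ring_of_triangles()
        a = detect_communities(m, method=method, seed=11, n_restarts=5)
        b = detect_communities(m, method=method, seed=11, n_restarts=5)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.quality == b.quality

    def test_isolated_nodes_unassigned_and_empty_graph_rejected(self):
        m = make_matrix({(0, 1): 1.0, (1, 2): 1.0, (0, 2): 1.0}, 5)
        p = detect_communities(m, seed=0, n_restarts=3)
        assert (p.labels[3:] == -1).all()
        with pytest.raises(ValueError):
            detect_communities(make_matrix({}, 4), seed=0)

    def test_codelength_prefers_planted_over_lumped(self):
        m = two_cliques(4, bridge=0.1)
        planted = np.array([1] * 4 + [2] * 4)
        lumped = np.ones(8, dtype=int)
        assert map_equation_codelength(m, planted) < map_equation_codelength(m, lumped)


class TestDensitySweep:
    def test_default_sweep_has_40_densities(self):
        assert len(default_densities()) == 40
        assert default_densities()[0] == pytest.approx(0.005)
        assert default_densities()[-1] == pytest.approx(0.20)

    def test_singleton_sweep_tags_density(self, rng):
        from conftest import random_symmetric

        m = random_symmetric(15, rng)
        parts = density_sweep(m, [0.07], seed=0, n_restarts=3)
        assert len(parts) == 1 and parts[0].density == 0.07

    def test_rejects_non_increasing_densities(self, rng):
        from conftest import random_symmetric

        with pytest.raises(ValueError):
            density_sweep(random_symmetric(8, rng), [0.1, 0.1], seed=0)

    def test_planted_blocks_recovered_across_sweep(self):
        d = SyntheticDesign(
            n_nodes=24, n_systems=3, within_r=0.6, between_r_base=0.05,
            between_r_age_slope=0.0, ages=(3.0,), seed=4,
        )
        nodes = generate_parcellation(d)
        cov = build_population_covariance(nodes, d, 0.0)
        z = np.arctanh(np.clip(cov, -0.99, 0.99))
        np.fill_diagonal(z, 0.0)
        m = make_matrix({}, 24)
        m.values = z
        planted = make_partition(nodes["system"].astype("category").cat.codes.to_numpy() + 1)
        densities = [x for x in default_densities() if x >= 0.05]
        for p in density_sweep(m, densities, seed=6, n_restarts=5):
            assert partition_similarity(p, planted)["ari"] == 1.0


class TestConsensus:
    def test_identity_when_all_communities_large(self):
        m = two_cliques(4, bridge=0.2)
        parts = density_sweep(m, [0.05, 0.07, 0.10], seed=1, n_restarts=5)
        ref = next(p for p in parts if math.isclose(p.density, 0.07))
        cons = consensus_partition(parts, m, min_size=3, reference_density=0.07)
        np.testing.assert_array_equal(cons.labels, ref.labels)

    def test_singleton_joins_plurality_community(self):
        # node 6 forms its own community but all its edges go to community 1
        edges = {(i, j): 1.0 for i in range(3) for j in range(i + 1, 3)}
        edges.update({(3 + i, 3 + j): 1.0 for i in range(3) for j in range(i + 1, 3)})
        edges[(0, 6)] = 0.5
        edges[(1, 6)] = 0.5
        m = make_matrix(edges, 7)
        ref = make_partition([1, 1, 1, 2, 2, 2, 3], density=1.0)
        cons = consensus_partition([ref], m, min_size=3, reference_density=1.0)
        assert cons.labels[6] == cons.labels[0]

    def test_spurious_small_community_dissolved_to_planted(self):
        d = SyntheticDesign(
            n_nodes=20, n_systems=4, within_r=0.6, between_r_base=0.05,
            between_r_age_slope=0.0, ages=(3.0,), seed=9,
        )
        nodes = generate_parcellation(d)
        cov = build_population_covariance(nodes, d, 0.0)
        z = np.arctanh(np.clip(cov, -0.99, 0.99))
        np.fill_diagonal(z, 0.0)
        m = make_matrix({}, 20)
        m.values = z
        planted = nodes["system"].astype("category").cat.codes.to_numpy() + 1
        corrupted = planted.copy()
        mislabeled = np.flatnonzero(planted == 1)[:2]
        corrupted[mislabeled] = 5  # spurious 2-node community
        ref = make_partition(corrupted, density=0.3)
        cons = consensus_partition([ref], m, min_size=3, reference_density=0.3)
        assert partition_similarity(cons, make_partition(planted))["ari"] == 1.0

    def test_rejects_when_everything_is_small(self):
        m = two_cliques(3)
        ref = make_partition([1, 2, 3, 4, 5, 6], density=0.5)
        with pytest.raises(ValueError, match="min_size"):
            consensus_partition([ref], m, min_size=4, reference_density=0.5)

    def test_requires_reference_density_present(self):
        m = two_cliques(3)
        ref = make_partition([1, 1, 1, 2, 2, 2], density=0.5)
        with pytest.raises(ValueError, match="reference density"):
            consensus_partition([ref], m, min_size=2, reference_density=0.07)


class TestPartitionSimilarity:
    def test_identical_partitions(self):
        p = make_partition([1, 1, 2, 2, 3, 3])
        sim = partition_similarity(p, p)
        assert sim == {"ari": 1.0, "nmi": 1.0}

    def test_singletons_vs_blocks_is_chance(self):
        a = make_partition(np.arange(1, 9))
        b = make_partition([1, 1, 1, 1, 2, 2, 2, 2])
        assert partition_similarity(a, b)["ari"] == pytest.approx(0.0, abs=1e-12)

    def test_ari_matches_contingency_formula(self):
        a = make_partition([1, 1, 1, 2, 2, 2, 3, 3])
        b = make_partition([1, 1, 2, 2, 2, 3, 3, 3])
        # independent oracle: direct contingency-table ARI
        labels_a, labels_b = a.labels, b.labels
        cont = np.zeros((3, 3))
        for x, y in zip(labels_a, labels_b):
            cont[x - 1, y - 1] += 1
        comb = lambda v: v * (v - 1) / 2.0
        sum_ij = comb(cont).sum()
        sum_a = comb(cont.sum(axis=1)).sum()
        sum_b = comb(cont.sum(axis=0)).sum()
        total = comb(np.array(8.0))
        expected = (sum_ij - sum_a * sum_b / total) / (
            0.5 * (sum_a + sum_b) - sum_a * sum_b / total
        )
        assert partition_similarity(a, b)["ari"] == pytest.approx(float(expected), abs=1e-12)

    def test_unassigned_excluded_and_no_overlap_rejected(self):
        a = make_partition([1, 1, -1, 2])
        b = make_partition([2, 2, 1, -1])
        sim = partition_similarity(a, b)  # only nodes 0, 1, 3 -> 0,1 co-assigned
        assert sim["ari"] == 1.0
        with pytest.raises(ValueError):
            partition_similarity(make_partition([-1, -1]), make_partition([1, 1]))
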