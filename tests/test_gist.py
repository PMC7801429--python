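import math
from collections import Counter

import numpy as np
import pytest

from impala.core_model import (
    InteractionNetwork,
    Pathway,
    PathwaySampleSet,
    SamplerMeta,
)
from impala.gist import (
    EnumerationCapExceeded,
    SamplerConfig,
    conditional_sample_position,
    consensus_network,
    enumerate_exact,
    enumerate_paths,
    estimate_edge_probabilities,
    initialize_pathway,
    rank_pathways,
    run_chain,
)
from impala.landscape import Landscape
from impala.potentials import PotentialTables, boltzmann_distribution

from conftest import make_boltzmann_fixture


def _uniform_tables(net: InteractionNetwork, lam=0.0) -> PotentialTables:
    edge: dict = {g: {} for g in net.genes}
    for e in net.edges:
        a, b = tuple(e)
        edge[a][b] = edge[b][a] = 0.0
    return PotentialTables(
        node={g: 0.0 for g in net.genes}, edge=edge, locations={}, lam=lam
    )


@pytest.fixture
def triangle_landscape(triangle):
    return Landscape(triangle, "A", "C", 3)


class TestEnumerate:
    def test_triangle_single_path(self, triangle_landscape):
        assert enumerate_paths(triangle_landscape) == [("A", "B", "C")]

    def test_cap_enforced(self):
        # complete graph on 9 nodes: 7!/(2!) length-5 paths exceed a tiny cap
        nodes = [f"N{i}" for i in range(9)]
        net = InteractionNetwork.build(
            [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
        )
        scape = Landscape(net, nodes[0], nodes[-1], 5)
        with pytest.raises(EnumerationCapExceeded):
            enumerate_paths(scape, cap=10)

    def test_single_path_probability_one(self, triangle_landscape, triangle):
        pathways, probs, edges = enumerate_exact(
            triangle_landscape, _uniform_tables(triangle)
        )
        assert probs == pytest.approx([1.0])
        assert edges[("A", "B")]["probability"] == 1.0

    def test_two_equal_paths(self):
        net = InteractionNetwork.build(
            [("S", "X"), ("S", "Y"), ("X", "T"), ("Y", "T")]
        )
        scape = Landscape(net, "S", "T", 3)
        pathways, probs, edges = enumerate_exact(scape, _uniform_tables(net))
        assert sorted(probs) == pytest.approx([0.5, 0.5])
        assert edges[("S", "X")]["mass"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [2, 3, 5])
    def test_probabilities_match_independent_normalization(self, seed):
        net, scape, tables = make_boltzmann_fixture(seed)
        pathways, probs, _ = enumerate_exact(scape, tables)
        # independent recomputation: score each path by direct summation
        u = []
        for pw in pathways:
            genes = pw.genes
            v1 = sum(tables.node[g] for g in genes)
            v2 = sum(tables.edge[a][b] for a, b in zip(genes[:-1], genes[1:]))
            v3 = 0.5  # lam=0.5, empty locations: fully concordant
            u.append(v1 + v2 + v3)
        w = np.exp((np.array(u) - max(u)) / tables.temperature)
        assert probs == pytest.approx(w / w.sum(), abs=1e-12)


class TestInitialize:
    def test_unique_path_always_found(self, triangle_landscape):
        rng = np.random.default_rng(0)
        for _ in range(5):
            assert initialize_pathway(triangle_landscape, rng) == ("A", "B", "C")

    def test_deterministic_given_seed(self):
        net, scape, _ = make_boltzmann_fixture(2)
        a = initialize_pathway(scape, np.random.default_rng(1))
        b = initialize_pathway(scape, np.random.default_rng(1))
        assert a == b

    def test_uniform_over_enumerable_paths(self):
        # 30-node fixture: every path within 4 sigma of the uniform share
        rng = np.random.default_rng(8)
        import networkx as nx

        g = nx.erdos_renyi_graph(30, 0.15, seed=4)
        nodes = [f"N{i:02d}" for i in range(30)]
        net = InteractionNetwork.build(
            [(nodes[a], nodes[b]) for a, b in g.edges], extra_genes=nodes
        )
        scape = Landscape(net, nodes[0], nodes[-1], 4)
        paths = enumerate_paths(scape)
        assert len(paths) > 2
        draws = 10_000
        hits = Counter(initialize_pathway(scape, rng) for _ in range(draws))
        p = 1 / len(paths)
        sigma = math.sqrt(draws * p * (1 - p))
        for path in paths:
            assert abs(hits[path] - draws * p) < 4 * sigma


class TestConditionalSample:
    def test_single_candidate_unchanged(self, triangle_landscape, triangle):
        rng = np.random.default_rng(0)
        out = conditional_sample_position(
            ("A", "B", "C"), 1, triangle_landscape, _uniform_tables(triangle), rng
        )
        assert out == ("A", "B", "C")

    def test_equal_energies_half_half(self):
        net = InteractionNetwork.build(
            [("S", "X"), ("S", "Y"), ("X", "T"), ("Y", "T")]
        )
        scape = Landscape(net, "S", "T", 3)
        tables = _uniform_tables(net)
        rng = np.random.default_rng(0)
        draws = 10_000
        hits = Counter(
            conditional_sample_position(("S", "X", "T"), 1, scape, tables, rng)[1]
            for _ in range(draws)
        )
        sigma = math.sqrt(draws * 0.25)
        assert abs(hits["X"] - draws / 2) < 3 * sigma

    def test_frequencies_match_boltzmann_ratios(self):
        # diamond with unequal node scores: P(X)/P(Y) = exp((U_X - U_Y)/T)
        net = InteractionNetwork.build(
            [("S", "X"), ("S", "Y"), ("S", "Z"), ("X", "T"), ("Y", "T"), ("Z", "T")]
        )
        scape = Landscape(net, "S", "T", 3)
        edge: dict = {g: {} for g in net.genes}
        for e in net.edges:
            a, b = tuple(e)
            edge[a][b] = edge[b][a] = 0.0
        node = {"S": 0.0, "T": 0.0, "X": 1.0, "Y": 0.3, "Z": 0.0}
        tables = PotentialTables(node=node, edge=edge, locations={}, lam=0.0)
        expected = boltzmann_distribution([1.0, 0.3, 0.0], 1.0)
        rng = np.random.default_rng(3)
        draws = 20_000
        hits = Counter(
            conditional_sample_position(("S", "X", "T"), 1, scape, tables, rng)[1]
            for _ in range(draws)
        )
        for gene, p in zip(("X", "Y", "Z"), expected):
            sigma = math.sqrt(draws * p * (1 - p))
            assert abs(hits[gene] - draws * p) < 3 * sigma

    def test_interior_only(self, triangle_landscape, triangle):
        with pytest.raises(ValueError):
            conditional_sample_position(
                ("A", "B", "C"), 0, triangle_landscape, _uniform_tables(triangle),
                np.random.default_rng(0),
            )


class TestRunChain:
    def test_unique_path_count_equals_post_burn_in(self, triangle_landscape, triangle):
        cfg = SamplerConfig(iterations=100, burn_in_fraction=0.2, seed=0)
        ss = run_chain(cfg, triangle_landscape, _uniform_tables(triangle))
        assert ss.counts == {("A", "B", "C"): 80}

    def test_bitwise_reproducible(self):
        net, scape, tables = make_boltzmann_fixture(3)
        cfg = SamplerConfig(iterations=2_000, seed=11)
        a = run_chain(cfg, scape, tables)
        b = run_chain(cfg, scape, tables)
        assert a.counts == b.counts and a.pathways == b.pathways

    def test_converges_to_boltzmann(self):
        net, scape, tables = make_boltzmann_fixture(6)
        pathways, probs, _ = enumerate_exact(scape, tables)
        exact = {p.genes: pr for p, pr in zip(pathways, probs)}
        ss = run_chain(SamplerConfig(iterations=20_000, seed=5), scape, tables)
        tv = 0.5 * sum(
            abs(ss.counts.get(k, 0) / ss.total - v) for k, v in exact.items()
        )
        assert tv < 0.1

    def test_convergence_improves_with_sweeps(self):
        net, scape, tables = make_boltzmann_fixture(6)
        pathways, probs, _ = enumerate_exact(scape, tables)
        exact = {p.genes: pr for p, pr in zip(pathways, probs)}

        def tv_at(iters):
            ss = run_chain(SamplerConfig(iterations=iters, seed=9), scape, tables)
            return 0.5 * sum(
                abs(ss.counts.get(k, 0) / ss.total - v) for k, v in exact.items()
            )

        assert tv_at(40_000) < tv_at(1_000)

    def test_samples_are_valid_paths(self):
        net, scape, tables = make_boltzmann_fixture(2)
        ss = run_chain(SamplerConfig(iterations=500, seed=1), scape, tables)
        for key in ss.counts:
            pw = ss.pathways[key]
            assert key[0] == scape.source and key[-1] == scape.target
            pw.validate_against(net)
            assert pw.energy == pytest.approx(pw.v1 + pw.v2 + pw.v3)


class TestEdgeProbabilities:
    def _sample_set(self, counts):
        pathways = {k: Pathway(genes=k) for k in counts}
        return PathwaySampleSet(counts=counts, pathways=pathways, meta=SamplerMeta())

    def test_one_orientation_is_certain(self):
        ss = self._sample_set({("A", "B", "C"): 10})
        probs = {(e.source, e.target): e for e in estimate_edge_probabilities(ss)}
        assert probs[("A", "B")].probability == 1.0
        assert probs[("B", "A")].probability == 0.0

    def test_tie_gives_half(self):
        ss = self._sample_set({("A", "B", "C"): 5, ("C", "B", "A"): 5})
        probs = {(e.source, e.target): e for e in estimate_edge_probabilities(ss)}
        assert probs[("A", "B")].probability == 0.5
        assert probs[("A", "B")].support == 10

    def test_orientations_sum_to_one(self):
        net, scape, tables = make_boltzmann_fixture(5)
        ss = run_chain(SamplerConfig(iterations=5_000, seed=2), scape, tables)
        probs = {(e.source, e.target): e.probability for e in estimate_edge_probabilities(ss)}
        for (a, b), p in probs.items():
            assert p + probs[(b, a)] == pytest.approx(1.0)
            assert 0.0 <= p <= 1.0

    def test_reverse_samples_are_reoriented(self):
        fwd = self._sample_set({("A", "B", "C"): 4})
        rev = self._sample_set({("C", "B", "A"): 4})  # target -> source search
        probs = {
            (e.source, e.target): e.probability
            for e in estimate_edge_probabilities(fwd, rev)
        }
        assert probs[("A", "B")] == 1.0  # both searches agree after flip

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            estimate_edge_probabilities([], [])


class TestConsensus:
    def _sample_set(self, counts, energies=None):
        pathways = {
            k: Pathway(genes=k, v1=(energies or {}).get(k, 0.0)) for k in counts
        }
        return PathwaySampleSet(counts=counts, pathways=pathways, meta=SamplerMeta())

    def test_top_one_is_modal_chain(self):
        ss = self._sample_set({("A", "B", "C"): 9, ("A", "D", "C"): 1})
        g = consensus_network(ss, top_k=1)
        assert list(g.edges) == [("A", "B"), ("B", "C")]

    def test_top_k_beyond_distinct_unions_everything(self):
        ss = self._sample_set({("A", "B", "C"): 9, ("A", "D", "C"): 1})
        g = consensus_network(ss, top_k=50)
        assert set(g.nodes) == {"A", "B", "C", "D"}

    def test_gene_frequency_annotation(self):
        ss = self._sample_set({("A", "B", "C"): 9, ("A", "D", "C"): 1})
        g = consensus_network(ss, top_k=50)
        assert g.nodes["A"]["count"] == 10
        assert g.nodes["D"]["frequency"] == pytest.approx(0.1)

    def test_top_200_matches_independent_ranking(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(40)]
        counts, energies = {}, {}
        while len(counts) < 300:
            k = tuple(rng.choice(genes, size=5, replace=False))
            counts[k] = int(rng.integers(1, 50))
            energies[k] = float(rng.normal())
        ss = self._sample_set(counts, energies)
        g = consensus_network(ss, top_k=200)
        # independent ranking oracle
        ranked = sorted(counts, key=lambda k: (-counts[k], -energies[k], k))[:200]
        expected_nodes = {x for k in ranked for x in k}
        assert set(g.nodes) == expected_nodes

    def test_tie_break_deterministic(self):
        ss = self._sample_set(
            {("A", "B", "C"): 5, ("A", "D", "C"): 5},
            energies={("A", "B", "C"): 0.0, ("A", "D", "C"): 1.0},
        )
        assert rank_pathways(ss)[0] == ("A", "D", "C")
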