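"""Shared fixtures: programmatically generated networks, expression data,
oracle landscapes with random potential tables, and planted pathway-family
sample sets.  Everything is deterministic given the seeds frozen here.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from impala.core_model import (
    ExpressionMatrix,
    InteractionNetwork,
    Pathway,
    PathwaySampleSet,
    SamplerMeta,
)
from impala.landscape import Landscape
from impala.potentials import PotentialTables


def make_boltzmann_fixture(seed: int, n: int = 12, p: float = 0.45, L: int = 5):
    """A small random landscape with random finite potential tables.

    Node/edge scores are N(0, 0.8) / |N(0, 0.8)| so the Boltzmann
    distribution at T=1 is peaked but not degenerate.
    """
    rng = np.random.default_rng(seed)
    g = nx.erdos_renyi_graph(n, p, seed=int(rng.integers(2**31)))
    nodes = [f"N{i:02d}" for i in range(n)]
    net = InteractionNetwork.build(
        [(nodes[a], nodes[b]) for a, b in g.edges], extra_genes=nodes
    )
    scape = Landscape(net, nodes[0], nodes[-1], L)
    # iterate in sorted order: score assignment must not depend on set
    # iteration order (PYTHONHASHSEED) or the fixture is not reproducible
    node = {x: float(rng.normal(0, 0.8)) for x in sorted(net.genes)}
    edge: dict = {x: {} for x in sorted(net.genes)}
    for a, b in sorted(tuple(sorted(e)) for e in net.edges):
        s = float(abs(rng.normal(0, 0.8)))
        edge[a][b] = s
        edge[b][a] = s
    tables = PotentialTables(
        node=node, edge=edge, locations={}, lam=0.5, temperature=1.0
    )
    return net, scape, tables


#: Seeds whose random graphs have a length-5 path space that is connected
#: under single-position Gibbs moves (verified by the connectivity check in
#: test_acceptance) and between 5 and 100 simple paths.
ORACLE_FIXTURE_SEEDS = (3, 4, 5, 6, 7, 10, 12)


def planted_family_samples(k: int):
    """``k`` pathway families: a 12-gene modal path plus 6 one-substitution
    variants each; consecutive families share exactly one hub gene.

    Within-family Jaccard >= 0.7, across-family <= 0.05.  Returns
    ``(samples, family_labels, hub_genes)``.
    """
    counts: dict = {}
    labels: dict = {}
    hubs = [f"HUB{i}" for i in range(k - 1)]
    modal_counts = [60 - 8 * f for f in range(k)]
    var_counts = (6, 5, 4, 3, 2, 2)
    for f in range(k):
        base = [f"F{f}G{j:02d}" for j in range(12)]
        if f > 0:
            base[3] = hubs[f - 1]
        if f < k - 1:
            base[8] = hubs[f]
        modal = tuple(base)
        counts[modal] = modal_counts[f]
        labels[modal] = f
        for v, pos in enumerate((0, 2, 5, 7, 10, 11)):
            var = list(base)
            var[pos] = f"F{f}X{v}"
            counts[tuple(var)] = var_counts[v]
            labels[tuple(var)] = f
    pathways = {key: Pathway(genes=key) for key in counts}
    samples = PathwaySampleSet(counts=counts, pathways=pathways, meta=SamplerMeta())
    return samples, labels, set(hubs)


@pytest.fixture
def path_graph():
    """A - B - C - D - E."""
    return InteractionNetwork.build(
        [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")]
    )


@pytest.fixture
def triangle():
    return InteractionNetwork.build([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def small_expr():
    """4 genes x 8 samples with one clearly differential gene (G2) and one
    pair of correlated genes (G0/G1)."""
    rng = np.random.default_rng(42)
    base = rng.standard_normal(8)
    values = np.vstack(
        [
            base + 0.05 * rng.standard_normal(8),
            base + 0.05 * rng.standard_normal(8),
            np.array([0.0, 0.1, -0.1, 0.05, 5.0, 5.1, 4.9, 5.05]),
            rng.standard_normal(8),
        ]
    )
    return ExpressionMatrix(
        values=values,
        gene_ids=("G0", "G1", "G2", "G3"),
        sample_ids=tuple(f"S{i}" for i in range(8)),
        group_labels=np.array([0, 0, 0, 0, 1, 1, 1, 1]),
    )
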