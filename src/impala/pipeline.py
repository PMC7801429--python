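"""End-to-end orchestration: landscape -> potentials -> forward/reverse
Gibbs chains -> pooled samples -> edge probabilities -> consensus network.

Forward and reverse searches run as independent chains; the reverse problem
swaps source and target and flips the subcellular-location order.  Reverse
samples are re-oriented before pooling, so every downstream artifact is in
source->target orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import networkx as nx
import numpy as np

from .core_model import (
    ExpressionMatrix,
    InfeasibleLandscapeError,
    InteractionNetwork,
    PathwaySampleSet,
)
from .gist import (
    EnumerationCapExceeded,
    SamplerConfig,
    consensus_network,
    enumerate_paths,
    estimate_edge_probabilities,
    flip_sample_set,
    run_chain,
)
from .landscape import Landscape, LandscapeConfig, extract_subnetwork
from .potentials import PotentialTables, build_potential_tables

logger = logging.getLogger("impala")


@dataclass
class PipelineConfig:
    landscape: LandscapeConfig
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    weights: tuple = (1.0, 1.0, 1.0)
    lambda_mode: str = "auto"


@dataclass
class PipelineResult:
    subnetwork: InteractionNetwork
    tables: PotentialTables
    forward: PathwaySampleSet
    reverse: PathwaySampleSet | None
    pooled: PathwaySampleSet  # forward-oriented union of both searches
    edge_probabilities: list
    consensus: nx.DiGraph
    skipped: list  # (source, target, length, reason)

    def predicted_genes(self) -> frozenset:
        return frozenset(self.consensus.nodes)

    def predicted_edges(self) -> dict:
        """Consensus directed edges -> pooled orientation probability."""
        return {
            (u, v): d["probability"] for u, v, d in self.consensus.edges(data=True)
        }


def _spawned_rng(seed: int | None, stream: int) -> np.random.Generator:
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def run_pipeline(
    network: InteractionNetwork,
    expr: ExpressionMatrix,
    config: PipelineConfig,
    locations: dict | None = None,
) -> PipelineResult:
    """Run the full sampler over every (source, target, length) combination.

    Each combination runs ``config.sampler.chains`` forward chains and the
    same number of reverse chains; samples are pooled across everything.
    Infeasible combinations are skipped and reported in ``result.skipped``.
    """
    lc = config.landscape
    sc = config.sampler
    seeds = set(lc.sources) | set(lc.targets)
    subnet = extract_subnetwork(network, seeds, lc.radius)
    locs = dict(network.locations)
    if locations:
        locs.update(locations)
    if not lc.location_prior:
        locs = {}
    tables = build_potential_tables(
        subnet,
        expr,
        locations=locs,
        weights=config.weights,
        temperature=sc.temperature,
        lambda_mode=config.lambda_mode,
    )
    rev_tables = tables.reversed()

    forward_sets: list = []
    reverse_sets: list = []
    skipped: list = []
    stream = 0
    for (src, tgt), length in product(
        ((s, t) for s, t in product(lc.sources, lc.targets) if s != t), lc.lengths
    ):
        for direction, s0, t0, tbl, sink in (
            ("forward", src, tgt, tables, forward_sets),
            ("reverse", tgt, src, rev_tables, reverse_sets),
        ):
            stream += 1
            try:
                scape = Landscape(subnet, s0, t0, length)
            except InfeasibleLandscapeError as exc:
                skipped.append((src, tgt, length, direction, str(exc)))
                continue
            init_paths = None
            try:
                init_paths = enumerate_paths(scape, cap=sc.init_enumeration_cap)
                if not init_paths:
                    skipped.append(
                        (src, tgt, length, direction, "no simple path of this length")
                    )
                    continue
            except EnumerationCapExceeded:
                init_paths = None
            for chain in range(sc.chains):
                rng = _spawned_rng(sc.seed, stream * 10_000 + chain)
                cc = SamplerConfig(
                    iterations=sc.iterations,
                    burn_in_fraction=sc.burn_in_fraction,
                    temperature=sc.temperature,
                    seed=sc.seed,
                    direction=direction,
                    top_k=sc.top_k,
                    chains=sc.chains,
                    init_enumeration_cap=sc.init_enumeration_cap,
                )
                init = None
                if init_paths is not None:
                    # round-robin over the enumerated path set so chains cover
                    # disconnected regions of path space
                    init = init_paths[chain % len(init_paths)]
                try:
                    sink.append(run_chain(cc, scape, tbl, rng=rng, init_path=init))
                except InfeasibleLandscapeError as exc:
                    skipped.append((src, tgt, length, direction, str(exc)))
                    break

    if not forward_sets and not reverse_sets:
        raise InfeasibleLandscapeError(
            "no feasible (source, target, length) combination; "
            f"skipped: {skipped}"
        )

    forward = PathwaySampleSet.pooled(forward_sets) if forward_sets else None
    reverse = PathwaySampleSet.pooled(reverse_sets) if reverse_sets else None
    pooled_parts = ([forward] if forward else []) + (
        [flip_sample_set(reverse, tables)] if reverse else []
    )
    pooled = PathwaySampleSet.pooled(pooled_parts)
    edge_probs = estimate_edge_probabilities(
        forward_sets, reverse_sets, forward_tables=tables
    )
    consensus = consensus_network(pooled, sc.top_k, edge_probabilities=edge_probs)
    if forward is None:
        forward = pooled
    return PipelineResult(
        subnetwork=subnet,
        tables=tables,
        forward=forward,
        reverse=reverse,
        pooled=pooled,
        edge_probabilities=edge_probs,
        consensus=consensus,
        skipped=skipped,
    )
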