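"""Candidate pathway landscape construction.

The landscape is a source/target-centred subnetwork plus, for each pathway
position ``i``, the set of genes that can legally occupy it (the per-position
domains).  A gene is admitted to position ``i`` of a length-``L`` pathway iff
it is reachable from the source in at most ``i - 1`` steps *and* from the
target in at most ``L - i`` steps; this prunes genes that cannot possibly lie
on a connected completion (it is a superset of the genes on valid simple
paths, never a subset).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .core_model import InfeasibleLandscapeError, InteractionNetwork


@dataclass
class LandscapeConfig:
    """Run-level landscape settings (serialized in the main run config)."""

    sources: tuple
    targets: tuple
    radius: int = 2
    lengths: tuple = (4, 5, 6, 7, 8)
    location_prior: bool = True

    def __post_init__(self) -> None:
        self.sources = tuple(self.sources)
        self.targets = tuple(self.targets)
        self.lengths = tuple(sorted(set(int(x) for x in self.lengths)))
        if self.radius < 0:
            raise ValueError("neighbourhood radius must be >= 0")
        if not self.sources or not self.targets:
            raise ValueError("need at least one source and one target")
        if any(x < 3 for x in self.lengths):
            raise ValueError("pathway length must be >= 3 (source, interior, target)")

    @staticmethod
    def parse_lengths(spec: str) -> tuple:
        """Parse ``"4:8"`` (inclusive range) or ``"4,6,8"``."""
        if ":" in spec:
            lo, hi = spec.split(":")
            return tuple(range(int(lo), int(hi) + 1))
        return tuple(int(x) for x in spec.split(","))


def extract_subnetwork(
    network: InteractionNetwork, seeds, k: int
) -> InteractionNetwork:
    """Induced subgraph on the union of closed ``k``-step neighbourhoods.

    Seeds are retained even when isolated.  ``k = 0`` yields the seeds alone.
    """
    seeds = set(seeds)
    missing = seeds - network.genes
    if missing:
        raise ValueError(f"seed gene(s) not in network: {sorted(missing)}")
    g = network.to_networkx()
    keep = set(seeds)
    if k > 0:
        for s in seeds:
            keep.update(nx.single_source_shortest_path_length(g, s, cutoff=k))
    return network.subgraph(keep)


def _bfs_depths(adjacency: dict, start: str, cutoff: int) -> dict:
    depths = {start: 0}
    frontier = [start]
    d = 0
    while frontier and d < cutoff:
        d += 1
        nxt = []
        for u in frontier:
            for v in adjacency[u]:
                if v not in depths:
                    depths[v] = d
                    nxt.append(v)
        frontier = nxt
    return depths


def candidate_domains(
    subnetwork: InteractionNetwork, source: str, target: str, length: int
):
    """Per-position candidate gene sets Omega_1 .. Omega_L.

    Raises :class:`InfeasibleLandscapeError` when no source->target path of
    at most ``length - 1`` edges exists, or when some interior position has
    an empty domain.
    """
    if source == target:
        raise ValueError("source and target must differ")
    for g, name in ((source, "source"), (target, "target")):
        if g not in subnetwork.genes:
            raise ValueError(f"{name} gene {g!r} not in subnetwork")
    if length < 2:
        raise ValueError("pathway length must be >= 2")
    adj = subnetwork.adjacency
    d_src = _bfs_depths(adj, source, length - 1)
    d_tgt = _bfs_depths(adj, target, length - 1)
    if target not in d_src:
        raise InfeasibleLandscapeError(
            f"no path of length <= {length} between {source!r} and {target!r}"
        )
    domains = [frozenset((source,))]
    for i in range(2, length):  # interior positions, 1-based index i
        omega = frozenset(
            g
            for g in subnetwork.genes
            if g not in (source, target)
            and d_src.get(g, length) <= i - 1
            and d_tgt.get(g, length) <= length - i
        )
        if not omega:
            raise InfeasibleLandscapeError(
                f"empty candidate domain at position {i} "
                f"({source!r}->{target!r}, L={length})"
            )
        domains.append(omega)
    domains.append(frozenset((target,)))
    return tuple(domains)


@dataclass
class Landscape:
    """A concrete sampling problem: subnetwork + domains for one (s, t, L)."""

    subnetwork: InteractionNetwork
    source: str
    target: str
    length: int
    domains: tuple = field(default=())

    def __post_init__(self) -> None:
        if not self.domains:
            self.domains = candidate_domains(
                self.subnetwork, self.source, self.target, self.length
            )
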