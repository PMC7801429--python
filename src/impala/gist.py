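"""Gibbs sampling over pathway space, edge-direction estimation, consensus
assembly, and an exact enumeration oracle for small instances.

The sampler performs systematic-scan sweeps: each sweep resamples every
interior position in order from a conditional distribution proportional to
``exp(U / T)`` restricted to candidates that keep the path connected, inside
its positional domain, and simple.  One pathway sample is recorded per
post-burn-in sweep (no thinning).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .core_model import (
    DirectedEdgeProbability,
    InfeasibleLandscapeError,
    Pathway,
    PathwaySampleSet,
    SamplerMeta,
)
from .landscape import Landscape
from .potentials import PotentialTables, _rank_map, boltzmann_distribution


@dataclass
class SamplerConfig:
    iterations: int = 10_000
    burn_in_fraction: float = 0.2
    temperature: float = 1.0
    seed: int | None = None
    direction: str = "forward"  # forward | reverse
    top_k: int = 200
    chains: int = 1
    init_enumeration_cap: int = 2_000

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn-in fraction must be in [0, 1)")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")

    @property
    def burn_in(self) -> int:
        return int(self.iterations * self.burn_in_fraction)


# ---------------------------------------------------------------------------
# Path enumeration (exact oracle + uniform initialization)
# ---------------------------------------------------------------------------


class EnumerationCapExceeded(Exception):
    """Raised when the instance is too large for the exact oracle."""


def enumerate_paths(landscape: Landscape, cap: int = 10_000) -> list:
    """All simple source->target paths of exactly the landscape length.

    Depth-first, restricted to the positional domains; deterministic order.
    Raises :class:`EnumerationCapExceeded` beyond ``cap`` paths.
    """
    adj = {g: tuple(sorted(ns)) for g, ns in landscape.subnetwork.adjacency.items()}
    domains = landscape.domains
    L = landscape.length
    out: list = []
    path = [landscape.source]
    used = {landscape.source}

    def extend(pos: int) -> None:
        if pos == L - 1:
            if landscape.target in adj[path[-1]] and landscape.target not in used:
                out.append(tuple(path) + (landscape.target,))
                if len(out) > cap:
                    raise EnumerationCapExceeded(
                        f"instance too large for exact oracle (> {cap} paths)"
                    )
            return
        dom = domains[pos]
        for g in adj[path[-1]]:
            if g in dom and g not in used:
                path.append(g)
                used.add(g)
                extend(pos + 1)
                path.pop()
                used.remove(g)

    extend(1)
    return out


def enumerate_exact(
    landscape: Landscape,
    tables: PotentialTables,
    temperature: float | None = None,
    cap: int = 10_000,
):
    """Exact Boltzmann distribution over the full path set of a landscape.

    Returns ``(pathways, probabilities, edge_probs)`` where ``edge_probs``
    maps each ordered pair to its exact orientation probability
    ``mass(i->j) / (mass(i->j) + mass(j->i))`` together with the raw
    marginal mass of the directed edge.
    """
    T = tables.temperature if temperature is None else temperature
    keys = enumerate_paths(landscape, cap=cap)
    if not keys:
        raise InfeasibleLandscapeError(
            f"no simple path of length {landscape.length} from "
            f"{landscape.source!r} to {landscape.target!r}"
        )
    pathways = [tables.score_pathway(k) for k in keys]
    probs = boltzmann_distribution(pathways, T)
    mass: dict = {}
    for pw, p in zip(pathways, probs):
        for a, b in pw.directed_edges():
            mass[(a, b)] = mass.get((a, b), 0.0) + p
    edge_probs: dict = {}
    for (a, b), m_ab in mass.items():
        m_ba = mass.get((b, a), 0.0)
        edge_probs[(a, b)] = {"probability": m_ab / (m_ab + m_ba), "mass": m_ab}
    return pathways, probs, edge_probs


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def initialize_pathway(
    landscape: Landscape,
    rng: np.random.Generator,
    enumeration_cap: int = 2_000,
    max_restarts: int = 10_000,
) -> tuple:
    """A valid simple source->target path of the required length.

    Uniform over the full path set whenever the instance is small enough to
    enumerate (below ``enumeration_cap`` paths); otherwise falls back to
    randomized depth-first search, which is valid but not exactly uniform.
    """
    try:
        paths = enumerate_paths(landscape, cap=enumeration_cap)
        if not paths:
            raise InfeasibleLandscapeError(
                f"no simple path of length {landscape.length} from "
                f"{landscape.source!r} to {landscape.target!r}"
            )
        return paths[rng.integers(len(paths))]
    except EnumerationCapExceeded:
        pass
    adj = {g: sorted(ns) for g, ns in landscape.subnetwork.adjacency.items()}
    domains = landscape.domains
    L = landscape.length
    for _ in range(max_restarts):
        path = [landscape.source]
        used = {landscape.source}
        ok = True
        for pos in range(1, L):
            cands = [g for g in adj[path[-1]] if g in domains[pos] and g not in used]
            if not cands:
                ok = False
                break
            g = cands[int(rng.integers(len(cands)))]
            path.append(g)
            used.add(g)
        if ok:
            return tuple(path)
    raise InfeasibleLandscapeError(
        f"randomized search failed to find a length-{L} path from "
        f"{landscape.source!r} to {landscape.target!r}"
    )


# ---------------------------------------------------------------------------
# Conditional sampling
# ---------------------------------------------------------------------------


def _sampler_state(landscape: Landscape, tables: PotentialTables):
    """Precompute fast lookup structures shared by all sweeps."""
    adj_sorted = {
        g: tuple(sorted(ns)) for g, ns in landscape.subnetwork.adjacency.items()
    }
    adj_set = landscape.subnetwork.adjacency
    rank_map = _rank_map(tables.reverse_flow)
    grank = {
        g: rank_map.get(tables.locations.get(g, "other"))
        for g in landscape.subnetwork.genes
    }
    w1, w2, w3 = tables.weights
    lam3 = w3 * tables.lam / (landscape.length - 1)
    return adj_sorted, adj_set, grank, w1, w2, w3, lam3


def _conditional_weights(
    path: list,
    i: int,
    used: set,
    domains,
    state,
    tables: PotentialTables,
) -> tuple:
    """Candidate genes for position ``i`` and their conditional energies."""
    adj_sorted, adj_set, grank, w1, w2, _w3, lam3 = state
    prev, cur, nxt = path[i - 1], path[i], path[i + 1]
    dom = domains[i]
    nbr_nxt = adj_set[nxt]
    node = tables.node
    edge = tables.edge
    eprev = edge[prev]
    rp, rn = grank[prev], grank[nxt]
    cands = []
    energies = []
    for g in adj_sorted[prev]:
        if g in nbr_nxt and g in dom and (g == cur or g not in used):
            rg = grank[g]
            flow = (rg is None or rp is None or rg >= rp) + (
                rn is None or rg is None or rn >= rg
            )
            cands.append(g)
            energies.append(w1 * node[g] + w2 * (eprev[g] + edge[g][nxt]) + lam3 * flow)
    return cands, energies


def conditional_sample_position(
    pathway: tuple,
    i: int,
    landscape: Landscape,
    tables: PotentialTables,
    rng: np.random.Generator,
) -> tuple:
    """Resample interior position ``i`` (0-based) of ``pathway``.

    The candidate set always contains the current gene, so it is never empty.
    """
    if not 0 < i < len(pathway) - 1:
        raise ValueError("can only resample interior positions")
    state = _sampler_state(landscape, tables)
    path = list(pathway)
    used = set(path)
    cands, energies = _conditional_weights(
        path, i, used, landscape.domains, state, tables
    )
    path[i] = _draw(cands, energies, tables.temperature, rng)
    return tuple(path)


def _draw(cands: list, energies: list, T: float, rng: np.random.Generator) -> str:
    if len(cands) == 1:
        return cands[0]
    mx = max(energies)
    weights = [math.exp((e - mx) / T) for e in energies]
    u = rng.random() * sum(weights)
    acc = 0.0
    for g, w in zip(cands, weights):
        acc += w
        if u <= acc:
            return g
    return cands[-1]


# ---------------------------------------------------------------------------
# The chain
# ---------------------------------------------------------------------------


def run_chain(
    config: SamplerConfig,
    landscape: Landscape,
    tables: PotentialTables,
    rng: np.random.Generator | None = None,
    init_path: tuple | None = None,
    return_sequence: bool = False,
):
    """Run one systematic-scan Gibbs chain and return the pooled samples.

    Each of ``config.iterations`` sweeps updates every interior position in
    order; one sample is recorded per post-burn-in sweep.  Bitwise
    reproducible given the config seed.  With ``return_sequence`` the raw
    post-burn-in sweep sequence is returned alongside the sample set (used
    for convergence diagnostics).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    T = config.temperature
    L = landscape.length
    domains = landscape.domains
    state = _sampler_state(landscape, tables)
    adj_sorted, adj_set, grank, w1, w2, _w3, lam3 = state
    node = tables.node
    edge = tables.edge

    if init_path is None:
        init_path = initialize_pathway(
            landscape, rng, enumeration_cap=config.init_enumeration_cap
        )
    path = list(init_path)
    used = set(path)
    burn_in = config.burn_in
    counts: dict = {}
    sequence: list = []
    interior = range(1, L - 1)
    rng_random = rng.random
    exp = math.exp

    for sweep in range(config.iterations):
        for i in interior:
            prev, cur, nxt = path[i - 1], path[i], path[i + 1]
            dom = domains[i]
            nbr_nxt = adj_set[nxt]
            eprev = edge[prev]
            rp, rn = grank[prev], grank[nxt]
            cands = []
            energies = []
            for g in adj_sorted[prev]:
                if g in nbr_nxt and g in dom and (g == cur or g not in used):
                    rg = grank[g]
                    flow = (rg is None or rp is None or rg >= rp) + (
                        rn is None or rg is None or rn >= rg
                    )
                    cands.append(g)
                    energies.append(
                        w1 * node[g] + w2 * (eprev[g] + edge[g][nxt]) + lam3 * flow
                    )
            if len(cands) > 1:
                mx = max(energies)
                weights = [exp((e - mx) / T) for e in energies]
                u = rng_random() * sum(weights)
                acc = 0.0
                chosen = cands[-1]
                for g, w in zip(cands, weights):
                    acc += w
                    if u <= acc:
                        chosen = g
                        break
            else:
                chosen = cands[0]
            if chosen != cur:
                used.remove(cur)
                used.add(chosen)
                path[i] = chosen
        if sweep >= burn_in:
            key = tuple(path)
            counts[key] = counts.get(key, 0) + 1
            if return_sequence:
                sequence.append(key)

    pathways = {k: tables.score_pathway(k) for k in counts}
    meta = SamplerMeta(
        iterations=config.iterations,
        burn_in=burn_in,
        temperature=T,
        seed=config.seed,
        direction=config.direction,
    )
    result = PathwaySampleSet(counts=counts, pathways=pathways, meta=meta)
    return (result, sequence) if return_sequence else result


# ---------------------------------------------------------------------------
# Edge-direction probabilities (Bernoulli estimates)
# ---------------------------------------------------------------------------


def _as_sets(x) -> list:
    if x is None:
        return []
    if isinstance(x, PathwaySampleSet):
        return [x]
    return list(x)


def flip_sample_set(
    samples: PathwaySampleSet, tables: PotentialTables | None = None
) -> PathwaySampleSet:
    """Re-orient a reverse-search sample set to source->target order.

    When ``tables`` is given the flipped pathways are re-scored so the flow
    potential reflects the forward location order.
    """
    counts: dict = {}
    pathways: dict = {}
    for k, c in samples.counts.items():
        rk = tuple(reversed(k))
        counts[rk] = counts.get(rk, 0) + c
        if tables is not None:
            pathways[rk] = tables.score_pathway(rk)
        else:
            p = samples.pathways[k]
            pathways[rk] = Pathway(genes=rk, v1=p.v1, v2=p.v2, v3=p.v3)
    meta = SamplerMeta(
        iterations=samples.meta.iterations,
        burn_in=samples.meta.burn_in,
        temperature=samples.meta.temperature,
        seed=samples.meta.seed,
        direction="forward",
    )
    return PathwaySampleSet(counts=counts, pathways=pathways, meta=meta)


def estimate_edge_probabilities(
    forward, reverse=None, forward_tables: PotentialTables | None = None
) -> list:
    """Bernoulli direction probabilities pooled over forward and reverse runs.

    Reverse-search pathways are re-oriented target->source before counting.
    For every unordered pair seen in any sample,
    ``p(i->j) = n(i->j) / (n(i->j) + n(j->i))``; ties give exactly 0.5 (no
    directional confidence).  Both orientations are reported.
    """
    fwd = _as_sets(forward)
    rev = [flip_sample_set(s, forward_tables) for s in _as_sets(reverse)]
    if not fwd and not rev:
        raise ValueError("empty pooled sample set")
    n: dict = {}
    for s in fwd + rev:
        for k, c in s.counts.items():
            for a, b in zip(k[:-1], k[1:]):
                n[(a, b)] = n.get((a, b), 0) + c
    if not n:
        raise ValueError("empty pooled sample set")
    out = []
    for a, b in sorted(n):
        nab = n[(a, b)]
        nba = n.get((b, a), 0)
        support = nab + nba
        out.append(
            DirectedEdgeProbability(
                source=a, target=b, probability=nab / support, support=support
            )
        )
        if nba == 0:  # emit the complementary orientation explicitly
            out.append(
                DirectedEdgeProbability(
                    source=b, target=a, probability=0.0, support=support
                )
            )
    return sorted(out, key=lambda e: (e.source, e.target))


# ---------------------------------------------------------------------------
# Consensus network
# ---------------------------------------------------------------------------


def rank_pathways(samples: PathwaySampleSet) -> list:
    """Distinct pathways ordered by count desc, energy desc, then gene order."""
    return sorted(
        samples.counts,
        key=lambda k: (-samples.counts[k], -samples.pathways[k].energy, k),
    )


def consensus_network(
    samples: PathwaySampleSet,
    top_k: int = 200,
    edge_probabilities: Iterable[DirectedEdgeProbability] | None = None,
    gene_attrs: dict | None = None,
) -> nx.DiGraph:
    """Union of the directed edges of the ``top_k`` distinct pathways.

    Nodes carry their total sampling frequency (count and fraction over the
    whole sample set); edges carry the pooled directional probability when
    supplied, else the orientation fraction within ``samples``.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    ranked = rank_pathways(samples)
    if top_k > len(ranked):
        top_k = len(ranked)
    top = ranked[:top_k]
    pmap = {}
    smap = {}
    if edge_probabilities is not None:
        for e in edge_probabilities:
            pmap[(e.source, e.target)] = e.probability
            smap[(e.source, e.target)] = e.support
    else:
        for e in estimate_edge_probabilities(samples):
            pmap[(e.source, e.target)] = e.probability
            smap[(e.source, e.target)] = e.support
    gene_freq = samples.gene_frequency()
    total = samples.total
    g = nx.DiGraph()
    nodes = sorted({x for k in top for x in k})
    for nd in nodes:
        attrs = {
            "count": gene_freq.get(nd, 0),
            "frequency": gene_freq.get(nd, 0) / total,
        }
        if gene_attrs and nd in gene_attrs:
            attrs.update(gene_attrs[nd])
        g.add_node(nd, **attrs)
    dedges = sorted({de for k in top for de in zip(k[:-1], k[1:])})
    for a, b in dedges:
        g.add_edge(
            a,
            b,
            probability=pmap.get((a, b), 1.0),
            support=smap.get((a, b), 0),
        )
    return g
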