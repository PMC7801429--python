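"""The three pathway potentials, the energy function, and the Boltzmann law.

* node potential: absolute z-score of between-group differential expression
  (Welch t statistic mapped through the two-sided normal quantile);
* edge potential: significance z of the Pearson correlation between the two
  genes across all samples (Fisher atanh transform, ``|atanh(r)| sqrt(m-3)``);
* flow potential: ``lambda`` times the fraction of consecutive transitions
  concordant with the membrane -> cytoplasm -> nucleus order ("other" matches
  anything).

Energy is the weighted sum ``U = w1 SUM V1 + w2 SUM V2 + w3 V3`` and pathway
probability follows ``P ~ exp(U / T)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_model import LOCATION_RANK, ExpressionMatrix, InteractionNetwork, Pathway

#: p-value floor for the z mapping; |r| = 1 and t = inf are capped here so all
#: score tables stay finite.
DEFAULT_CAP_P = 1e-16


def _z_from_p(p: float, cap_p: float = DEFAULT_CAP_P) -> float:
    p = max(float(p), cap_p)
    return float(stats.norm.isf(p / 2.0))


def z_cap(cap_p: float = DEFAULT_CAP_P) -> float:
    """Largest score any single potential term can take."""
    return float(stats.norm.isf(cap_p / 2.0))


def gene_potential(
    gene: str, expr: ExpressionMatrix, cap_p: float = DEFAULT_CAP_P
) -> float:
    """|z| of the between-group mean difference (Welch t -> two-sided p -> z).

    Genes absent from the expression matrix score 0 (neutral), as do genes
    with zero variance and equal means in both groups.
    """
    row = expr.row(gene)
    if row is None:
        return 0.0
    a = row[expr.group_labels == 0]
    b = row[expr.group_labels == 1]
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        return 0.0 if a.mean() == b.mean() else z_cap(cap_p)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if math.isnan(p):
        return 0.0
    return _z_from_p(p, cap_p)


def edge_potential(
    gene_a: str,
    gene_b: str,
    expr: ExpressionMatrix,
    cap_p: float = DEFAULT_CAP_P,
) -> float:
    """Fisher-z significance of Pearson correlation over all samples.

    Symmetric in its arguments; 0 when either gene is missing or constant.
    """
    m = expr.n_samples
    if m < 4:
        raise ValueError("insufficient samples for correlation z (need m >= 4)")
    xa, xb = expr.row(gene_a), expr.row(gene_b)
    if xa is None or xb is None:
        return 0.0
    if xa.std() == 0.0 or xb.std() == 0.0:
        return 0.0
    r = float(np.corrcoef(xa, xb)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return z_cap(cap_p)
    return min(abs(math.atanh(r)) * math.sqrt(m - 3), z_cap(cap_p))


def _rank_map(reverse: bool = False) -> dict:
    if not reverse:
        return dict(LOCATION_RANK)
    return {loc: 4 - rank for loc, rank in LOCATION_RANK.items()}


def concordant(loc_a: str, loc_b: str, rank: dict | None = None) -> bool:
    """True when the transition ``loc_a -> loc_b`` respects the rank order.

    Unranked labels ("other"/unknown) match anything.
    """
    rank = rank or LOCATION_RANK
    ra, rb = rank.get(loc_a), rank.get(loc_b)
    if ra is None or rb is None:
        return True
    return rb >= ra

def flow_potential(
    genes,
    locations: dict,
    lam: float = 1.0,
    reverse: bool = False,
) -> float:
    """``lam`` x (concordant consecutive transitions) / (L - 1)."""
    genes = tuple(genes)
    if len(genes) < 2:
        return 0.0
    rank = _rank_map(reverse)
    hits = sum(
        concordant(locations.get(a, "other"), locations.get(b, "other"), rank)
        for a, b in zip(genes[:-1], genes[1:])
    )
    return lam * hits / (len(genes) - 1)


@dataclass
class PotentialTables:
    """Precomputed scores over a (sub)network plus scoring parameters.

    Node and edge scores are sample-independent, so they are computed once
    per run rather than per Gibbs draw.
    """

    node: dict  # gene -> V1 score
    edge: dict  # gene -> {neighbour -> V2 score}; symmetric
    locations: dict
    lam: float = 1.0
    weights: tuple = (1.0, 1.0, 1.0)
    temperature: float = 1.0
    reverse_flow: bool = False

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        for g, s in self.node.items():
            if not math.isfinite(s):
                raise ValueError(f"non-finite node score for {g!r}")
        for a, row in self.edge.items():
            for b, s in row.items():
                if not math.isfinite(s):
                    raise ValueError(f"non-finite edge score for {a!r}-{b!r}")
                if self.edge.get(b, {}).get(a) != s:
                    raise ValueError(f"edge table asymmetric at {a!r}-{b!r}")

    def edge_score(self, a: str, b: str) -> float:
        try:
            return self.edge[a][b]
        except KeyError:
            raise ValueError(f"edge {a!r}-{b!r} not scored in tables") from None

    def node_score(self, g: str) -> float:
        try:
            return self.node[g]
        except KeyError:
            raise ValueError(f"gene {g!r} not scored in tables") from None

    def reversed(self) -> "PotentialTables":
        """Same evidence with the location order flipped (reverse search)."""
        return PotentialTables(
            node=self.node,
            edge=self.edge,
            locations=self.locations,
            lam=self.lam,
            weights=self.weights,
            temperature=self.temperature,
            reverse_flow=not self.reverse_flow,
        )

    def score_pathway(self, genes) -> Pathway:
        """Score a gene sequence into a :class:`Pathway` (v1, v2, v3 filled)."""
        genes = tuple(genes)
        w1, w2, w3 = self.weights
        v1 = w1 * sum(self.node_score(g) for g in genes)
        v2 = w2 * sum(self.edge_score(a, b) for a, b in zip(genes[:-1], genes[1:]))
        v3 = w3 * flow_potential(genes, self.locations, self.lam, self.reverse_flow)
        return Pathway(genes=genes, v1=v1, v2=v2, v3=v3)


def build_potential_tables(
    network: InteractionNetwork,
    expr: ExpressionMatrix,
    locations: dict | None = None,
    weights=(1.0, 1.0, 1.0),
    temperature: float = 1.0,
    lambda_mode: str = "auto",
    cap_p: float = DEFAULT_CAP_P,
) -> PotentialTables:
    """Score every gene and edge of ``network`` against ``expr``.

    ``lambda_mode`` is ``"auto"`` (lambda = mean of the nonzero node scores,
    keeping the flow term commensurate with the node terms) or
    ``"fixed:<value>"``.
    """
    locations = dict(locations) if locations else dict(network.locations)
    # deterministic iteration: table construction and the auto-lambda mean
    # must not depend on set iteration order
    node = {g: gene_potential(g, expr, cap_p) for g in sorted(network.genes)}
    edge: dict = {g: {} for g in sorted(network.genes)}
    for a, b in sorted(tuple(sorted(e)) for e in network.edges):
        s = edge_potential(a, b, expr, cap_p)
        edge[a][b] = s
        edge[b][a] = s
    if lambda_mode == "auto":
        nonzero = [s for s in node.values() if s > 0]
        lam = float(np.mean(nonzero)) if nonzero else 1.0
    elif lambda_mode.startswith("fixed:"):
        lam = float(lambda_mode.split(":", 1)[1])
    else:
        raise ValueError(f"unknown lambda_mode: {lambda_mode!r}")
    return PotentialTables(
        node=node,
        edge=edge,
        locations=locations,
        lam=lam,
        weights=tuple(float(w) for w in weights),
        temperature=float(temperature),
    )


def pathway_energy(pathway: Pathway, tables: PotentialTables) -> float:
    """Recompute ``U`` for a pathway from the tables (w1 SUM V1 + w2 SUM V2 + w3 V3)."""
    return tables.score_pathway(pathway.genes).energy


def boltzmann_distribution(energies, temperature: float) -> np.ndarray:
    """Normalized ``exp(U / T)`` over an enumerated set (max-shifted softmax).

    Exact only when the enumeration is exhaustive; the partition function is
    taken over the supplied list.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    u = np.asarray([e.energy if isinstance(e, Pathway) else e for e in energies], dtype=float)
    if u.size == 0:
        raise ValueError("empty pathway list")
    s = u / temperature
    s -= s.max()
    w = np.exp(s)
    return w / w.sum()
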