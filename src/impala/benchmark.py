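"""Synthetic benchmark: planted-pathway network simulation, expression
simulation, and precision/recall scoring of gene and edge identification.

Type I scenarios plant alternative pathways between a single source and a
single target; type II plants pathways among multiple sources and targets
that share intermediate genes (crosstalk).  Decoy ("false") interactions are
added as a fraction of the true edge count, and expression noise is a
zero-mean Gaussian whose variance is relative to the unit-variance signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_model import ExpressionMatrix, InteractionNetwork
from .gist import SamplerConfig
from .landscape import LandscapeConfig
from .pipeline import PipelineConfig, PipelineResult, run_pipeline

logger = logging.getLogger("impala")


@dataclass
class SimulationScenario:
    structure: str = "I"  # "I" or "II"
    n_paths: int = 5
    length_range: tuple = (5, 7)
    n_decoy_genes: int = 20
    false_fraction: float = 0.0  # phi
    noise_variance: float = 0.0  # sigma^2, relative to unit signal variance
    samples_per_group: int = 20
    effect_size: float = 1.0
    seed: int = 0
    n_sources: int = 2  # type II only
    n_targets: int = 2  # type II only
    interior_pool: int | None = None  # shared interior gene pool size
    decay: float = 0.8  # signal propagation decay along a path

    def __post_init__(self) -> None:
        if self.structure not in ("I", "II"):
            raise ValueError("structure must be 'I' or 'II'")
        if not 0.0 <= self.false_fraction <= 1.0:
            raise ValueError("false-interaction fraction must be in [0, 1]")
        if self.noise_variance < 0:
            raise ValueError("noise variance must be >= 0")
        if self.n_paths < 1:
            raise ValueError("need at least one true pathway")
        lo, hi = self.length_range
        if lo < 3 or hi < lo:
            raise ValueError("length range must satisfy 3 <= lo <= hi")


@dataclass
class GroundTruth:
    paths: tuple  # gene tuples, source -> target
    sources: tuple
    targets: tuple

    @property
    def genes(self) -> frozenset:
        return frozenset(g for p in self.paths for g in p)

    @property
    def directed_edges(self) -> frozenset:
        return frozenset(de for p in self.paths for de in zip(p[:-1], p[1:]))

    @property
    def undirected_edges(self) -> frozenset:
        return frozenset(frozenset(de) for de in self.directed_edges)

    def to_dict(self) -> dict:
        return {
            "paths": [list(p) for p in self.paths],
            "sources": list(self.sources),
            "targets": list(self.targets),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            paths=tuple(tuple(p) for p in d["paths"]),
            sources=tuple(d["sources"]),
            targets=tuple(d["targets"]),
        )


def _rng(scenario: SimulationScenario, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=scenario.seed, spawn_key=(stream,))
    )


def paper_scale_scenario(structure: str = "I", **overrides) -> SimulationScenario:
    """A scenario at the reference benchmark scale (~260 genes, ~1000
    interactions once decoy edges are added): many planted alternative paths
    threading a shared interior gene pool.
    """
    defaults = dict(
        structure=structure,
        n_paths=170,
        length_range=(5, 7),
        interior_pool=250,
        n_decoy_genes=60,
        samples_per_group=10,
        effect_size=0.6,
        decay=0.9,
    )
    defaults.update(overrides)
    return SimulationScenario(**defaults)


# ---------------------------------------------------------------------------
# Network simulation
# ---------------------------------------------------------------------------


def simulate_network(scenario: SimulationScenario):
    """Plant true directed pathways, strip direction, add decoy edges.

    Locations are assigned monotonically along true paths (source = membrane,
    interior = cytoplasm, target = nucleus); decoy genes get random labels.
    Returns ``(InteractionNetwork, GroundTruth)``.
    """
    rng = _rng(scenario, 0)
    lo, hi = scenario.length_range
    if scenario.structure == "I":
        sources = ("SRC",)
        targets = ("TGT",)
    else:
        sources = tuple(f"SRC{i + 1}" for i in range(scenario.n_sources))
        targets = tuple(f"TGT{i + 1}" for i in range(scenario.n_targets))

    pool = None
    if scenario.interior_pool is not None:
        pool = [f"G{i:04d}" for i in range(scenario.interior_pool)]
    elif scenario.structure == "II":
        # shared pool sized to force gene sharing between pathways
        per_path = max(hi - 2, 1)
        pool = [f"G{i:04d}" for i in range(max(per_path * scenario.n_paths // 2, per_path + 1))]

    paths = []
    fresh = 0
    for p in range(scenario.n_paths):
        length = int(rng.integers(lo, hi + 1))
        n_interior = length - 2
        src = sources[p % len(sources)]
        tgt = targets[p % len(targets)]
        if pool is not None:
            interior = list(rng.choice(pool, size=n_interior, replace=False))
        else:
            interior = [f"G{fresh + i:04d}" for i in range(n_interior)]
            fresh += n_interior
        paths.append((src, *interior, tgt))

    if scenario.structure == "II":
        shared = set()
        for i, a in enumerate(paths):
            for b in paths[i + 1 :]:
                shared |= set(a[1:-1]) & set(b[1:-1])
        if not shared and len(paths) >= 2:
            # force at least one crosstalk gene
            donor = paths[0][1]
            b = list(paths[1])
            if donor not in b:
                b[1] = donor
                paths[1] = tuple(b)

    truth = GroundTruth(paths=tuple(paths), sources=sources, targets=targets)
    true_undirected = truth.undirected_edges

    decoy_genes = [f"D{i:04d}" for i in range(scenario.n_decoy_genes)]
    all_genes = sorted(truth.genes) + decoy_genes
    n_decoy_edges = round(scenario.false_fraction * len(true_undirected))
    n_possible = len(all_genes) * (len(all_genes) - 1) // 2 - len(true_undirected)
    if n_decoy_edges > n_possible:
        raise ValueError(
            f"requested {n_decoy_edges} decoy edges but only {n_possible} non-edges exist"
        )
    edges = set(true_undirected)
    while len(edges) < len(true_undirected) + n_decoy_edges:
        i, j = rng.integers(len(all_genes)), rng.integers(len(all_genes))
        if i == j:
            continue
        e = frozenset((all_genes[i], all_genes[j]))
        if e not in edges:
            edges.add(e)

    locations = {}
    for path in truth.paths:
        locations[path[0]] = "membrane"
        locations[path[-1]] = "nucleus"
        for g in path[1:-1]:
            locations.setdefault(g, "cytoplasm")
    for g in decoy_genes:
        locations[g] = ("membrane", "cytoplasm", "nucleus")[int(rng.integers(3))]

    net = InteractionNetwork(
        genes=frozenset(all_genes),
        edges=frozenset(edges),
        locations=locations,
    )
    return net, truth


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------


def simulate_expression(
    network: InteractionNetwork,
    truth: GroundTruth,
    scenario: SimulationScenario,
) -> ExpressionMatrix:
    """Latent-signal expression with planted differential shifts.

    A unit-variance latent signal is propagated along each true path
    (child = decay * parent + innovation), inducing positive correlation on
    true edges.  True-pathway genes are centered within each condition group
    and group 1 is shifted by exactly +/- effect size per gene, so in the
    noiseless limit the group mean difference magnitude equals the effect
    size.  Decoy genes carry independent noise only.  Gaussian noise with
    variance ``noise_variance`` is then added everywhere.
    """
    if scenario.samples_per_group < 4:
        raise ValueError("need >= 4 samples per group for correlation z-scores")
    rng = _rng(scenario, 1)
    spg = scenario.samples_per_group
    m = 2 * spg
    genes = sorted(network.genes)
    gi = {g: i for i, g in enumerate(genes)}
    values = np.zeros((len(genes), m))
    decay = scenario.decay
    innov_scale = float(np.sqrt(max(1.0 - decay**2, 0.0)))

    signal: dict = {}
    for path in truth.paths:
        for pos, g in enumerate(path):
            if pos == 0:
                parent = signal.setdefault(g, rng.standard_normal(m))
            else:
                child = decay * parent + innov_scale * rng.standard_normal(m)
                parent = signal.setdefault(g, child)

    labels = np.array([0] * spg + [1] * spg)
    signs = {g: (1.0 if rng.random() < 0.5 else -1.0) for g in sorted(truth.genes)}
    for g in genes:
        if g in signal:
            row = signal[g].copy()
            row[labels == 0] -= row[labels == 0].mean()
            row[labels == 1] -= row[labels == 1].mean()
            row[labels == 1] += signs[g] * scenario.effect_size
            values[gi[g]] = row
        else:
            values[gi[g]] = rng.standard_normal(m)
    if scenario.noise_variance > 0:
        values += rng.normal(0.0, np.sqrt(scenario.noise_variance), values.shape)

    return ExpressionMatrix(
        values=values,
        gene_ids=tuple(genes),
        sample_ids=tuple(f"S{j + 1:03d}" for j in range(m)),
        group_labels=labels,
    )


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvalResult:
    precision: float
    recall: float
    f1: float
    undefined_precision: bool = False


def _prf(tp: int, n_pred: int, n_true: int) -> EvalResult:
    undefined = n_pred == 0
    precision = 0.0 if undefined else tp / n_pred
    recall = tp / n_true if n_true else 0.0
    f1 = (
        0.0
        if precision + recall == 0
        else 2 * precision * recall / (precision + recall)
    )
    return EvalResult(precision, recall, f1, undefined)


def evaluate_genes(predicted, truth: GroundTruth) -> EvalResult:
    pred = set(predicted)
    true = set(truth.genes)
    return _prf(len(pred & true), len(pred), len(true))


def evaluate_edges(predicted, truth: GroundTruth, threshold: float = 0.6) -> EvalResult:
    """Score directed-edge calls at an orientation-probability threshold.

    ``predicted`` maps ordered pairs to probabilities (or is an iterable of
    :class:`DirectedEdgeProbability`).  An edge counts as called when its
    probability passes the threshold; a call on the correct pair but wrong
    orientation is a false positive (and the true orientation stays missed).
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    if not isinstance(predicted, dict):
        predicted = {(e.source, e.target): e.probability for e in predicted}
    calls = {pair for pair, p in predicted.items() if p >= threshold}
    true = set(truth.directed_edges)
    return _prf(len(calls & true), len(calls), len(true))


# ---------------------------------------------------------------------------
# End-to-end benchmark
# ---------------------------------------------------------------------------


def run_gist_on_scenario(
    scenario: SimulationScenario,
    iterations: int = 400,
    chains: int = 2,
    temperature: float = 1.0,
    top_k: int = 200,
    extra_lengths: int = 0,
) -> tuple:
    """Simulate a scenario and run the full sampler on it.

    Returns ``(result, truth)``.  The sampler is told the true source/target
    genes and the planted length range (optionally widened by
    ``extra_lengths`` on each side).
    """
    net, truth = simulate_network(scenario)
    expr = simulate_expression(net, truth, scenario)
    lo, hi = scenario.length_range
    lengths = tuple(range(max(3, lo - extra_lengths), hi + extra_lengths + 1))
    config = PipelineConfig(
        landscape=LandscapeConfig(
            sources=truth.sources,
            targets=truth.targets,
            radius=max(lengths) - 1,
            lengths=lengths,
        ),
        sampler=SamplerConfig(
            iterations=iterations,
            temperature=temperature,
            seed=scenario.seed,
            chains=chains,
            top_k=top_k,
        ),
    )
    result = run_pipeline(net, expr, config, locations=net.locations)
    return result, truth


def score_result(
    result: PipelineResult, truth: GroundTruth, threshold: float = 0.6
) -> dict:
    """Score a pipeline run against planted truth.

    Gene identification uses every gene with nonzero sampling frequency (the
    gene-level output of the sampler is its marginal sampling frequency);
    edge identification uses every directed edge called at probability >=
    ``threshold`` over the pooled forward/reverse samples.
    """
    gene_eval = evaluate_genes(result.pooled.gene_frequency(), truth)
    edge_eval = evaluate_edges(result.edge_probabilities, truth, threshold)
    return {
        "gene_precision": gene_eval.precision,
        "gene_recall": gene_eval.recall,
        "gene_f1": gene_eval.f1,
        "edge_precision": edge_eval.precision,
        "edge_recall": edge_eval.recall,
        "edge_f1": edge_eval.f1,
    }


def run_benchmark(
    base: SimulationScenario,
    noise_levels=(0.2, 0.5, 0.8),
    false_fractions=(0.1, 0.3, 0.5),
    seeds=(0, 1, 2, 3, 4),
    threshold: float = 0.6,
    iterations: int = 400,
    chains: int = 2,
    temperature: float = 1.0,
) -> pd.DataFrame:
    """Grid evaluation over noise x false-interaction levels x seeds.

    Returns a tidy table with one row per grid cell; cell failures are
    recorded (error column) and the run continues.
    """
    rows = []
    for sigma2 in noise_levels:
        for phi in false_fractions:
            for seed in seeds:
                scenario = replace(
                    base,
                    noise_variance=float(sigma2),
                    false_fraction=float(phi),
                    seed=int(seed),
                )
                row = {
                    "structure": scenario.structure,
                    "sigma2": float(sigma2),
                    "phi": float(phi),
                    "seed": int(seed),
                }
                try:
                    result, truth = run_gist_on_scenario(
                        scenario,
                        iterations=iterations,
                        chains=chains,
                        temperature=temperature,
                    )
                    row.update(score_result(result, truth, threshold))
                    row["error"] = ""
                except Exception as exc:  # cell failure must not kill the grid
                    logger.warning("benchmark cell failed: %s", exc)
                    row["error"] = str(exc)
                rows.append(row)
    return pd.DataFrame(rows)


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of every metric per (sigma2, phi) cell."""
    metrics = [c for c in table.columns if c.endswith(("precision", "recall", "f1"))]
    ok = table[table["error"] == ""] if "error" in table else table
    return ok.groupby(["sigma2", "phi"])[metrics].agg(["mean", "std"])
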