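"""Domain types and file readers/writers shared by all pipeline stages.

Gene identifiers are opaque case-sensitive strings.  Subcellular locations
are restricted to the vocabulary ``{membrane, cytoplasm, nucleus, other}``;
genes with unknown location are treated as ``other``.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("impala")

LOCATION_VOCAB = ("membrane", "cytoplasm", "nucleus", "other")

#: Monotone order used by the flow potential.  "other" carries no rank and
#: matches any neighbour.
LOCATION_RANK = {"membrane": 1, "cytoplasm": 2, "nucleus": 3}


class ImpalaError(Exception):
    """Base class for all package errors."""


class ParseError(ImpalaError):
    """Malformed input file."""


class InfeasibleLandscapeError(ImpalaError):
    """No valid source->target path exists under the given constraints."""


# ---------------------------------------------------------------------------
# InteractionNetwork
# ---------------------------------------------------------------------------


@dataclass
class InteractionNetwork:
    """Undirected gene interaction graph.

    Parameters
    ----------
    genes
        Full gene domain (may include isolated genes).
    edges
        Unordered gene pairs, each stored once as a ``frozenset`` of size 2.
    locations
        Optional per-gene subcellular location label.
    """

    genes: frozenset
    edges: frozenset
    locations: dict = field(default_factory=dict)
    _adjacency: dict | None = field(default=None, repr=False, compare=False)

    @classmethod
    def build(
        cls,
        edge_pairs: Iterable[tuple],
        extra_genes: Iterable[str] = (),
        locations: Mapping[str, str] | None = None,
    ) -> "InteractionNetwork":
        """Construct a network, dropping self-loops and duplicate edges.

        Dropped counts are logged rather than raised: public interaction
        exports routinely contain both.
        """
        edges = set()
        genes = set(extra_genes)
        self_loops = 0
        duplicates = 0
        for a, b in edge_pairs:
            genes.add(a)
            genes.add(b)
            if a == b:
                self_loops += 1
                continue
            e = frozenset((a, b))
            if e in edges:
                duplicates += 1
            else:
                edges.add(e)
        if self_loops:
            logger.info("dropped %d self-loop(s)", self_loops)
        if duplicates:
            logger.info("collapsed %d duplicate edge(s)", duplicates)
        locs = dict(locations) if locations else {}
        for g, loc in locs.items():
            if loc not in LOCATION_VOCAB:
                raise ValueError(f"unknown location label {loc!r} for gene {g!r}")
        return cls(genes=frozenset(genes), edges=frozenset(edges), locations=locs)

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-loop or malformed edge: {set(e)}")
            if not e <= self.genes:
                raise ValueError(f"edge endpoint outside gene set: {set(e)}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def adjacency(self) -> dict:
        """Gene -> frozenset of neighbours (computed once, cached)."""
        if self._adjacency is None:
            adj: dict = {g: set() for g in self.genes}
            for e in self.edges:
                a, b = tuple(e)
                adj[a].add(b)
                adj[b].add(a)
            self._adjacency = {g: frozenset(ns) for g, ns in adj.items()}
        return self._adjacency

    def has_edge(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges

    def location(self, gene: str) -> str:
        return self.locations.get(gene, "other")

    def subgraph(self, nodes: Iterable[str]) -> "InteractionNetwork":
        keep = frozenset(nodes)
        missing = keep - self.genes
        if missing:
            raise ValueError(f"genes not in network: {sorted(missing)}")
        edges = frozenset(e for e in self.edges if e <= keep)
        locs = {g: self.locations[g] for g in keep if g in self.locations}
        return InteractionNetwork(genes=keep, edges=edges, locations=locs)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.genes))
        g.add_edges_from(sorted(tuple(sorted(e)) for e in self.edges))
        return g


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a binary condition labelling."""

    values: np.ndarray
    gene_ids: tuple
    sample_ids: tuple
    group_labels: np.ndarray  # 0/1 per sample
    _index: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.group_labels = np.asarray(self.group_labels, dtype=int)
        n, m = self.values.shape
        if len(self.gene_ids) != n:
            raise ValueError("gene_ids length does not match matrix rows")
        if len(self.sample_ids) != m or len(self.group_labels) != m:
            raise ValueError("sample annotation length does not match columns")
        dupes = pd.Index(self.gene_ids)[pd.Index(self.gene_ids).duplicated()]
        if len(dupes):
            raise ValueError(f"duplicated gene row(s): {sorted(set(dupes))}")
        if set(np.unique(self.group_labels)) - {0, 1}:
            raise ValueError("group labels must be binary (0/1)")
        sizes = np.bincount(self.group_labels, minlength=2)
        if sizes[0] < 2 or sizes[1] < 2:
            raise ValueError(
                f"each condition group needs >= 2 samples, got sizes {tuple(sizes)}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def gene_index(self) -> dict:
        if self._index is None:
            self._index = {g: i for i, g in enumerate(self.gene_ids)}
        return self._index

    def row(self, gene: str) -> np.ndarray | None:
        i = self.gene_index.get(gene)
        return None if i is None else self.values[i]

    def group_columns(self, label: int) -> np.ndarray:
        return self.values[:, self.group_labels == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


# ---------------------------------------------------------------------------
# Pathway
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Pathway:
    """An ordered simple path of genes with its three potential components.

    The total energy is the exact sum of the components by construction.
    """

    genes: tuple
    v1: float = 0.0
    v2: float = 0.0
    v3: float = 0.0

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"pathway revisits a gene: {self.genes}")
        if len(self.genes) < 2:
            raise ValueError("pathway needs at least a source and a target")

    @property
    def energy(self) -> float:
        return self.v1 + self.v2 + self.v3

    @property
    def length(self) -> int:
        return len(self.genes)

    def directed_edges(self) -> tuple:
        return tuple(zip(self.genes[:-1], self.genes[1:]))

    def validate_against(self, network: InteractionNetwork) -> None:
        adj = network.adjacency
        for a, b in self.directed_edges():
            if b not in adj.get(a, ()):  # pragma: no cover - defensive
                raise ValueError(f"pathway uses non-edge {a}-{b}")


# ---------------------------------------------------------------------------
# PathwaySampleSet
# ---------------------------------------------------------------------------


@dataclass
class SamplerMeta:
    iterations: int = 0
    burn_in: int = 0
    temperature: float = 1.0
    seed: int | None = None
    direction: str = "forward"  # forward | reverse | pooled


@dataclass
class PathwaySampleSet:
    """Pooled Gibbs samples: distinct pathways with integer counts."""

    counts: dict  # gene tuple -> int
    pathways: dict  # gene tuple -> Pathway
    meta: SamplerMeta = field(default_factory=SamplerMeta)

    def __post_init__(self) -> None:
        if set(self.counts) != set(self.pathways):
            raise ValueError("counts and pathways must share keys")
        for k, c in self.counts.items():
            if c <= 0:
                raise ValueError(f"non-positive count for {k}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    def frequency(self, genes: tuple) -> float:
        return self.counts.get(tuple(genes), 0) / self.total

    def gene_frequency(self) -> dict:
        """Gene -> number of samples whose pathway contains the gene."""
        freq: dict = {}
        for key, c in self.counts.items():
            for g in key:
                freq[g] = freq.get(g, 0) + c
        return freq

    @classmethod
    def pooled(cls, sets: Sequence["PathwaySampleSet"]) -> "PathwaySampleSet":
        if not sets:
            raise ValueError("nothing to pool")
        counts: dict = {}
        pathways: dict = {}
        for s in sets:
            for k, c in s.counts.items():
                counts[k] = counts.get(k, 0) + c
                pathways.setdefault(k, s.pathways[k])
        meta = SamplerMeta(
            iterations=sum(s.meta.iterations for s in sets),
            burn_in=sum(s.meta.burn_in for s in sets),
            temperature=sets[0].meta.temperature,
            seed=sets[0].meta.seed,
            direction="pooled",
        )
        return cls(counts=counts, pathways=pathways, meta=meta)

    def to_dict(self) -> dict:
        return {
            "meta": {
                "iterations": self.meta.iterations,
                "burn_in": self.meta.burn_in,
                "temperature": self.meta.temperature,
                "seed": self.meta.seed,
                "direction": self.meta.direction,
            },
            "samples": [
                {
                    "genes": list(k),
                    "count": self.counts[k],
                    "v1": self.pathways[k].v1,
                    "v2": self.pathways[k].v2,
                    "v3": self.pathways[k].v3,
                }
                for k in sorted(self.counts)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PathwaySampleSet":
        counts: dict = {}
        pathways: dict = {}
        for rec in d["samples"]:
            k = tuple(rec["genes"])
            counts[k] = int(rec["count"])
            pathways[k] = Pathway(genes=k, v1=rec["v1"], v2=rec["v2"], v3=rec["v3"])
        m = d.get("meta", {})
        meta = SamplerMeta(
            iterations=m.get("iterations", 0),
            burn_in=m.get("burn_in", 0),
            temperature=m.get("temperature", 1.0),
            seed=m.get("seed"),
            direction=m.get("direction", "forward"),
        )
        return cls(counts=counts, pathways=pathways, meta=meta)


@dataclass(frozen=True)
class DirectedEdgeProbability:
    """Bernoulli estimate that signal flows ``source -> target``."""

    source: str
    target: str
    probability: float
    support: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability outside [0, 1]")
        if self.support < 0:
            raise ValueError("negative support")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _infer_network_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    p = str(path).lower()
    return "sif" if p.endswith(".sif") else "tsv"


def read_network(path, fmt: str | None = None) -> InteractionNetwork:
    """Read an undirected network from SIF (``a rel b``) or 2-column TSV.

    Self-loops and duplicate edges are dropped with a logged count; any other
    malformed row raises :class:`ParseError` naming the line number.
    """
    fmt = _infer_network_format(path, fmt)
    if fmt not in ("sif", "tsv"):
        raise ValueError(f"unsupported network format: {fmt}")
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if fmt == "sif":
                if len(fields) == 3:
                    a, _, b = fields
                elif len(fields) == 2:  # tolerate relation-less rows
                    a, b = fields
                else:
                    raise ParseError(f"{path}:{lineno}: expected 2-3 fields, got {len(fields)}")
            else:
                if len(fields) < 2:
                    raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
                a, b = fields[0], fields[1]
            if not a or not b:
                raise ParseError(f"{path}:{lineno}: empty gene identifier")
            pairs.append((a, b))
    net = InteractionNetwork.build(pairs)
    if net.n_genes == 0:
        raise ParseError(f"{path}: empty network")
    return net


def read_expression(path, labels: Mapping[str, int]) -> ExpressionMatrix:
    """Read a genes x samples TSV (header = sample IDs) and attach groups.

    ``labels`` maps sample ID to 0/1.  Labels naming unknown samples and
    non-numeric cells are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    unknown = set(labels) - set(df.columns)
    if unknown:
        raise ValueError(f"labels reference unknown sample(s): {sorted(unknown)}")
    missing = set(df.columns) - set(labels)
    if missing:
        raise ValueError(f"samples without a group label: {sorted(missing)}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].to_numpy()):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-numeric value {raw!r} at gene {df.index[i]!r}, "
                    f"sample {col!r}"
                ) from None
    return ExpressionMatrix(
        values=values,
        gene_ids=tuple(df.index),
        sample_ids=tuple(df.columns),
        group_labels=np.array([int(labels[s]) for s in df.columns]),
    )


def read_labels(path) -> dict:
    """Read a 2-column TSV ``sample<TAB>group`` into a sample -> 0/1 map."""
    out: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'sample<TAB>group'")
            sample, grp = fields
            if sample == "sample" and grp == "group":  # optional header
                continue
            if grp not in ("0", "1"):
                raise ParseError(f"{path}:{lineno}: group must be 0 or 1, got {grp!r}")
            out[sample] = int(grp)
    return out


def read_locations(path) -> dict:
    """Read a 2-column TSV ``gene<TAB>location``; vocabulary is enforced."""
    out: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'gene<TAB>location'")
            gene, loc = fields
            if loc not in LOCATION_VOCAB:
                raise ParseError(
                    f"{path}:{lineno}: unknown location {loc!r} "
                    f"(expected one of {LOCATION_VOCAB})"
                )
            out[gene] = loc
    return out


def read_gene_list(path) -> list:
    """One-gene-per-line text, or GMT (genes from column 3 on, all rows)."""
    genes: list = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if "\t" in line:
                fields = line.split("\t")
                items = fields[2:] if len(fields) >= 3 else fields[:1]
            else:
                items = [line.strip()]
            for g in items:
                if g and g not in seen:
                    seen.add(g)
                    genes.append(g)
    return genes


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", float_format="%.17g")


def write_labels(labels: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for s in labels:
            fh.write(f"{s}\t{labels[s]}\n")


def write_locations(locations: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(locations):
            fh.write(f"{g}\t{locations[g]}\n")


def write_network(net: InteractionNetwork, path, fmt: str = "sif") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            if fmt == "sif":
                fh.write(f"{a}\tpp\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def write_directed_network(
    edges: Iterable[DirectedEdgeProbability],
    path,
    fmt: str = "tsv",
    gene_attrs: Mapping[str, Mapping[str, float]] | None = None,
) -> None:
    """Serialize directed edges with probabilities.

    ``gene_attrs`` maps gene -> {attribute: value} (e.g. sampling frequency,
    log2 fold change); attributes are embedded in GraphML only, since SIF/TSV
    are edge lists.
    """
    edges = sorted(edges, key=lambda e: (e.source, e.target))
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tprobability\tsupport\n")
            for e in edges:
                fh.write(f"{e.source}\t{e.target}\t{e.probability:.17g}\t{e.support}\n")
    elif fmt == "sif":
        with open(path, "w") as fh:
            for e in edges:
                fh.write(f"{e.source}\tdir\t{e.target}\n")
    elif fmt == "graphml":
        g = nx.DiGraph()
        nodes = sorted({e.source for e in edges} | {e.target for e in edges})
        if gene_attrs:
            nodes = sorted(set(nodes) | set(gene_attrs))
        for n in nodes:
            attrs = dict(gene_attrs.get(n, {})) if gene_attrs else {}
            g.add_node(n, **attrs)
        for e in edges:
            g.add_edge(e.source, e.target, probability=e.probability, support=e.support)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unsupported directed-network format: {fmt}")


def read_directed_network(path, fmt: str = "tsv") -> list:
    """Inverse of :func:`write_directed_network` for tsv/graphml."""
    if fmt == "tsv":
        out = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("source"):
                raise ParseError(f"{path}: missing header row")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 4:
                    raise ParseError(f"{path}:{lineno}: expected 4 fields")
                out.append(
                    DirectedEdgeProbability(
                        source=fields[0],
                        target=fields[1],
                        probability=float(fields[2]),
                        support=int(fields[3]),
                    )
                )
        return out
    if fmt == "graphml":
        g = nx.read_graphml(path)
        return [
            DirectedEdgeProbability(
                source=u,
                target=v,
                probability=float(d["probability"]),
                support=int(d["support"]),
            )
            for u, v, d in g.edges(data=True)
        ]
    raise ValueError(f"unsupported directed-network format: {fmt}")


def write_sample_set(samples: PathwaySampleSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(samples.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_sample_set(path) -> PathwaySampleSet:
    with open(path) as fh:
        return PathwaySampleSet.from_dict(json.load(fh))
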