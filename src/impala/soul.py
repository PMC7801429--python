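"""Pathway-module detection from pooled Gibbs samples.

Distinct sampled pathways are clustered hierarchically on gene-set Jaccard
similarity, the sampling-frequency landscape is re-ordered by dendrogram
leaf order, modules are called at prominent local peaks of the smoothed
landscape, and genes shared between modules are reported as crosstalk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.signal import find_peaks
from scipy.spatial.distance import squareform

from .core_model import Pathway, PathwaySampleSet

logger = logging.getLogger("impala")


def pathway_similarity(a: Pathway | tuple, b: Pathway | tuple) -> float:
    """Jaccard index of the two pathways' gene sets (order-insensitive)."""
    sa = set(a.genes if isinstance(a, Pathway) else a)
    sb = set(b.genes if isinstance(b, Pathway) else b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


@dataclass
class PathwayClustering:
    """Hierarchical clustering of distinct pathways.

    ``pathways`` are held in canonical (lexicographic) order so the result is
    invariant to the order pathways were sampled in.
    """

    pathways: tuple  # gene tuples, canonical order
    similarity: np.ndarray  # square, symmetric, diag 1
    linkage: np.ndarray  # scipy merge history
    leaf_order: tuple  # indices into pathways

    def __post_init__(self) -> None:
        s = self.similarity
        if s.shape[0] != s.shape[1] or not np.allclose(s, s.T):
            raise ValueError("similarity matrix must be square and symmetric")
        if not np.allclose(np.diag(s), 1.0):
            raise ValueError("similarity diagonal must be 1")
        if s.min() < -1e-12 or s.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")

    def assignments(self, n_clusters: int) -> np.ndarray:
        if len(self.pathways) == 1:
            return np.array([1])
        return hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")

    def assignments_at_height(self, height: float) -> np.ndarray:
        if len(self.pathways) == 1:
            return np.array([1])
        return hierarchy.fcluster(self.linkage, t=height, criterion="distance")


def cluster_pathways(
    samples: PathwaySampleSet, linkage_method: str = "average"
) -> PathwayClustering:
    """Agglomerative clustering on 1 - Jaccard distance over distinct pathways."""
    if linkage_method not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    keys = tuple(sorted(samples.counts))
    n = len(keys)
    if n == 0:
        raise ValueError("no pathways to cluster")
    sets = [frozenset(k) for k in keys]
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = len(sets[i] & sets[j]) / len(sets[i] | sets[j])
            sim[i, j] = sim[j, i] = s
    if n == 1:
        return PathwayClustering(
            pathways=keys,
            similarity=sim,
            linkage=np.empty((0, 4)),
            leaf_order=(0,),
        )
    z = hierarchy.linkage(squareform(1.0 - sim, checks=False), method=linkage_method)
    leaves = tuple(int(i) for i in hierarchy.leaves_list(z))
    return PathwayClustering(pathways=keys, similarity=sim, linkage=z, leaf_order=leaves)


def reorder_frequency_landscape(
    clustering: PathwayClustering, samples: PathwaySampleSet
) -> list:
    """(pathway, count) pairs arranged by dendrogram leaf order."""
    missing = set(samples.counts) - set(clustering.pathways)
    if missing:
        raise ValueError("clustering does not cover all sampled pathways")
    return [
        (clustering.pathways[i], samples.counts[clustering.pathways[i]])
        for i in clustering.leaf_order
    ]


@dataclass
class Module:
    index: int
    pathways: tuple  # gene tuples
    counts: tuple  # aligned with pathways
    peak_position: int  # index into the reordered landscape
    mass: int  # aggregate sampling frequency

    @property
    def genes(self) -> frozenset:
        return frozenset(g for k in self.pathways for g in k)

    @property
    def directed_edges(self) -> frozenset:
        return frozenset(de for k in self.pathways for de in zip(k[:-1], k[1:]))


@dataclass
class ModuleSet:
    modules: tuple
    crosstalk: dict = field(default_factory=dict)  # gene -> sorted module indices

    def __post_init__(self) -> None:
        for m in self.modules:
            if not m.pathways:
                raise ValueError("empty module")
        membership: dict = {}
        for m in self.modules:
            for g in m.genes:
                membership.setdefault(g, set()).add(m.index)
        self.crosstalk = {
            g: tuple(sorted(ms)) for g, ms in sorted(membership.items()) if len(ms) >= 2
        }

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def shared_gene_counts(self) -> dict:
        """Module-pair -> number of shared genes."""
        out: dict = {}
        mods = self.modules
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                shared = mods[i].genes & mods[j].genes
                if shared:
                    out[(mods[i].index, mods[j].index)] = len(shared)
        return out

    def shared_genes(self, i: int, j: int) -> frozenset:
        by_index = {m.index: m for m in self.modules}
        return by_index[i].genes & by_index[j].genes


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the boundaries."""
    if window <= 1 or len(x) == 1:
        return x.astype(float)
    half = window // 2
    out = np.empty(len(x), dtype=float)
    for i in range(len(x)):
        lo = max(0, i - half)
        hi = min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def detect_modules(
    ordered_landscape: list,
    min_prominence: float = 0.1,
    smoothing_window: int = 5,
) -> ModuleSet:
    """Call modules at prominent local peaks of the reordered landscape.

    Frequencies are smoothed with a centered moving average; local maxima
    with prominence >= ``min_prominence`` x max raw frequency seed modules,
    and module boundaries are drawn at the minima between consecutive peaks.
    When no peak passes the threshold a single module covering everything is
    returned.
    """
    if not ordered_landscape:
        raise ValueError("empty landscape")
    keys = [k for k, _ in ordered_landscape]
    counts = np.array([c for _, c in ordered_landscape], dtype=float)
    smoothed = _smooth(counts, smoothing_window)
    threshold = min_prominence * counts.max()
    # zero-pad so boundary peaks are eligible (frequency is zero outside the
    # landscape), then refine each smoothed peak to the raw local maximum in
    # its neighbourhood: smoothing displaces peak positions by up to half a
    # window.
    padded = np.concatenate(([0.0], smoothed, [0.0]))
    raw_peaks, _props = find_peaks(padded, prominence=threshold)
    half = max(smoothing_window // 2, 1)
    peaks = []
    for p in raw_peaks - 1:
        lo = max(0, p - half)
        hi = min(len(counts), p + half + 1)
        refined = lo + int(np.argmax(counts[lo:hi]))
        if refined not in peaks:
            peaks.append(refined)
    peaks = np.array(sorted(peaks), dtype=int)
    if len(peaks) == 0:
        logger.info("no prominent peak; returning a single module")
        module = Module(
            index=0,
            pathways=tuple(keys),
            counts=tuple(int(c) for c in counts),
            peak_position=int(np.argmax(smoothed)),
            mass=int(counts.sum()),
        )
        return ModuleSet(modules=(module,))
    bounds = [0]
    for a, b in zip(peaks[:-1], peaks[1:]):
        # cut just after the deepest raw valley between consecutive peaks
        bounds.append(a + 1 + int(np.argmin(counts[a + 1 : b])) + 1)
    bounds.append(len(keys))
    modules = []
    for idx, (lo, hi, pk) in enumerate(zip(bounds[:-1], bounds[1:], peaks)):
        modules.append(
            Module(
                index=idx,
                pathways=tuple(keys[lo:hi]),
                counts=tuple(int(c) for c in counts[lo:hi]),
                peak_position=int(pk),
                mass=int(counts[lo:hi].sum()),
            )
        )
    return ModuleSet(modules=tuple(modules))


def crosstalk(modules: ModuleSet):
    """Gene -> modules table (genes in >= 2 modules) and pairwise shared counts."""
    return modules.crosstalk, modules.shared_gene_counts()


def run_soul(
    samples: PathwaySampleSet,
    linkage_method: str = "average",
    min_prominence: float = 0.1,
    smoothing_window: int = 5,
):
    """Full pipeline: cluster, reorder, detect modules, extract crosstalk."""
    clustering = cluster_pathways(samples, linkage_method)
    landscape = reorder_frequency_landscape(clustering, samples)
    modules = detect_modules(landscape, min_prominence, smoothing_window)
    return clustering, landscape, modules
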