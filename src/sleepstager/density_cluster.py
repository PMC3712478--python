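"""Nonparametric density-estimation clustering of epochs in PC space.

A cluster is a high-density region of the data that is connected through the
Delaunay triangulation of the points.  The method:

1. estimates the probability density at every point with a product-Gaussian
   kernel (normal-reference bandwidth per dimension, shrunk by ``h_mult``);
2. connects the points by Delaunay triangulation;
3. scans density levels downward from the maximum, counting connected
   components of the subgraph induced by points at or above each level.
   A component being born is a density peak (a new cluster core); two
   components merging is a saddle.  Cores stop growing once they merge;
4. allocates every remaining point to a cluster along the graph in
   decreasing density order.

The number of clusters is the number of peaks, chosen by the data rather
than by the user.  Large recordings are split into interleaved subsets of at
most ``max_subset`` epochs, clustered independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import cdist


class ClusteringError(Exception):
    pass


class DegenerateDimensionError(ClusteringError):
    """A score dimension has zero spread; no bandwidth can be formed."""


class PeakSaddleMismatchError(ClusteringError):
    """The density's peaks cannot all be paired with detected saddles.

    Signature of a density estimate too shaggy for the scan resolution
    (bandwidth too small): modes are born and merge away within a single
    scan step, so the peak/saddle bookkeeping cannot pair them.  Increase
    ``h_mult`` (or ``n_grid``).
    """


@dataclass
class ClusterParams:
    """Tuning constants of the clustering step.

    h_mult
        Multiplicative shrinkage of the normal-reference kernel bandwidth.
        The default 0.7 trades mode resolution against stability; the
        clustering method's own authors recommend 0.75.
    n_grid
        Number of density levels scanned between the maximum and minimum
        density when the subset holds ``max_subset`` points; proportionally
        fewer for smaller subsets.  540 at 5400 points scans every 10th
        point.
    max_subset
        Upper bound on the number of points clustered at once; larger
        datasets are split into interleaved subsets.
    jitter_seed
        Seed for the deterministic jitter applied only when the Delaunay
        triangulation encounters degenerate geometry.
    """

    h_mult: float = 0.7
    n_grid: int = 540
    max_subset: int = 5400
    jitter_seed: int = 0

    def __post_init__(self) -> None:
        if not self.h_mult > 0:
            raise ClusteringError("h_mult must be positive")
        if self.n_grid < 1:
            raise ClusteringError("n_grid must be >= 1")
        if self.max_subset < 1:
            raise ClusteringError("max_subset must be >= 1")


@dataclass
class ScanDiagnostics:
    """Bookkeeping of one density-level scan."""

    stride: int
    level_ranks: list[int]
    n_components: list[int]
    peaks: list[tuple[int, int]]          # (level rank, cluster id)
    saddles: list[tuple[int, tuple[int, ...]]]  # (level rank, merged ids)
    level_partitions: list[list[frozenset[int]]] | None = None


@dataclass
class SubsetClusterResult:
    """Clustering of one subset of points."""

    labels: np.ndarray      # (n,) int, 1..n_clusters
    core_labels: np.ndarray  # (n,) int, 1..n_clusters or 0 for non-core
    density: np.ndarray
    is_core: np.ndarray
    n_clusters: int
    diagnostics: ScanDiagnostics


@dataclass
class ClusterResult:
    """Per-epoch clustering over all subsets of a recording."""

    label: np.ndarray        # within-subset cluster id per clean epoch
    density: np.ndarray
    is_core: np.ndarray
    subset_id: np.ndarray    # 1-based subset index per clean epoch
    n_clusters_per_subset: list[int]
    diagnostics: list[ScanDiagnostics] = field(default_factory=list)


# ---------------------------------------------------------------------------
# chunking
# ---------------------------------------------------------------------------

def chunk_indices(m: int, max_subset: int = 5400) -> list[np.ndarray]:
    """Split ``0..m-1`` into k interleaved subsets, k = ceil(m / max_subset).

    Subset i (0-based) holds indices ``{i, i+k, i+2k, ...}``; the subsets
    partition the index set and each one samples the whole recording
    uniformly in time.
    """
    if m < 1:
        raise ClusteringError("need at least one point to chunk")
    k = math.ceil(m / max_subset)
    return [np.arange(i, m, k) for i in range(k)]


# ---------------------------------------------------------------------------
# density estimation
# ---------------------------------------------------------------------------

def bandwidths(scores: np.ndarray, h_mult: float = 0.7) -> np.ndarray:
    """Per-dimension kernel bandwidths, normal-reference rule times h_mult.

    h_j = h_mult * sigma_j * (4 / ((d + 2) n)) ** (1 / (d + 4))
    """
    scores = np.asarray(scores, dtype=float)
    n, d = scores.shape
    if n < 2:
        raise ClusteringError("need at least 2 points to estimate bandwidths")
    if not h_mult > 0:
        raise ClusteringError("h_mult must be positive")
    sigma = scores.std(axis=0, ddof=1)
    if np.any(sigma == 0):
        bad = np.flatnonzero(sigma == 0).tolist()
        raise DegenerateDimensionError(f"zero spread in score dimension(s) {bad}")
    return h_mult * sigma * (4.0 / ((d + 2) * n)) ** (1.0 / (d + 4))


def estimate_density(
    scores: np.ndarray, bw: np.ndarray, chunk: int = 512
) -> np.ndarray:
    """Product-Gaussian kernel density estimate at every data point.

    Includes each point's own kernel, so all densities are strictly
    positive.  Evaluation is blocked to keep memory at O(chunk * n).
    """
    scores = np.asarray(scores, dtype=float)
    bw = np.asarray(bw, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ClusteringError("non-finite values in scores")
    if np.any(bw <= 0):
        raise ClusteringError("bandwidths must be positive")
    n, d = scores.shape
    u = scores / bw
    const = 1.0 / (n * np.prod(bw) * (2.0 * np.pi) ** (d / 2.0))
    out = np.empty(n)
    for start in range(0, n, chunk):
        block = u[start : start + chunk]
        sq = cdist(block, u, metric="sqeuclidean")
        out[start : start + chunk] = np.exp(-0.5 * sq).sum(axis=1)
    return out * const


# ---------------------------------------------------------------------------
# Delaunay connectivity
# ---------------------------------------------------------------------------

@dataclass
class Graph:
    """Undirected adjacency from a Delaunay triangulation (CSR layout)."""

    n: int
    indptr: np.ndarray
    indices: np.ndarray
    edges: np.ndarray  # (n_edges, 2), a < b

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i] : self.indptr[i + 1]]


def delaunay_graph(scores: np.ndarray, jitter_seed: int = 0) -> Graph:
    """Delaunay adjacency: edge (a, b) iff a, b share at least one simplex.

    Degenerate geometry (e.g. cospherical points) is retried up to three
    times with a deterministic jitter of 1e-9 times the per-dimension spread.
    """
    scores = np.asarray(scores, dtype=float)
    n, d = scores.shape
    if n < d + 1:
        raise ClusteringError(f"need at least {d + 1} points in {d}-D, have {n}")
    rng = np.random.default_rng(jitter_seed)
    pts = scores
    tri = None
    for attempt in range(4):
        try:
            tri = Delaunay(pts)
            break
        except QhullError:
            scale = scores.std(axis=0)
            scale[scale == 0] = 1.0
            pts = scores + rng.normal(scale=1e-9 * scale, size=scores.shape)
    if tri is None:
        raise ClusteringError("Delaunay triangulation failed after jitter retries")

    simplices = tri.simplices
    k = simplices.shape[1]
    pairs = []
    for a in range(k):
        for b in range(a + 1, k):
            pairs.append(simplices[:, [a, b]])
    edges = np.vstack(pairs)
    edges.sort(axis=1)
    edges = np.unique(edges, axis=0)

    both = np.concatenate([edges, edges[:, ::-1]])
    order = np.lexsort((both[:, 1], both[:, 0]))
    both = both[order]
    counts = np.bincount(both[:, 0], minlength=n)
    indptr = np.concatenate([[0], np.cumsum(counts)])
    return Graph(n=n, indptr=indptr, indices=both[:, 1].copy(), edges=edges)


# ---------------------------------------------------------------------------
# level-set scan
# ---------------------------------------------------------------------------

class _UnionFind:
    __slots__ = ("parent", "size")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, x: int) -> int:
        parent = self.parent
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb] or (
            self.size[ra] == self.size[rb] and rb < ra
        ):
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def density_order(density: np.ndarray) -> np.ndarray:
    """Point indices by decreasing density, ties broken by lower index."""
    density = np.asarray(density, dtype=float)
    return np.argsort(-density, kind="stable")


def scan_level_ranks(n: int, n_grid: int) -> tuple[int, list[int]]:
    """Density ranks (0-based, from the maximum) evaluated during the scan.

    The scan visits every ``stride``-th point from the maximum with
    stride = max(1, floor(n / n_grid)); the minimum-density point is always
    included as the final level so every point is placed.
    """
    stride = max(1, n // n_grid)
    ranks = list(range(stride - 1, n, stride))
    if ranks[-1] != n - 1:
        ranks.append(n - 1)
    return stride, ranks


def detect_cores(
    density: np.ndarray,
    graph: Graph,
    n_grid: int,
    record_levels: bool = False,
) -> tuple[np.ndarray, int, ScanDiagnostics]:
    """Find cluster cores by scanning density levels from the maximum down.

    At each scanned level the subgraph induced by the points at or above the
    level is examined: a newborn connected component is a peak and opens a
    new cluster core; a merge of two previously seen components is a saddle,
    and the cores involved are frozen (points that join a merged region
    afterwards stay unlabeled, to be allocated later).

    Returns ``(core_labels, n_clusters, diagnostics)`` where ``core_labels``
    holds 1-based cluster ids and 0 for non-core points.  Raises
    :class:`PeakSaddleMismatchError` when the peak and saddle counts are
    inconsistent at the end of the scan, which happens when three or more
    peaks merge within a single scan step: one saddle is then observed where
    at least two exist, the failure mode of a density too shaggy for the
    scan resolution.
    """
    density = np.asarray(density, dtype=float)
    n = graph.n
    if len(density) != n:
        raise ClusteringError("density and graph size mismatch")
    if n_grid > n:
        raise ClusteringError("n_grid cannot exceed the number of points")
    order = density_order(density)
    stride, level_ranks = scan_level_ranks(n, n_grid)

    uf = _UnionFind(n)
    added = np.zeros(n, dtype=bool)
    core_labels = np.zeros(n, dtype=int)
    comp_of: dict[int, int] = {}   # uf root -> component id at last level
    alive: dict[int, bool] = {}
    next_id = 1
    peaks: list[tuple[int, int]] = []
    saddles: list[tuple[int, tuple[int, ...]]] = []
    n_components_log: list[int] = []
    partitions: list[list[frozenset[int]]] | None = [] if record_levels else None

    find = uf.find
    prev_rank = -1
    for rank in level_ranks:
        gap = [order[rr] for rr in range(prev_rank + 1, rank + 1)]
        for p in gap:
            added[p] = True
            for q in graph.neighbors(p):
                if added[q]:
                    uf.union(p, q)
        # regroup the previous level's components under the current roots
        inherited: dict[int, set[int]] = {}
        for old_root, cid in comp_of.items():
            inherited.setdefault(find(old_root), set()).add(cid)
        new_comp: dict[int, int] = {}
        for root, cids_set in inherited.items():
            cids = sorted(cids_set)
            if len(cids) == 1:
                new_comp[root] = cids[0]
            else:
                saddles.append((rank, tuple(cids)))
                for c in cids:
                    alive[c] = False
                new_comp[root] = cids[0]
        # components made only of newly added points are births (in density
        # order of their top point, for deterministic ids)
        for p in gap:
            root = find(p)
            if root not in new_comp:
                cid = next_id
                next_id += 1
                alive[cid] = True
                new_comp[root] = cid
                peaks.append((rank, cid))
        comp_of = new_comp
        # newly visible points accrete into their component's core while alive
        for p in gap:
            cid = comp_of[find(p)]
            if alive[cid]:
                core_labels[p] = cid
        n_components_log.append(len(comp_of))
        if partitions is not None:
            members: dict[int, list[int]] = {}
            for rr in range(0, rank + 1):
                q = order[rr]
                members.setdefault(find(q), []).append(q)
            partitions.append([frozenset(v) for v in members.values()])
        prev_rank = rank

    n_peaks = len(peaks)
    n_saddles = len(saddles)
    diagnostics = ScanDiagnostics(
        stride=stride,
        level_ranks=level_ranks,
        n_components=n_components_log,
        peaks=peaks,
        saddles=saddles,
        level_partitions=partitions,
    )
    if n_peaks != n_saddles + 1:
        raise PeakSaddleMismatchError(
            f"found {n_peaks} density peaks but {n_saddles} saddles; the "
            "density estimate is too shaggy for the scan to pair them — "
            "increase h_mult (or n_grid)"
        )
    return core_labels, n_peaks, diagnostics


def allocate_remaining(
    core_labels: np.ndarray,
    density: np.ndarray,
    graph: Graph,
    scores: np.ndarray,
) -> np.ndarray:
    """Assign every non-core point to a cluster, in decreasing density order.

    Each unlabeled point takes the label of its highest-density labeled
    Delaunay neighbor (ties by lower index); points with no labeled neighbor
    are deferred to a second pass, and any still-isolated point is assigned
    by nearest labeled point in Euclidean distance.
    """
    labels = np.asarray(core_labels, dtype=int).copy()
    if not np.any(labels > 0):
        raise ClusteringError("no cluster cores to allocate from")
    density = np.asarray(density, dtype=float)
    order = density_order(density)

    def try_assign(p: int) -> bool:
        best = -1
        for q in graph.neighbors(p):
            if labels[q] > 0 and (
                best < 0
                or density[q] > density[best]
                or (density[q] == density[best] and q < best)
            ):
                best = q
        if best >= 0:
            labels[p] = labels[best]
            return True
        return False

    pending = [p for p in order if labels[p] == 0 and not try_assign(p)]
    still = [p for p in pending if not try_assign(p)]
    if still:
        labeled = np.flatnonzero(labels > 0)
        for p in still:
            dists = np.linalg.norm(scores[labeled] - scores[p], axis=1)
            labels[p] = labels[labeled[np.argmin(dists)]]
    return labels


def cluster_subset(
    scores: np.ndarray,
    params: ClusterParams | None = None,
    record_levels: bool = False,
) -> SubsetClusterResult:
    """Cluster one subset: bandwidths, KDE, Delaunay graph, core scan,
    allocation.  ``n_grid`` is scaled down proportionally for subsets smaller
    than ``max_subset`` so the scan stride stays comparable.

    If the scan cannot pair peaks with saddles at the configured grid, it is
    retried once at full resolution (``n_grid = n``), the setting with the
    maximal core-detection capability; a mismatch there is conclusive and
    propagates.
    """
    params = params or ClusterParams()
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if n < scores.shape[1] + 2:
        raise ClusteringError(
            f"subset of {n} points is too small to triangulate in "
            f"{scores.shape[1]}-D"
        )
    if n >= params.max_subset:
        n_grid = min(params.n_grid, n)
    else:
        n_grid = min(n, max(1, round(n * params.n_grid / params.max_subset)))
    bw = bandwidths(scores, params.h_mult)
    density = estimate_density(scores, bw)
    graph = delaunay_graph(scores, jitter_seed=params.jitter_seed)
    try:
        core_labels, n_clusters, diagnostics = detect_cores(
            density, graph, n_grid, record_levels=record_levels
        )
    except PeakSaddleMismatchError:
        if n_grid >= n:
            raise
        core_labels, n_clusters, diagnostics = detect_cores(
            density, graph, n, record_levels=record_levels
        )
    labels = allocate_remaining(core_labels, density, graph, scores)
    # compress cluster ids to 1..n_clusters in birth order
    born = [cid for _, cid in diagnostics.peaks]
    remap = {cid: i + 1 for i, cid in enumerate(born)}
    labels = np.array([remap[c] for c in labels])
    core = np.array([remap.get(c, 0) for c in core_labels])
    return SubsetClusterResult(
        labels=labels,
        core_labels=core,
        density=density,
        is_core=core > 0,
        n_clusters=n_clusters,
        diagnostics=diagnostics,
    )


def cluster_scores(
    scores: np.ndarray,
    params: ClusterParams | None = None,
) -> ClusterResult:
    """Cluster all clean epochs: interleaved chunking, one independent
    clustering per subset."""
    params = params or ClusterParams()
    scores = np.asarray(scores, dtype=float)
    m = scores.shape[0]
    subsets = chunk_indices(m, params.max_subset)
    label = np.zeros(m, dtype=int)
    density = np.zeros(m)
    is_core = np.zeros(m, dtype=bool)
    subset_id = np.zeros(m, dtype=int)
    n_clusters_per_subset = []
    diags = []
    for i, idx in enumerate(subsets):
        res = cluster_subset(scores[idx], params)
        label[idx] = res.labels
        density[idx] = res.density
        is_core[idx] = res.is_core
        subset_id[idx] = i + 1
        n_clusters_per_subset.append(res.n_clusters)
        diags.append(res.diagnostics)
    return ClusterResult(
        label=label,
        density=density,
        is_core=is_core,
        subset_id=subset_id,
        n_clusters_per_subset=n_clusters_per_subset,
        diagnostics=diags,
    )
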