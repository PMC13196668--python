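"""Join-count spatial autocorrelation and kernel density maps.

Cell types live on a symmetric k-nearest-neighbour graph over cell
positions (k = 7 by default, the smallest k leaving no unattached cells
in these organs).  For every unordered pair of types, the join count is
the number of graph edges whose endpoints carry that pair; significance
comes from a sampled permutation null (labels shuffled over the fixed
graph, 9999 permutations, add-one pseudo p-values).  Zone occupancy maps
are 2D Gaussian kernel density estimates over the normalized unit disk.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class WeightsGraph:
    """Symmetric binary KNN adjacency: undirected edge list over n nodes."""

    n: int
    edges: tuple[tuple[int, int], ...]  # sorted (u, v), u < v
    k: int

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError("self-edge in weights graph")
            if not (0 <= u < v < self.n):
                raise ValueError("edge endpoint out of range or unsorted")

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class JoinCountResult:
    """Observed join counts per unordered label pair, with the sampled
    permutation null (mean, SD, pseudo p) when one was run."""

    observed: dict
    n_edges: int
    null_mean: dict = field(default_factory=dict)
    null_sd: dict = field(default_factory=dict)
    pseudo_p: dict = field(default_factory=dict)
    n_permutations: int = 0
    seed: int | None = None
    alternative: str = "greater"


def knn_graph(points, k: int = 7) -> WeightsGraph:
    """Symmetric KNN graph: edge if either point is among the other's k
    nearest (union symmetrization), Euclidean distance, ties by index."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n <= k:
        raise ValueError(f"need more than k={k} points (minimum n = {k + 1})")
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k + 1)  # first hit is the point itself
    edges = set()
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j != i:
                edges.add((min(i, j), max(i, j)))
    return WeightsGraph(n=n, edges=tuple(sorted(edges)), k=k)


def _pair_key(a, b) -> tuple:
    return (a, b) if str(a) <= str(b) else (b, a)


def join_counts(labels, graph: WeightsGraph) -> JoinCountResult:
    """Observed join counts: edges per unordered label pair (same-label
    pairs included).  Counts over all pairs sum to |E|."""
    lab = np.asarray(labels)
    if lab.size != graph.n:
        raise ValueError(f"{lab.size} labels for {graph.n} nodes")
    values = np.unique(lab)
    observed: dict = {
        _pair_key(values[i], values[j]): 0
        for i in range(len(values))
        for j in range(i, len(values))
    }
    for u, v in graph.edges:
        observed[_pair_key(lab[u], lab[v])] += 1
    return JoinCountResult(observed=observed, n_edges=graph.n_edges)


def permutation_null(
    labels,
    graph: WeightsGraph,
    n_perm: int = 9999,
    seed: int | None = None,
    alternative: str = "greater",
) -> JoinCountResult:
    """Sampled permutation null for join counts.

    Labels are shuffled uniformly over the fixed graph ``n_perm`` times;
    per pair, pseudo-p = (1 + #{null >= observed}) / (n_perm + 1) for
    ``alternative='greater'`` (mirrored for 'lesser').  Pairs absent from
    the observed labeling but possible under permutation are included.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "lesser"):
        raise ValueError("alternative must be 'greater' or 'lesser'")
    lab = np.asarray(labels)
    base = join_counts(lab, graph)

    values, inv = np.unique(lab, return_inverse=True)
    m = len(values)
    u = np.fromiter((e[0] for e in graph.edges), dtype=int, count=graph.n_edges)
    v = np.fromiter((e[1] for e in graph.edges), dtype=int, count=graph.n_edges)

    # encode unordered code pairs as a single bincount index
    def pair_counts(codes: np.ndarray) -> np.ndarray:
        a = codes[u]
        b = codes[v]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        return np.bincount(lo * m + hi, minlength=m * m)

    keys = [
        _pair_key(values[i], values[j])
        for i in range(m)
        for j in range(i, m)
    ]
    flat_idx = [i * m + j for i in range(m) for j in range(i, m)]

    obs_flat = pair_counts(inv)[flat_idx]
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(flat_idx)), dtype=np.int64)
    codes = inv.copy()
    for t in range(n_perm):
        rng.shuffle(codes)
        null[t] = pair_counts(codes)[flat_idx]

    if alternative == "greater":
        extreme = (null >= obs_flat).sum(axis=0)
    else:
        extreme = (null <= obs_flat).sum(axis=0)
    pseudo = (1.0 + extreme) / (n_perm + 1.0)

    return JoinCountResult(
        observed={k: int(o) for k, o in zip(keys, obs_flat)},
        n_edges=base.n_edges,
        null_mean={k: float(x) for k, x in zip(keys, null.mean(axis=0))},
        null_sd={k: float(x) for k, x in zip(keys, null.std(axis=0, ddof=1))},
        pseudo_p={k: float(x) for k, x in zip(keys, pseudo)},
        n_permutations=int(n_perm),
        seed=seed,
        alternative=alternative,
    )


@dataclass(frozen=True)
class DensityGrid:
    """Evaluated 2D KDE: grid axes, density values, bandwidth factor."""

    x: np.ndarray
    y: np.ndarray
    density: np.ndarray  # shape (len(y), len(x))
    bandwidth_factor: float

    def integral(self) -> float:
        dx = self.x[1] - self.x[0]
        dy = self.y[1] - self.y[0]
        return float(self.density.sum() * dx * dy)


def kde_map(
    theta_deg,
    r,
    grid_n: int = 100,
    bandwidth_rule: str = "scott",
    extent: float = 1.0,
) -> DensityGrid:
    """Gaussian KDE of normalized cell positions on the unit disk.

    Polar coordinates are converted to Cartesian (x, y) = (r cos(theta),
    r sin(theta)) and a 2D Gaussian KDE (Scott's or Silverman's bandwidth
    rule) is evaluated on a grid_n x grid_n grid over
    [-extent, extent]^2.
    """
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    rr = np.asarray(r, dtype=float)
    if theta.size < 2:
        raise ValueError("KDE needs at least 2 cells")
    xy = np.vstack([rr * np.cos(theta), rr * np.sin(theta)])
    if np.allclose(xy.var(axis=1), 0.0):
        raise ValueError("degenerate input: no coordinate spread")
    if bandwidth_rule not in ("scott", "silverman"):
        raise ValueError("bandwidth_rule must be 'scott' or 'silverman'")
    kde = sps.gaussian_kde(xy, bw_method=bandwidth_rule)
    ax = np.linspace(-extent, extent, grid_n)
    gx, gy = np.meshgrid(ax, ax)
    dens = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(grid_n, grid_n)
    return DensityGrid(x=ax, y=ax, density=dens, bandwidth_factor=float(kde.factor))
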