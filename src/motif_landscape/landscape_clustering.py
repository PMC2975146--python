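"""Landscape clustering of gene-motif vectors.

The procedure mirrors the behaviour of force-directed knowledge-mapping
tools: genes are scattered on a plane, an iterative annealing-like process
pulls similar genes together and pushes dissimilar genes apart until no more
movement is observed, a kernel-density "terrain" is built over the final
coordinates, and clusters are read off as density peaks with their
steepest-ascent basins.  No number of clusters is chosen in advance; the
peaks that emerge from the terrain *are* the clusters.  Peak selection —
done visually in interactive tools — is automated here by a topographic
prominence threshold.

Force model (this package's definition): attraction along similarity-graph
edges proportional to weight × distance (a linear spring), pairwise
repulsion proportional to 1/distance, per-iteration step capped by a
temperature that decays geometrically (cooling factor γ).  Initial positions
are keyed to gene ids (hashed together with the seed), so results are
invariant to input order.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .motif_profiling import ProfileMatrix, profile_distance

__all__ = [
    "LayoutParams",
    "DensityGrid",
    "LandscapeResult",
    "similarity_graph",
    "force_layout",
    "density_landscape",
    "extract_peaks",
    "cluster_genes",
    "plot_landscape",
]

UNCLUSTERED = "unclustered"

_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class LayoutParams:
    """Force-directed layout parameters.

    ``convergence_tol`` is the maximum per-iteration displacement below which
    the layout is considered quiescent; ``None`` means 1e-3 × the current
    plane diagonal.  ``repulsion_floor`` bounds the 1/d repulsion so
    coincident points (identical profiles) cannot produce unbounded forces.
    """

    k_neighbors: int = 10
    attraction_scale: float = 0.2
    repulsion_scale: float = 0.002
    cooling_factor: float = 0.97
    initial_temperature: float = 0.1
    convergence_tol: float | None = None
    max_iterations: int = 2000
    repulsion_floor: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.cooling_factor < 1.0:
            raise ValueError("cooling_factor must be in (0, 1)")
        if self.convergence_tol is not None and self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if self.initial_temperature <= 0:
            raise ValueError("initial_temperature must be > 0")


def similarity_graph(
    profiles: ProfileMatrix, metric: str = "cosine", k: int = 10
) -> nx.Graph:
    """Mutualized k-nearest-neighbour similarity graph over genes.

    An edge is kept if either endpoint lists the other among its k nearest
    profiles; weight = 1 − (distance / max pairwise distance) ∈ [0, 1].
    Neighbour selection and tie-breaking are canonicalized on
    lexicographically sorted gene ids, so the graph is independent of input
    order.
    """
    n = len(profiles.genes)
    if n < 2:
        raise ValueError("similarity_graph requires >= 2 genes")
    if k >= n:
        raise ValueError(f"k ({k}) must be < number of genes ({n})")
    order = sorted(range(n), key=lambda i: profiles.genes[i])
    ids = [profiles.genes[i] for i in order]
    X = profiles.counts[order].astype(float)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = profile_distance(X[i], X[j], metric)
            dist[i, j] = dist[j, i] = d
    dmax = dist.max()
    norm = dist / dmax if dmax > 0 else dist
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for i in range(n):
        # stable argsort on (distance, canonical index) excludes self
        nbrs = sorted((j for j in range(n) if j != i), key=lambda j: (dist[i, j], j))
        for j in nbrs[:k]:
            a, b = min(i, j), max(i, j)
            graph.add_edge(ids[a], ids[b], weight=float(1.0 - norm[a, b]))
    return graph


def _initial_position(gene: str, seed: int) -> np.ndarray:
    # position keyed to (seed, gene id): order-invariant and reproducible
    digest = hashlib.blake2b(f"{seed}:{gene}".encode(), digest_size=16).digest()
    x = int.from_bytes(digest[:8], "big") / 2**64
    y = int.from_bytes(digest[8:], "big") / 2**64
    return np.array([x, y])


def force_layout(
    graph: nx.Graph, params: LayoutParams
) -> tuple[dict[str, tuple[float, float]], int]:
    """Run the annealed force-directed layout to quiescence.

    Returns final coordinates per gene and the number of iterations used.
    Deterministic given the seed; independent of node insertion order.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    X = np.array([_initial_position(g, params.seed) for g in nodes])
    if n == 1:
        return {nodes[0]: (float(X[0, 0]), float(X[0, 1]))}, 1
    index = {g: i for i, g in enumerate(nodes)}
    W = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        W[index[a], index[b]] = W[index[b], index[a]] = data.get("weight", 1.0)
    degree = W.sum(axis=1)

    temperature = params.initial_temperature
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        diff = X[:, None, :] - X[None, :, :]  # diff[i, j] = x_i - x_j
        d = np.linalg.norm(diff, axis=2)
        np.fill_diagonal(d, np.inf)
        d = np.maximum(d, params.repulsion_floor)
        # attraction: sum_j w_ij (x_j - x_i);  repulsion: sum_j (x_i - x_j)/d^2
        attraction = params.attraction_scale * (W @ X - degree[:, None] * X)
        repulsion = params.repulsion_scale * (diff / (d**2)[:, :, None]).sum(axis=1)
        disp = attraction + repulsion
        norms = np.linalg.norm(disp, axis=1)
        over = norms > temperature
        if np.any(over):
            disp[over] *= (temperature / norms[over])[:, None]
            norms = np.minimum(norms, temperature)
        X = X + disp
        temperature *= params.cooling_factor
        span = X.max(axis=0) - X.min(axis=0)
        diagonal = max(float(np.hypot(*span)), 1e-6)
        tol = params.convergence_tol if params.convergence_tol is not None else 1e-3 * diagonal
        if float(norms.max()) < tol:
            break
    return {g: (float(X[i, 0]), float(X[i, 1])) for i, g in enumerate(nodes)}, iterations


@dataclass
class DensityGrid:
    """Gaussian kernel density over the layout plane.

    ``values[iy, ix]`` is the density at (xs[ix], ys[iy]); the grid covers
    the point bounding box padded by 3 bandwidths and integrates to the
    number of points (each kernel carries unit mass).
    """

    xs: np.ndarray
    ys: np.ndarray
    values: np.ndarray
    bandwidth: float

    @property
    def cell_area(self) -> float:
        return float((self.xs[1] - self.xs[0]) * (self.ys[1] - self.ys[0]))


def scott_bandwidth(points: np.ndarray, factor: float = 0.5) -> float:
    """Default terrain bandwidth: a Scott-style rule scaled down for modes.

    Scott's 2-D rule (n^(-1/6) × rms marginal standard deviation) targets
    unimodal densities and oversmooths a landscape whose whole point is its
    separate peaks, so the default halves it; pass an explicit bandwidth to
    override entirely.
    """
    n = len(points)
    if n < 2:
        return 0.05
    std = math.sqrt(float(points.var(axis=0).mean()))
    return max(factor * n ** (-1.0 / 6.0) * std, 1e-3)


def density_landscape(
    coords: dict[str, tuple[float, float]],
    bandwidth: float | None = None,
    grid_size: int = 96,
) -> DensityGrid:
    """Build the density terrain over the final coordinates."""
    if not coords:
        raise ValueError("no coordinates")
    pts = np.array([coords[g] for g in sorted(coords)])
    if bandwidth is None:
        bandwidth = scott_bandwidth(pts)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    pad = 3.0 * bandwidth
    x0, y0 = pts.min(axis=0) - pad
    x1, y1 = pts.max(axis=0) + pad
    xs = np.linspace(x0, x1, grid_size)
    ys = np.linspace(y0, y1, grid_size)
    gx, gy = np.meshgrid(xs, ys)  # shape (grid_size, grid_size), [iy, ix]
    values = np.zeros_like(gx)
    norm = 1.0 / (2.0 * math.pi * bandwidth**2)
    for px, py in pts:
        values += norm * np.exp(
            -((gx - px) ** 2 + (gy - py) ** 2) / (2.0 * bandwidth**2)
        )
    return DensityGrid(xs=xs, ys=ys, values=values, bandwidth=float(bandwidth))


def _local_maxima(values: np.ndarray) -> list[tuple[int, int]]:
    ny, nx = values.shape
    out = []
    for iy in range(ny):
        for ix in range(nx):
            v = values[iy, ix]
            is_max = True
            for dy, dx in _NEIGHBORS8:
                jy, jx = iy + dy, ix + dx
                if 0 <= jy < ny and 0 <= jx < nx and values[jy, jx] > v:
                    is_max = False
                    break
            if is_max:
                out.append((iy, ix))
    return out


def _peak_prominences(values: np.ndarray) -> dict[tuple[int, int], float]:
    """Topographic prominence of every local maximum, by persistence.

    Cells are processed in descending height with union-find; when a cell
    joins two components the lower peak dies with prominence equal to its
    height minus the saddle height.  The global maximum gets its own height.
    """
    ny, nx = values.shape
    order = sorted(
        ((iy, ix) for iy in range(ny) for ix in range(nx)),
        key=lambda c: (-values[c], c),
    )
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    comp_peak: dict[tuple[int, int], tuple[int, int]] = {}
    prominence: dict[tuple[int, int], float] = {}

    def find(c):
        root = c
        while parent[root] != root:
            root = parent[root]
        while parent[c] != root:
            parent[c], c = root, parent[c]
        return root

    for cell in order:
        iy, ix = cell
        neighbor_roots = []
        for dy, dx in _NEIGHBORS8:
            nb = (iy + dy, ix + dx)
            if nb in parent:
                r = find(nb)
                if r not in neighbor_roots:
                    neighbor_roots.append(r)
        parent[cell] = cell
        if not neighbor_roots:
            comp_peak[cell] = cell
            continue
        # attach to the highest neighbouring component; others die here
        neighbor_roots.sort(key=lambda r: (-values[comp_peak[r]], comp_peak[r]))
        main = neighbor_roots[0]
        parent[cell] = main
        for other in neighbor_roots[1:]:
            dead_peak = comp_peak[other]
            prominence[dead_peak] = float(values[dead_peak] - values[cell])
            parent[other] = main
    # the surviving component's peak is the global maximum
    global_peak = order[0]
    prominence[global_peak] = float(values[global_peak])
    return prominence


@dataclass
class Peak:
    peak_id: str
    cell: tuple[int, int]  # (iy, ix)
    height: float
    prominence: float


def extract_peaks(
    density: DensityGrid,
    min_prominence: float,
    coords: dict[str, tuple[float, float]],
) -> tuple[list[Peak], dict[str, str]]:
    """Prominence-thresholded peaks and steepest-ascent basin labels.

    A local maximum is a peak if its topographic prominence is at least
    ``min_prominence`` × the global maximum height.  Each gene follows a
    discrete steepest ascent from its nearest grid cell; genes whose ascent
    ends at a sub-threshold maximum are labelled "unclustered".
    """
    if not 0.0 < min_prominence < 1.0:
        raise ValueError("min_prominence must be in (0, 1)")
    values = density.values
    if values.size == 0:
        raise ValueError("empty density grid")
    prominences = _peak_prominences(values)
    threshold = min_prominence * float(values.max())
    kept = [
        (cell, prominences.get(cell, 0.0))
        for cell in _local_maxima(values)
        if prominences.get(cell, 0.0) >= threshold
    ]
    kept.sort(key=lambda t: (-values[t[0]], t[0]))
    peaks = [
        Peak(peak_id=f"P{i + 1}", cell=cell, height=float(values[cell]), prominence=prom)
        for i, (cell, prom) in enumerate(kept)
    ]
    peak_by_cell = {p.cell: p.peak_id for p in peaks}

    ny, nx = values.shape

    def ascend(iy: int, ix: int) -> tuple[int, int]:
        while True:
            best = (iy, ix)
            best_v = values[iy, ix]
            for dy, dx in _NEIGHBORS8:
                jy, jx = iy + dy, ix + dx
                if 0 <= jy < ny and 0 <= jx < nx and values[jy, jx] > best_v:
                    best, best_v = (jy, jx), values[jy, jx]
            if best == (iy, ix):
                return best
            iy, ix = best

    def plateau_peak(cell: tuple[int, int]) -> str | None:
        # search the equal-height plateau around a summit cell for a kept peak
        target = values[cell]
        seen = {cell}
        stack = [cell]
        while stack:
            cy, cx = stack.pop()
            if (cy, cx) in peak_by_cell:
                return peak_by_cell[(cy, cx)]
            for dy, dx in _NEIGHBORS8:
                nb = (cy + dy, cx + dx)
                if (
                    0 <= nb[0] < ny
                    and 0 <= nb[1] < nx
                    and nb not in seen
                    and values[nb] == target
                ):
                    seen.add(nb)
                    stack.append(nb)
        return None

    labels: dict[str, str] = {}
    for gene in sorted(coords):
        x, y = coords[gene]
        ix = int(np.clip(np.abs(density.xs - x).argmin(), 0, nx - 1))
        iy = int(np.clip(np.abs(density.ys - y).argmin(), 0, ny - 1))
        summit = ascend(iy, ix)
        labels[gene] = plateau_peak(summit) or UNCLUSTERED
    return peaks, labels


@dataclass
class LandscapeResult:
    """Full clustering output: coordinates, terrain, peaks and labels."""

    coords: dict[str, tuple[float, float]]
    density: DensityGrid
    peaks: list[Peak]
    labels: dict[str, str]
    iterations: int
    params: LayoutParams
    bandwidth: float
    min_prominence: float
    metric: str = "cosine"

    def n_clusters(self) -> int:
        return len(self.peaks)

    def members(self, peak_id: str) -> list[str]:
        return sorted(g for g, p in self.labels.items() if p == peak_id)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": {
                "k_neighbors": self.params.k_neighbors,
                "attraction_scale": self.params.attraction_scale,
                "repulsion_scale": self.params.repulsion_scale,
                "cooling_factor": self.params.cooling_factor,
                "initial_temperature": self.params.initial_temperature,
                "convergence_tol": self.params.convergence_tol,
                "max_iterations": self.params.max_iterations,
                "repulsion_floor": self.params.repulsion_floor,
                "seed": self.params.seed,
            },
            "bandwidth": self.bandwidth,
            "min_prominence": self.min_prominence,
            "metric": self.metric,
            "iterations": self.iterations,
            "coords": {g: list(xy) for g, xy in sorted(self.coords.items())},
            "peaks": [
                {
                    "id": p.peak_id,
                    "cell": list(p.cell),
                    "height": p.height,
                    "prominence": p.prominence,
                }
                for p in self.peaks
            ],
            "labels": dict(sorted(self.labels.items())),
        }
        with open(path, "w", newline="\n") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    def write_labels(self, path: str | Path) -> None:
        with open(path, "w", newline="\n") as fh:
            fh.write("gene\tpeak\n")
            for gene in sorted(self.labels):
                fh.write(f"{gene}\t{self.labels[gene]}\n")


def cluster_genes(
    profiles: ProfileMatrix,
    params: LayoutParams | None = None,
    bandwidth: float | None = None,
    min_prominence: float = 0.1,
    metric: str = "cosine",
    grid_size: int = 96,
) -> LandscapeResult:
    """Layout → terrain → peaks, end to end.

    Genes with all-zero profiles receive coordinates but are excluded from
    the terrain and labelled "unclustered" (a zero vector carries no motif
    evidence, so it must not seed or join a peak).
    """
    if params is None:
        params = LayoutParams()
    nonzero = [g for g, z in zip(profiles.genes, profiles.counts.sum(axis=1)) if z > 0]
    if len(nonzero) == 0:
        raise ValueError(
            "all gene profiles are zero; lower min_sig upstream so motifs survive"
        )
    if len(profiles.genes) < 2:
        raise ValueError("cluster_genes requires >= 2 genes")
    k = min(params.k_neighbors, len(profiles.genes) - 1)
    graph = similarity_graph(profiles, metric=metric, k=k)
    coords, iterations = force_layout(graph, params)
    nonzero_coords = {g: coords[g] for g in nonzero}
    if bandwidth is None:
        # the layout cannot bring even identical profiles closer than the
        # spring/repulsion equilibrium spacing, so the terrain must not
        # resolve structure finer than that (matters only at tiny n, where
        # the Scott-style rule collapses below the spacing)
        equilibrium = (params.repulsion_scale / max(params.attraction_scale, 1e-12)) ** (1 / 3)
        pts = np.array([nonzero_coords[g] for g in sorted(nonzero_coords)])
        bandwidth = max(scott_bandwidth(pts), equilibrium)
    density = density_landscape(nonzero_coords, bandwidth=bandwidth, grid_size=grid_size)
    peaks, labels = extract_peaks(density, min_prominence, nonzero_coords)
    for g in profiles.genes:
        if g not in labels:
            labels[g] = UNCLUSTERED
    return LandscapeResult(
        coords=coords,
        density=density,
        peaks=peaks,
        labels=labels,
        iterations=iterations,
        params=params,
        bandwidth=density.bandwidth,
        min_prominence=min_prominence,
        metric=metric,
    )


def plot_landscape(result: LandscapeResult, path: str | Path) -> None:
    """Static terrain plot with gene positions and peaks marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    d = result.density
    ax.contourf(d.xs, d.ys, d.values, levels=20, cmap="terrain")
    pts = np.array([result.coords[g] for g in sorted(result.coords)])
    ax.plot(pts[:, 0], pts[:, 1], "k.", ms=3)
    for p in result.peaks:
        iy, ix = p.cell
        ax.plot(d.xs[ix], d.ys[iy], "r^", ms=9)
        ax.annotate(p.peak_id, (d.xs[ix], d.ys[iy]), color="red", fontsize=9)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_title("motif-profile landscape")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
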