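"""Skeleton-graph shape descriptors for segmented aggregates.

Each aggregate mask is thinned to a 1-px skeleton; the skeleton is
turned into a graph whose nodes are endpoints (degree 1) and junctions
(degree >= 3, adjacent junction pixels merged into one node) and whose
edges are junction-free pixel paths. Path length follows the standard
geodesic estimate: 1 px per axial step, sqrt(2) px per diagonal step,
scaled by the pixel size. Redundant diagonal adjacencies (a diagonal
step shortcutting two axial steps through a shared neighbour) are
pruned so that length is not double counted.

From the skeleton and the intensity image the per-aggregate feature
vector used for shape classification is assembled:

f1 longest chain length (µm)           f5 branch points / f1 (1/µm)
f2 mean width along the chain (µm)     f6 intensity peaks / f1 (1/µm)
f3 f2 / f1 (dimensionless)             f7 100 * f1 / total length (%)
f4 total fluorescence intensity (a.u.)

with the total skeleton length available as an optional eighth feature
behind a flag.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy import ndimage
from skimage.feature import blob_log
from skimage.morphology import skeletonize

from aggremorph.image import Image
from aggremorph.segment import AggregateRegion

SQRT2 = math.sqrt(2.0)

# LoG blob scales default to punctum radii 0.15–0.5 µm (the puncta are
# ~0.5 µm across); the response threshold is relative to the region's
# maximum intensity.
DEFAULT_SIGMA_RANGE_UM = (0.15, 0.5)
LOG_RESPONSE_FRACTION = 0.3
# blobs whose local Hessian is strongly anisotropic are ridge points
# (fibril body, ratio < 0.1) or ridge tips (~0.25), not puncta (isolated
# ~1.0, tangent chain members ~0.5)
BLOB_CURVATURE_RATIO = 0.35

_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class SkeletonGraph:
    """Topological skeleton of one aggregate as a node/edge graph."""

    nodes: list[tuple[tuple[int, int], int]]  # (representative pixel, degree)
    edges: list[tuple[int, int, list[tuple[int, int]], float]]  # (i, j, path, µm)
    total_length: float  # µm, sum of edge path lengths
    longest_chain_length: float  # µm
    longest_chain_path: list[tuple[int, int]]
    n_branch_points: int
    ring_flag: bool
    pixel_size: float
    skeleton_pixels: np.ndarray = field(default=None, repr=False)  # type: ignore

    def __post_init__(self) -> None:
        assert self.longest_chain_length <= self.total_length + 1e-9


def _pixel_graph(pixels: set[tuple[int, int]]) -> nx.Graph:
    """8-connected pixel graph with redundant diagonals pruned.

    A diagonal edge (a, c) is dropped when some pixel b is axially
    adjacent to both a and c: the path a-b-c already covers it and the
    diagonal would double-count length.
    """
    g = nx.Graph()
    g.add_nodes_from(pixels)
    for (y, x) in pixels:
        for dy, dx in _N8:
            q = (y + dy, x + dx)
            if q in pixels and (y, x) < q:
                g.add_edge((y, x), q, weight=1.0 if dy == 0 or dx == 0 else SQRT2)
    # prune shortcut diagonals
    for (a, c) in [e for e in g.edges if g.edges[e]["weight"] > 1.0]:
        for dy, dx in ((a[0], c[1]), (c[0], a[1])):
            b = (dy, dx)
            if b in pixels and g.has_edge(a, b) and g.has_edge(b, c) \
                    and g.edges[a, b]["weight"] == 1.0 and g.edges[b, c]["weight"] == 1.0:
                g.remove_edge(a, c)
                break
    return g


def brute_force_skeleton_length(pixels: set[tuple[int, int]],
                                pixel_size: float = 1.0) -> float:
    """Independent total-length computation by exhaustive pairwise check.

    Enumerates every pixel pair, keeps pairs at unit or sqrt(2)
    distance, applies the same shortcut-diagonal pruning rule, and sums
    step lengths. O(n^2); intended for oracles on small masks.
    """
    pts = sorted(pixels)
    total = 0.0
    for i, a in enumerate(pts):
        for b in pts[i + 1:]:
            dy, dx = abs(a[0] - b[0]), abs(a[1] - b[1])
            if max(dy, dx) != 1:
                continue
            if dy + dx == 1:
                total += 1.0
            else:  # diagonal: count only if no axial two-step path exists
                c1, c2 = (a[0], b[1]), (b[0], a[1])
                if not (c1 in pixels or c2 in pixels):
                    total += SQRT2
    return total * pixel_size


def skeletonize_region(region: AggregateRegion, mask_shape: tuple[int, int],
                       pixel_size: float) -> SkeletonGraph:
    """Thin the region to a skeleton and build its topology graph."""
    if region.area == 0:
        raise ValueError("region is empty")
    mask = region.mask(mask_shape)
    skel = skeletonize(mask)
    pixels = set(map(tuple, np.argwhere(skel)))
    if not pixels:
        # a very small mask can thin away entirely; fall back to its centroid px
        cy, cx = region.centroid
        pixels = {(int(round(cy)), int(round(cx)))}
    g = _pixel_graph(pixels)
    return _graph_from_pixels(g, pixels, pixel_size)


def _graph_from_pixels(g: nx.Graph, pixels: set[tuple[int, int]],
                       pixel_size: float) -> SkeletonGraph:
    deg = dict(g.degree)
    node_pixels = {p for p, d in deg.items() if d != 2}

    # merge adjacent junction pixels (degree >= 3) into single nodes
    junction = {p for p in node_pixels if deg[p] >= 3}
    jg = g.subgraph(junction)
    cluster_of: dict[tuple[int, int], int] = {}
    nodes: list[tuple[tuple[int, int], int]] = []
    for comp in nx.connected_components(jg):
        rep = min(comp)
        idx = len(nodes)
        for p in comp:
            cluster_of[p] = idx
        nodes.append((rep, 0))
    for p in sorted(node_pixels - junction):
        cluster_of[p] = len(nodes)
        nodes.append((p, 0))

    edges: list[tuple[int, int, list[tuple[int, int]], float]] = []
    visited: set[frozenset] = set()

    def _ekey(a, b):
        return frozenset((a, b))

    # walk from each node pixel through degree-2 chains
    for p in sorted(node_pixels):
        for q in sorted(g.neighbors(p)):
            if _ekey(p, q) in visited:
                continue
            path = [p, q]
            length = g.edges[p, q]["weight"]
            visited.add(_ekey(p, q))
            prev, cur = p, q
            while cur not in node_pixels:
                nbrs = [r for r in g.neighbors(cur) if r != prev]
                if not nbrs:
                    break  # dangling (shouldn't happen on pruned graphs)
                nxt = nbrs[0]
                if _ekey(cur, nxt) in visited:
                    break
                visited.add(_ekey(cur, nxt))
                length += g.edges[cur, nxt]["weight"]
                path.append(nxt)
                prev, cur = cur, nxt
            edges.append((cluster_of[path[0]], cluster_of.get(path[-1], -1),
                          path, length * pixel_size))

    ring_flag = False
    # pure cycles with no node pixels (isolated rings)
    remaining = {frozenset(e) for e in g.edges} - visited
    if remaining:
        comp_pixels = {p for e in remaining for p in e}
        sub = g.edge_subgraph([tuple(e) for e in remaining])
        for comp in nx.connected_components(sub.to_undirected()):
            comp = set(comp)
            start = min(comp)
            cyc_len = sum(sub.edges[e]["weight"] for e in sub.subgraph(comp).edges)
            idx = len(nodes)
            nodes.append((start, 0))
            cluster_of[start] = idx
            edges.append((idx, idx, sorted(comp), cyc_len * pixel_size))
            ring_flag = True
        del comp_pixels

    if not node_pixels and not remaining and len(pixels) == 1:
        p = next(iter(pixels))
        nodes = [(p, 0)]
        cluster_of[p] = 0

    # degrees on the collapsed multigraph
    mg = nx.MultiGraph()
    mg.add_nodes_from(range(len(nodes)))
    for (i, j, path, length) in edges:
        mg.add_edge(i, j, weight=length, path=path)
    nodes = [(rep, mg.degree(i)) for i, (rep, _) in enumerate(nodes)]
    n_branch = sum(1 for _, d in nodes if d >= 3)
    total_length = sum(e[3] for e in edges)

    chain_len, chain_path, is_ring = _longest_chain(mg, nodes, edges)
    return SkeletonGraph(
        nodes=nodes,
        edges=edges,
        total_length=total_length,
        longest_chain_length=chain_len,
        longest_chain_path=chain_path,
        n_branch_points=n_branch,
        ring_flag=ring_flag or is_ring,
        pixel_size=pixel_size,
        skeleton_pixels=np.asarray(sorted(pixels)),
    )


def _longest_chain(mg: nx.MultiGraph, nodes, edges) -> tuple[float, list, bool]:
    """Maximum-length simple path between endpoint (degree-1) nodes.

    Exhaustive over endpoint pairs; forests use the unique tree path,
    cyclic graphs enumerate simple edge paths (skeleton graphs are
    small). A graph with no endpoints (pure ring) returns the longest
    cycle and flags it.
    """
    if not edges:
        return 0.0, [nodes[0][0]] if nodes else [], False
    endpoints = [i for i, (_, d) in enumerate(nodes) if d == 1]
    if not endpoints:
        # ring: report the longest cycle's circumference
        best = max(edges, key=lambda e: e[3])
        if best[0] == best[1]:
            return best[3], list(best[2]), True
        cycle = max(nx.cycle_basis(nx.Graph(mg)), key=len, default=None)
        if cycle is None:
            return best[3], list(best[2]), True
        length = 0.0
        path: list = []
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            data = min(mg.get_edge_data(a, b).values(), key=lambda d: d["weight"])
            length += data["weight"]
            path.extend(data["path"])
        return length, path, True

    best_len, best_path = -1.0, []
    forest = nx.is_forest(nx.Graph(mg)) and mg.number_of_edges() == nx.Graph(mg).number_of_edges()
    if forest:
        simple = nx.Graph()
        for (i, j, path, length) in edges:
            simple.add_edge(i, j, weight=length, path=path)
        for a in endpoints:
            dist = nx.single_source_dijkstra_path_length(simple, a, weight="weight")
            b = max((n for n in endpoints), key=lambda n: dist.get(n, -1))
            if dist.get(b, -1) > best_len:
                best_len = dist[b]
                node_path = nx.dijkstra_path(simple, a, b, weight="weight")
                best_path = list(itertools.chain.from_iterable(
                    simple.edges[u, v]["path"] for u, v in zip(node_path, node_path[1:])))
        if best_len < 0:  # single edge / isolated node fallback
            best = max(edges, key=lambda e: e[3])
            return best[3], list(best[2]), False
        return best_len, best_path, False

    for a, b in itertools.combinations(endpoints, 2):
        for epath in nx.all_simple_edge_paths(mg, a, b):
            length = sum(mg.edges[e]["weight"] for e in epath)
            if length > best_len:
                best_len = length
                best_path = list(itertools.chain.from_iterable(
                    mg.edges[e]["path"] for e in epath))
    if best_len < 0:
        best = max(edges, key=lambda e: e[3])
        return best[3], list(best[2]), False
    return best_len, best_path, False


def longest_chain(graph: SkeletonGraph) -> tuple[float, list[tuple[int, int]]]:
    """Longest chain of an already-built skeleton graph (µm, pixel path)."""
    return graph.longest_chain_length, graph.longest_chain_path


def mean_width_along_chain(region: AggregateRegion, chain_path: list[tuple[int, int]],
                           mask_shape: tuple[int, int], pixel_size: float) -> float:
    """Mean aggregate width along the longest chain.

    Width at a chain pixel is twice the Euclidean distance transform of
    the region mask minus one pixel (half-pixel convention: a 1-px line
    has width 1 px), averaged over the chain and scaled to µm.
    """
    if not chain_path:
        raise ValueError("chain path is empty")
    mask = region.mask(mask_shape)
    path = np.asarray(chain_path)
    if not mask[path[:, 0], path[:, 1]].all():
        raise ValueError("chain path leaves the region mask")
    edt = ndimage.distance_transform_edt(mask)
    widths = 2.0 * edt[path[:, 0], path[:, 1]] - 1.0
    return float(np.mean(widths)) * pixel_size


def count_intensity_peaks(img: Image, region: AggregateRegion,
                          sigma_range_um: tuple[float, float] = DEFAULT_SIGMA_RANGE_UM,
                          response_fraction: float = LOG_RESPONSE_FRACTION,
                          num_sigma: int = 8) -> int:
    """Count fluorescence puncta inside a region by multiscale LoG.

    The region's bounding box is cut out (other pixels zeroed), scaled
    to unit maximum, and searched with scale-normalised
    Laplacian-of-Gaussian blob detection over punctum radii
    ``sigma_range_um``. Blobs are kept when their response exceeds
    ``response_fraction`` of the (normalised) region maximum, their
    centre lies inside the region, and the local Hessian is
    blob-like rather than ridge-like (principal-curvature ratio
    >= BLOB_CURVATURE_RATIO with both curvatures negative) — the ridge
    test prevents the smooth body of a fibril from being counted as a
    train of puncta.
    """
    lo, hi = sigma_range_um
    if not (0 < lo < hi):
        raise ValueError("sigma_range_um must be an increasing positive pair")
    px = img.pixel_size
    min_sigma = lo / math.sqrt(2) / px
    max_sigma = hi / math.sqrt(2) / px
    pad = int(math.ceil(3 * max_sigma)) + 1
    r0, c0, r1, c1 = region.bbox
    h, w = img.shape
    rr0, cc0 = max(0, r0 - pad), max(0, c0 - pad)
    rr1, cc1 = min(h, r1 + pad), min(w, c1 + pad)
    mask = region.mask(img.shape)
    crop = np.where(mask, img.pixels, 0.0)[rr0:rr1, cc0:cc1]
    peak = crop.max()
    if peak <= 0:
        return 0
    crop = crop / peak
    # overlap pruning is disabled: tangent puncta overlap heavily and the
    # pruner would keep the merged large-scale blob instead of the pair
    blobs = blob_log(crop, min_sigma=min_sigma, max_sigma=max_sigma,
                     num_sigma=num_sigma, threshold=response_fraction,
                     overlap=1.0)
    kept: list[tuple[float, float]] = []
    for (by, bx, bs) in blobs:
        gy, gx = int(round(by)) + rr0, int(round(bx)) + cc0
        if not (0 <= gy < h and 0 <= gx < w and mask[gy, gx]):
            continue
        if not _is_bloblike(crop, by, bx, bs):
            continue
        # one punctum can surface at two adjacent scales; merge near-coincident hits
        if any((by - ky) ** 2 + (bx - kx) ** 2 < min_sigma**2 for ky, kx in kept):
            continue
        kept.append((by, bx))
    return len(kept)


def _is_bloblike(crop: np.ndarray, by: float, bx: float, sigma: float) -> bool:
    """Hessian curvature-ratio test at the detected blob centre/scale."""
    sm = ndimage.gaussian_filter(crop, sigma)
    y, x = int(round(by)), int(round(bx))
    h, w = sm.shape
    if not (1 <= y < h - 1 and 1 <= x < w - 1):
        return False
    dyy = sm[y + 1, x] - 2 * sm[y, x] + sm[y - 1, x]
    dxx = sm[y, x + 1] - 2 * sm[y, x] + sm[y, x - 1]
    dxy = (sm[y + 1, x + 1] - sm[y + 1, x - 1] - sm[y - 1, x + 1] + sm[y - 1, x - 1]) / 4
    tr = dxx + dyy
    det = dxx * dyy - dxy * dxy
    disc = max(tr * tr / 4 - det, 0.0)
    l1 = tr / 2 - math.sqrt(disc)
    l2 = tr / 2 + math.sqrt(disc)  # |l1| >= |l2| for bright blobs (both negative)
    if l1 >= 0 or l2 >= 0:
        return False
    return abs(l2) / abs(l1) >= BLOB_CURVATURE_RATIO


@dataclass
class FeatureVector:
    """Per-aggregate shape descriptor fed to PCA / k-means."""

    aggregate_id: int
    longest_chain_um: float                # f1
    mean_width_um: float                   # f2
    width_per_chain: float                 # f3 = f2 / f1
    total_intensity_au: float              # f4
    branch_points_per_um: float            # f5
    intensity_peaks_per_um: float          # f6
    chain_fraction_pct: float              # f7 = 100 * f1 / total length
    n_branch_points: int
    n_intensity_peaks: int
    total_length_um: float                 # optional f8 (off by default in PCA)
    ring_flag: bool
    edge_flag: bool

    FEATURE_COLUMNS = (
        "longest_chain_um", "mean_width_um", "width_per_chain",
        "total_intensity_au", "branch_points_per_um",
        "intensity_peaks_per_um", "chain_fraction_pct",
    )
    OPTIONAL_COLUMN = "total_length_um"


def extract_features(img: Image, region: AggregateRegion,
                     sigma_range_um: tuple[float, float] = DEFAULT_SIGMA_RANGE_UM,
                     ) -> FeatureVector:
    """Compose skeleton, width and peak measurements into the feature vector.

    The reported longest chain carries an end-cap correction: thinning
    retracts each skeleton endpoint about half a local width inside the
    object tip, so the tip-to-tip length is the skeleton chain plus the
    mean width (no correction for rings, which have no tips). The chain
    fraction f7 is the uncorrected skeleton ratio. Degenerate skeletons
    (a single pixel) are floored at one pixel of chain length so the
    per-length features stay finite.
    """
    px = img.pixel_size
    graph = skeletonize_region(region, img.shape, px)
    raw_chain = max(graph.longest_chain_length, px)
    total = max(graph.total_length, raw_chain)
    chain_path = graph.longest_chain_path or [tuple(graph.skeleton_pixels[0])]
    f2 = max(mean_width_along_chain(region, chain_path, img.shape, px), 0.0)
    f1 = raw_chain if graph.ring_flag else raw_chain + f2
    n_peaks = count_intensity_peaks(img, region, sigma_range_um)
    return FeatureVector(
        aggregate_id=region.id,
        longest_chain_um=f1,
        mean_width_um=f2,
        width_per_chain=f2 / f1,
        total_intensity_au=region.total_intensity,
        branch_points_per_um=graph.n_branch_points / f1,
        intensity_peaks_per_um=n_peaks / f1,
        chain_fraction_pct=100.0 * min(raw_chain / total, 1.0),
        n_branch_points=graph.n_branch_points,
        n_intensity_peaks=n_peaks,
        total_length_um=total,
        ring_flag=graph.ring_flag,
        edge_flag=region.edge_flag,
    )


def features_to_frame(features: list[FeatureVector]):
    """Feature table (one row per aggregate)."""
    import pandas as pd

    return pd.DataFrame([vars(f) for f in features])
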