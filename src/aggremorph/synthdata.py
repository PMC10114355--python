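"""Ground-truth-labelled synthetic scenes, kinetics traces and TEM renders.

The generator emulates the growth model inferred from time-lapse imaging
of mCherry-Nter aggregation: ~0.5-µm fluorescent puncta dock to each
other by diffusion (stick on first contact), producing linear chains
first, then branched fractal clusters as chains dock onto chains —
a 2-D diffusion-limited cluster–cluster aggregation (DLCA) process.
Fibril-shaped aggregates instead grow by polymerisation from a single
punctum and are modelled as worm-like chains tens of micrometres long,
optionally carrying a few embedded puncta.

Rendered scenes mimic the microscope: Gaussian PSF, 16-bit camera scale,
Poisson photon noise plus Gaussian read noise, and an injected
translational chromatic shift between the mCherry and ThT channels.
Aggregation kinetics are generated as logistic (sigmoidal) ThT traces
parameterised by the tangent-intercept lag time, the same convention
the kinetics estimator uses. TEM fibrils are rendered as negative-stain
ribbons whose perpendicular profile peaks at the two ribbon edges.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
from scipy import ndimage
from scipy.spatial import cKDTree

from aggremorph.image import Image

# Fractional tolerance on centre separation for two puncta to count as
# touching (avoids floating-point contact ambiguity).
TANGENCY_TOL = 0.01

CLASS_LABELS = ("linear_fractal", "branched_fractal", "fibril")


class DockingError(RuntimeError):
    """Raised when random-walk docking fails to converge within budget."""


@dataclass
class SimParams:
    """Physical and camera parameters of a simulated scene.

    Lengths are in micrometres; intensities on the 16-bit camera scale.
    ``pixel_size`` defaults to a 6.5-µm camera pixel behind a 40x
    objective (0.1625 µm/px); that calibration is a config value, not a
    measured constant.
    """

    n_puncta: int = 7
    punctum_diameter: float = 0.5
    docking_stages: int = 2
    fibril_length: float = 27.0
    fibril_width: float = 0.15
    persistence_length: float = 50.0
    embedded_puncta: int = 2
    psf_sigma: float = 0.12
    background_level: float = 20.0
    noise_read_sigma: float = 3.0
    photon_gain: float = 1.0
    punctum_photons: float = 4000.0
    fibril_photons_per_um: float = 3000.0
    chromatic_shift: tuple[float, float] = (0.0, 0.0)
    pixel_size: float = 0.1625
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_puncta < 1:
            raise ValueError("n_puncta must be >= 1")
        for name in ("punctum_diameter", "fibril_length", "fibril_width",
                     "persistence_length", "psf_sigma", "pixel_size",
                     "photon_gain"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 <= self.background_level < 65535):
            raise ValueError("background_level must lie in [0, 65535)")
        if self.noise_read_sigma < 0:
            raise ValueError("noise_read_sigma must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass
class AggregateTruth:
    """Ground truth for one simulated aggregate.

    Coordinates are (y, x) in micrometres in the scene frame.
    ``backbone_polyline`` is non-empty exactly for fibrils.
    """

    class_label: str
    punctum_centers: np.ndarray
    backbone_polyline: np.ndarray
    true_longest_chain: float
    true_branch_points: int
    true_width: float

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        self.punctum_centers = np.asarray(self.punctum_centers, dtype=float).reshape(-1, 2)
        self.backbone_polyline = np.asarray(self.backbone_polyline, dtype=float).reshape(-1, 2)
        is_fibril = self.class_label == "fibril"
        if is_fibril != (len(self.backbone_polyline) > 0):
            raise ValueError("backbone_polyline must be non-empty iff class is fibril")
        if self.class_label == "linear_fractal" and self.true_branch_points != 0:
            raise ValueError("linear_fractal aggregates have zero branch points")


@dataclass
class GroundTruth:
    aggregates: list[AggregateTruth] = field(default_factory=list)

    def labels(self) -> list[str]:
        return [a.class_label for a in self.aggregates]


# ---------------------------------------------------------------------------
# puncta adjacency bookkeeping


def adjacency_graph(centers: np.ndarray, diameter: float) -> nx.Graph:
    """Tangency adjacency graph of punctum centres.

    Two puncta are adjacent when their centre separation is at most
    ``diameter * (1 + TANGENCY_TOL)``.
    """
    centers = np.asarray(centers, dtype=float)
    g = nx.Graph()
    g.add_nodes_from(range(len(centers)))
    cutoff = diameter * (1.0 + TANGENCY_TOL)
    for i in range(len(centers)):
        d = np.hypot(*(centers[i + 1:] - centers[i]).T)
        for j in np.nonzero(d <= cutoff)[0]:
            g.add_edge(i, int(j) + i + 1)
    return g


def _chain_metrics(centers: np.ndarray, diameter: float) -> tuple[float, int]:
    """Longest chain (µm, incl. the two end caps) and branch-point count.

    Docked clusters are trees under the tangency relation, so the
    longest simple path is the weighted tree diameter (two sweeps of
    Dijkstra). Each graph edge contributes one punctum diameter; one
    extra diameter accounts for the two end-cap radii.
    """
    g = adjacency_graph(centers, diameter)
    if len(centers) == 1:
        return diameter, 0
    if not nx.is_connected(g):
        raise DockingError("cluster is not a single connected component")
    n_branch = sum(1 for _, deg in g.degree if deg >= 3)
    # weighted diameter; exact for trees, a good lower bound otherwise
    far, dist = _farthest(g, 0)
    far2, dist2 = _farthest(g, far)
    return dist2 * diameter + diameter, n_branch


def _farthest(g: nx.Graph, src: int) -> tuple[int, int]:
    lengths = nx.single_source_shortest_path_length(g, src)
    node = max(lengths, key=lambda k: (lengths[k], -k))
    return node, lengths[node]


# ---------------------------------------------------------------------------
# fractal aggregate growth


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    theta = rng.uniform(0, 2 * math.pi)
    return np.array([math.sin(theta), math.cos(theta)])


def _build_chain(n: int, diameter: float, rng: np.random.Generator,
                 wiggle_sd: float = 0.35) -> np.ndarray:
    """Linear chain of n tangent puncta.

    Consecutive bond directions wander by a Gaussian angle (sd in rad),
    rejected if a new punctum would overlap an existing one, so the
    adjacency graph is exactly a path.
    """
    centers = [np.zeros(2)]
    theta = rng.uniform(0, 2 * math.pi)
    for _ in range(n - 1):
        for _attempt in range(200):
            cand_theta = theta + rng.normal(0.0, wiggle_sd)
            cand = centers[-1] + diameter * np.array(
                [math.sin(cand_theta), math.cos(cand_theta)])
            d = np.hypot(*(np.asarray(centers[:-1]) - cand).T) if len(centers) > 1 else np.array([np.inf])
            # keep non-neighbours clearly separated so tangency stays a path
            if np.all(d > diameter * (1.0 + 2 * TANGENCY_TOL)):
                centers.append(cand)
                theta = cand_theta
                break
        else:
            raise DockingError("could not extend chain without overlap")
    return np.asarray(centers)


def _dock_cluster(fixed: np.ndarray, incoming: np.ndarray, diameter: float,
                  rng: np.random.Generator, max_steps: int = 200_000) -> np.ndarray:
    """Random-walk docking: translate ``incoming`` rigidly by an
    off-lattice 2-D random walk until first contact with ``fixed``,
    then back up along the last step to exact tangency.

    Returns the docked incoming coordinates. Raises DockingError if the
    walk exhausts its step budget.
    """
    tree = cKDTree(fixed)
    step = diameter / 4.0
    contact = diameter  # tangency target
    span = (np.ptp(fixed, axis=0).max() + np.ptp(incoming, axis=0).max()) / 2 + 2 * diameter
    launch_r = span + 3 * diameter

    def min_dist(offset: np.ndarray) -> float:
        return float(tree.query(incoming + offset)[0].min())

    center_fixed = fixed.mean(axis=0)
    offset = center_fixed + launch_r * _random_unit(rng) - incoming.mean(axis=0)
    # make sure the launch position is not already overlapping
    while min_dist(offset) < contact:
        offset = center_fixed + 1.5 * launch_r * _random_unit(rng) - incoming.mean(axis=0)

    batch = 2048
    n_in = len(incoming)
    steps_done = 0
    while steps_done < max_steps:
        thetas = rng.uniform(0, 2 * math.pi, size=batch)
        moves = step * np.column_stack([np.sin(thetas), np.cos(thetas)])
        offsets = offset + np.cumsum(moves, axis=0)
        # distance of every incoming punctum at every batch position
        pts = (incoming[None, :, :] + offsets[:, None, :]).reshape(-1, 2)
        dmin = tree.query(pts)[0].reshape(batch, n_in).min(axis=1)
        hit = np.nonzero(dmin <= contact)[0]
        if hit.size:
            k = int(hit[0])
            prev = offset if k == 0 else offsets[k - 1]
            move = offsets[k] - prev
            # bisect the final step to land at tangency within tol
            lo, hi = 0.0, 1.0  # fraction of `move`: lo=no contact, hi=contact
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if min_dist(prev + mid * move) <= contact:
                    hi = mid
                else:
                    lo = mid
                if min_dist(prev + hi * move) >= contact * (1 - TANGENCY_TOL / 2):
                    break
            return incoming + prev + hi * move
        offset = offsets[-1]
        steps_done += batch
        # re-inject walkers that wander off
        if np.linalg.norm(incoming.mean(axis=0) + offset - center_fixed) > 4 * launch_r:
            offset = center_fixed + launch_r * _random_unit(rng) - incoming.mean(axis=0)
    raise DockingError(f"docking did not converge within {max_steps} steps")


def simulate_fractal_aggregate(params: SimParams, stage: int,
                               rng: np.random.Generator | None = None) -> AggregateTruth:
    """Grow one fractal-shaped aggregate by hierarchical puncta docking.

    stage 1: single puncta dock into a linear chain.
    stage 2: chains dock onto each other (branched cluster).
    stage 3: stage-2 clusters dock onto each other (larger branched).

    Punctum count is conserved: the returned cluster holds exactly
    ``params.n_puncta`` centres forming one connected tangency cluster.
    """
    if stage not in (1, 2, 3):
        raise ValueError("stage must be 1, 2 or 3")
    if rng is None:
        rng = params.rng()
    d = params.punctum_diameter
    n = params.n_puncta

    if stage == 1:
        centers = _build_chain(n, d, rng)
    else:
        # split n puncta into sub-units appropriate for the stage
        if stage == 2:
            sizes = _split_sizes(n, lo=2, hi=3, rng=rng)
            units = [_build_chain(s, d, rng) for s in sizes]
        else:
            sizes = _split_sizes(n, lo=4, hi=7, rng=rng)
            units = []
            for s in sizes:
                sub = SimParams(**{**asdict(params), "n_puncta": s,
                                   "chromatic_shift": tuple(params.chromatic_shift)})
                units.append(simulate_fractal_aggregate(sub, stage=2, rng=rng).punctum_centers)
        cluster = units[0]
        for unit in units[1:]:
            docked = _dock_cluster(cluster, unit, d, rng)
            cluster = np.vstack([cluster, docked])
        centers = cluster

    longest, n_branch = _chain_metrics(centers, d)
    label = "linear_fractal" if n_branch == 0 else "branched_fractal"
    return AggregateTruth(
        class_label=label,
        punctum_centers=centers - centers.mean(axis=0),
        backbone_polyline=np.empty((0, 2)),
        true_longest_chain=longest,
        true_branch_points=n_branch,
        true_width=d,
    )


def _split_sizes(n: int, lo: int, hi: int, rng: np.random.Generator) -> list[int]:
    """Partition n into parts of size lo..hi (last part may be smaller)."""
    sizes: list[int] = []
    remaining = n
    while remaining > 0:
        s = min(int(rng.integers(lo, hi + 1)), remaining)
        sizes.append(max(s, 1))
        remaining -= sizes[-1]
    if len(sizes) == 1 and n > 1:
        # ensure at least two units so docking actually happens
        sizes = [n - n // 2, n // 2]
    return sizes


def grow_branched_cluster(params: SimParams, rng: np.random.Generator,
                          main_puncta: int, n_arms: int,
                          arm_lengths: tuple[int, ...] = (2, 3),
                          arm_wiggle_sd: float = 0.25) -> AggregateTruth:
    """Branched cluster: a main chain decorated with outward-growing arms.

    Each arm starts from a punctum that random-walk docks onto the
    cluster (stick on first contact, conditioned on landing at a
    punctum that already has two neighbours, so the joint becomes a
    branch point) and then grows outward from the landing site — the
    tip-polymerisation behaviour of diffusion-limited growth, where new
    material arrives from outside the cluster. Arms that cannot be
    placed without overlap within the retry budget are skipped, so the
    realised branch count can fall below ``n_arms``; the class label is
    derived from the realised topology.
    """
    d = params.punctum_diameter
    cluster = _build_chain(main_puncta, d, rng)
    for _ in range(n_arms):
        arm_len = int(rng.choice(arm_lengths))
        g = adjacency_graph(cluster, d)
        deg = dict(g.degree)
        for _attempt in range(40):
            seed_pt = _dock_cluster(cluster, np.zeros((1, 2)), d, rng)
            cid = int(np.argmin(np.hypot(*(cluster - seed_pt[0]).T)))
            if deg.get(cid, 0) < 2:
                continue
            direction = seed_pt[0] - cluster[cid]
            direction = direction / np.linalg.norm(direction)
            arm_pts = [seed_pt[0]]
            ok = True
            for _j in range(1, arm_len):
                theta = rng.normal(0.0, arm_wiggle_sd)
                rot = np.array([[math.cos(theta), -math.sin(theta)],
                                [math.sin(theta), math.cos(theta)]])
                direction = rot @ direction
                nxt = arm_pts[-1] + d * direction
                others = np.vstack([cluster, np.asarray(arm_pts[:-1]).reshape(-1, 2)])
                if np.hypot(*(others - nxt).T).min() < d * (1 + 2 * TANGENCY_TOL):
                    ok = False
                    break
                arm_pts.append(nxt)
            if ok:
                cluster = np.vstack([cluster, np.asarray(arm_pts)])
                break
    longest, n_branch = _chain_metrics(cluster, d)
    label = "branched_fractal" if n_branch > 0 else "linear_fractal"
    return AggregateTruth(
        class_label=label,
        punctum_centers=cluster - cluster.mean(axis=0),
        backbone_polyline=np.empty((0, 2)),
        true_longest_chain=longest,
        true_branch_points=n_branch,
        true_width=d,
    )


# Study-condition morphology scales: linear fractals are short chains of
# ~0.5-µm puncta (~2 puncta typical, median length ~1.4 µm); branched
# fractals have a ~3-5 µm longest chain with a handful of branch
# points; fibrils are tens of µm long (median 27, quartiles 19–50 µm,
# lognormal spread) with a couple of embedded puncta. Class mix 56 %
# linear / 32 % branched / 12 % fibril.
STUDY_CLASS_MIX = {"linear_fractal": 0.56, "branched_fractal": 0.32, "fibril": 0.12}
FIBRIL_LOG_MEDIAN = math.log(27.0)
FIBRIL_LOG_SIGMA = 0.72  # matches quartiles ~[19, 50] µm


def sample_study_aggregate(class_label: str, params: SimParams,
                           rng: np.random.Generator) -> AggregateTruth:
    """One aggregate of the requested class at the study's scales."""
    if class_label == "linear_fractal":
        n = int(rng.integers(2, 5))
        sub = SimParams(**{**asdict(params), "n_puncta": n,
                           "chromatic_shift": tuple(params.chromatic_shift)})
        return simulate_fractal_aggregate(sub, stage=1, rng=rng)
    if class_label == "branched_fractal":
        main = int(rng.integers(4, 7))
        n_arms = int(rng.integers(4, 8))
        return grow_branched_cluster(params, rng, main_puncta=main, n_arms=n_arms)
    if class_label == "fibril":
        length = float(np.clip(np.exp(rng.normal(FIBRIL_LOG_MEDIAN, FIBRIL_LOG_SIGMA)),
                               10.0, 60.0))
        sub = SimParams(**{**asdict(params), "fibril_length": length,
                           "embedded_puncta": int(rng.integers(0, 4)),
                           "chromatic_shift": tuple(params.chromatic_shift)})
        return simulate_fibril(sub, rng=rng)
    raise ValueError(f"unknown class label {class_label!r}")


def simulate_study_scene(params: SimParams, rng: np.random.Generator | None = None,
                         n_aggregates: int = 6,
                         class_mix: dict[str, float] = None,
                         ) -> tuple[GroundTruth, Image, Image, np.ndarray]:
    """One rendered scene with aggregates drawn from the study class mix.

    Returns (ground truth with labels, mCherry image, ThT image, label
    mask). Aggregate placement keeps a clear margin between objects so
    the ground-truth count is recoverable by segmentation.
    """
    if rng is None:
        rng = params.rng()
    if class_mix is None:
        class_mix = STUDY_CLASS_MIX
    labels = list(class_mix)
    probs = np.array([class_mix[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    draw = rng.choice(len(labels), size=n_aggregates, p=probs)
    truths = [sample_study_aggregate(labels[i], params, rng) for i in draw]
    scene = assemble_scene(truths, params, rng=rng)
    img_a, img_b, mask = render_scene(scene, params, rng=rng)
    return scene, img_a, img_b, mask


# ---------------------------------------------------------------------------
# fibrils


def simulate_fibril(params: SimParams, rng: np.random.Generator | None = None,
                    straight: bool = False) -> AggregateTruth:
    """Worm-like-chain fibril backbone with optional embedded puncta.

    The backbone is a tangent-angle random walk: heading increments are
    i.i.d. Gaussian with variance ds / persistence_length per arc step
    ds, giving the stated persistence length. ``straight=True`` is the
    infinite-stiffness limit. Total arc length equals
    ``params.fibril_length`` by construction (piecewise-linear chords).
    """
    if rng is None:
        rng = params.rng()
    if params.fibril_length < params.pixel_size:
        raise ValueError("fibril_length must be at least one pixel")
    if not params.persistence_length > 0:
        raise ValueError("persistence_length must be strictly positive")
    L = params.fibril_length
    ds = min(0.05, L / 10)
    n_seg = max(1, round(L / ds))
    ds = L / n_seg
    theta0 = rng.uniform(0, 2 * math.pi)
    if straight or math.isinf(params.persistence_length):
        thetas = np.full(n_seg, theta0)
    else:
        dtheta = rng.normal(0.0, math.sqrt(ds / params.persistence_length), size=n_seg - 1)
        thetas = theta0 + np.concatenate([[0.0], np.cumsum(dtheta)])
    steps = ds * np.column_stack([np.sin(thetas), np.cos(thetas)])
    pts = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])

    centers = np.empty((0, 2))
    if params.embedded_puncta > 0:
        # place puncta on the backbone, spread out so they stay isolated
        s_frac = (np.arange(params.embedded_puncta) + rng.uniform(0.2, 0.8,
                  size=params.embedded_puncta)) / params.embedded_puncta
        idx = np.clip((s_frac * n_seg).astype(int), 0, n_seg)
        centers = pts[idx]

    mean = pts.mean(axis=0)
    pts = pts - mean
    if len(centers):
        centers = centers - mean
    return AggregateTruth(
        class_label="fibril",
        punctum_centers=centers,
        backbone_polyline=pts,
        true_longest_chain=L,
        true_branch_points=0,
        true_width=params.fibril_width,
    )


def polyline_arc_length(pts: np.ndarray) -> float:
    pts = np.asarray(pts, dtype=float)
    return float(np.hypot(*np.diff(pts, axis=0).T).sum())


# ---------------------------------------------------------------------------
# scene assembly and rendering


def assemble_scene(truths: list[AggregateTruth], params: SimParams,
                   rng: np.random.Generator | None = None,
                   min_separation: float = 3.0) -> GroundTruth:
    """Place aggregates in a common scene frame without overlap.

    Aggregates are laid out on a jittered grid with at least
    ``min_separation`` µm between bounding boxes so segmentation can
    resolve them.
    """
    if rng is None:
        rng = params.rng()
    placed: list[AggregateTruth] = []
    x_cursor = 0.0
    y_cursor = 0.0
    row_height = 0.0
    row_width_limit = max(
        (np.ptp(_all_points(t), axis=0).max() for t in truths), default=5.0
    ) * 3 + 3 * min_separation
    for t in truths:
        pts = _all_points(t)
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        size = hi - lo
        if x_cursor > 0 and x_cursor + size[1] > row_width_limit:
            x_cursor = 0.0
            y_cursor += row_height + min_separation
            row_height = 0.0
        shift = np.array([y_cursor - lo[0], x_cursor - lo[1]])
        shift = shift + rng.uniform(0, min_separation / 4, size=2)
        placed.append(_shifted(t, shift))
        x_cursor += size[1] + min_separation
        row_height = max(row_height, size[0])
    return GroundTruth(aggregates=placed)


def _all_points(t: AggregateTruth) -> np.ndarray:
    parts = [p for p in (t.punctum_centers, t.backbone_polyline) if len(p)]
    return np.vstack(parts) if parts else np.zeros((1, 2))


def _shifted(t: AggregateTruth, shift: np.ndarray) -> AggregateTruth:
    return AggregateTruth(
        class_label=t.class_label,
        punctum_centers=t.punctum_centers + shift if len(t.punctum_centers) else t.punctum_centers,
        backbone_polyline=t.backbone_polyline + shift if len(t.backbone_polyline) else t.backbone_polyline,
        true_longest_chain=t.true_longest_chain,
        true_branch_points=t.true_branch_points,
        true_width=t.true_width,
    )


def _splat(points: np.ndarray, weights: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear deposition of weighted point sources onto a pixel grid."""
    img = np.zeros(shape)
    y, x = points[:, 0], points[:, 1]
    y0 = np.floor(y).astype(int)
    x0 = np.floor(x).astype(int)
    fy, fx = y - y0, x - x0
    for dy, dx, w in ((0, 0, (1 - fy) * (1 - fx)), (0, 1, (1 - fy) * fx),
                      (1, 0, fy * (1 - fx)), (1, 1, fy * fx)):
        yy, xx = y0 + dy, x0 + dx
        ok = (yy >= 0) & (yy < shape[0]) & (xx >= 0) & (xx < shape[1])
        np.add.at(img, (yy[ok], xx[ok]), weights[ok] * w[ok])
    return img


def _aggregate_field(t: AggregateTruth, params: SimParams, origin: np.ndarray,
                     shape: tuple[int, int]) -> np.ndarray:
    """Noiseless expected photon count per pixel for one aggregate."""
    px = params.pixel_size
    field = np.zeros(shape)
    if len(t.punctum_centers):
        pts = (t.punctum_centers - origin) / px
        w = np.full(len(pts), params.punctum_photons)
        spot_sigma = math.hypot(params.psf_sigma, params.punctum_diameter / 4) / px
        field += ndimage.gaussian_filter(_splat(pts, w, shape), spot_sigma,
                                         mode="constant", truncate=6.0)
    if len(t.backbone_polyline) > 1:
        # resample the backbone densely and deposit line photons
        poly = (t.backbone_polyline - origin) / px
        seg = np.hypot(*np.diff(poly, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        n_samp = max(2, int(s[-1] / 0.5))  # every half pixel
        si = np.linspace(0, s[-1], n_samp)
        ys = np.interp(si, s, poly[:, 0])
        xs = np.interp(si, s, poly[:, 1])
        w = np.full(n_samp, params.fibril_photons_per_um * s[-1] * px / n_samp)
        field += ndimage.gaussian_filter(
            _splat(np.column_stack([ys, xs]), w, shape),
            params.psf_sigma / px, mode="constant", truncate=6.0)
    return field


def render_scene(truth: GroundTruth, params: SimParams,
                 shape: tuple[int, int] | None = None,
                 noise: bool = True,
                 rng: np.random.Generator | None = None,
                 origin: tuple[float, float] | None = None,
                 ) -> tuple[Image, Image, np.ndarray]:
    """Render a two-channel scene (mCherry-like, ThT-like) + label mask.

    The ThT channel is the mCherry channel's noiseless photon field
    translated by ``params.chromatic_shift`` (pixels) and then noised
    independently — both dyes stain the same aggregates, so apart from
    the chromatic shift and noise the channels are identical.

    ``origin`` fixes the scene coordinate (y, x) in µm of pixel (0, 0);
    by default the canvas is auto-fitted around the aggregates with a
    PSF-sized margin. The label mask assigns each pixel the 1-based
    index of the aggregate contributing the most photons there
    (0 = background).
    """
    if rng is None:
        rng = params.rng()
    px = params.pixel_size
    margin = 4 * math.hypot(params.psf_sigma, params.punctum_diameter / 2) + 2 * px

    if truth.aggregates:
        pts = np.vstack([_all_points(t) for t in truth.aggregates])
        lo = pts.min(axis=0) - margin
        hi = pts.max(axis=0) + margin
    else:
        lo = np.zeros(2)
        hi = np.full(2, 16 * px)
    if origin is not None:
        lo = np.asarray(origin, dtype=float)
    if shape is None:
        shape = (int(np.ceil((hi[0] - lo[0]) / px)) + 1,
                 int(np.ceil((hi[1] - lo[1]) / px)) + 1)
    origin = lo

    fields = [_aggregate_field(t, params, origin, shape) for t in truth.aggregates]
    total = np.sum(fields, axis=0) if fields else np.zeros(shape)

    peak = total.max() * params.photon_gain + params.background_level
    if peak > 65535:
        raise ValueError(
            f"rendered field peaks at {peak:.0f} a.u. (> 65535): reduce gain or photons")

    # label mask: dominant aggregate where signal is appreciable
    mask = np.zeros(shape, dtype=np.uint16)
    if fields:
        stack = np.stack(fields)
        sig = stack.sum(axis=0)
        floor = max(sig.max() * 0.02, 1e-9)
        winner = np.argmax(stack, axis=0) + 1
        mask[sig > floor] = winner[sig > floor].astype(np.uint16)

    shift = np.asarray(params.chromatic_shift, dtype=float)
    if np.any(shift != 0):
        total_b = ndimage.shift(total, shift, order=1, mode="constant", cval=0.0)
    else:
        total_b = total

    def _expose(photons: np.ndarray) -> np.ndarray:
        if noise:
            counts = rng.poisson(np.clip(photons, 0, None)).astype(float)
            out = (counts * params.photon_gain + params.background_level
                   + rng.normal(0.0, params.noise_read_sigma, size=photons.shape))
        else:
            out = photons * params.photon_gain + params.background_level
        return np.clip(out, 0, 65535)

    img_a = Image(_expose(total), pixel_size=px, channel="mCherry")
    img_b = Image(_expose(total_b), pixel_size=px, channel="ThT")
    return img_a, img_b, mask


# ---------------------------------------------------------------------------
# kinetics


@dataclass
class KineticsParams:
    """Parameters of a sigmoidal ThT aggregation time course.

    ``lag_time`` follows the tangent-intercept convention: the tangent
    at the point of maximum slope crosses the baseline at t = lag_time,
    which for the logistic means t_mid = lag_time + 2 / growth_rate.
    The optional ``initial_monomer_peak`` adds a decaying exponential
    reproducing the high non-aggregate ThT signal seen immediately
    after mixing monomer with the dye.
    """

    amplitude: float = 1000.0
    lag_time: float = 300.0
    growth_rate: float = 0.012
    baseline: float = 100.0
    initial_monomer_peak: float = 0.0
    monomer_decay_tau: float = 120.0
    seeded: bool = False
    sampling_interval: float = 10.0
    duration: float = 1440.0
    replicate_noise_sigma: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.lag_time < 0:
            raise ValueError("lag_time must be >= 0")
        if self.duration < self.sampling_interval:
            raise ValueError("duration must cover at least one sampling interval")
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be positive")

    @property
    def t_mid(self) -> float:
        return self.lag_time + 2.0 / self.growth_rate


@dataclass
class KineticsTrace:
    times: np.ndarray
    intensity: np.ndarray
    condition: str = "unseeded"
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times.shape != self.intensity.shape:
            raise ValueError("times and intensity must have the same length")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9)):
            raise ValueError("times must be strictly increasing and uniformly spaced")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")


# Study kinetics conditions: unseeded aggregation shows a ~300-min lag
# and reaches its plateau around 800 min (24 h measured every 10 min,
# three replicates); seeding with preformed aggregates cuts the lag
# below 100 min. The growth rate 0.01/min makes the 95 %-amplitude
# plateau of a 300-min-lag logistic fall at ~794 min.
STUDY_KINETICS_UNSEEDED = dict(amplitude=1000.0, lag_time=300.0,
                               growth_rate=0.01, baseline=100.0,
                               replicate_noise_sigma=50.0)
STUDY_KINETICS_SEEDED = dict(amplitude=1000.0, lag_time=80.0,
                             growth_rate=0.01, baseline=100.0,
                             replicate_noise_sigma=50.0, seeded=True)


def logistic(t: np.ndarray, baseline: float, amplitude: float,
             growth_rate: float, t_mid: float) -> np.ndarray:
    return baseline + amplitude / (1.0 + np.exp(-growth_rate * (t - t_mid)))


def simulate_kinetics(params: KineticsParams, n_replicates: int = 1,
                      rng: np.random.Generator | None = None) -> list[KineticsTrace]:
    """Simulate sigmoidal ThT traces (one per replicate)."""
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    t = np.arange(0.0, params.duration + params.sampling_interval / 2,
                  params.sampling_interval)
    clean = logistic(t, params.baseline, params.amplitude,
                     params.growth_rate, params.t_mid)
    if params.initial_monomer_peak:
        clean = clean + params.initial_monomer_peak * np.exp(-t / params.monomer_decay_tau)
    condition = "seeded" if params.seeded else "unseeded"
    traces = []
    for rep in range(n_replicates):
        y = clean + rng.normal(0.0, params.replicate_noise_sigma, size=t.shape) \
            if params.replicate_noise_sigma > 0 else clean.copy()
        traces.append(KineticsTrace(times=t, intensity=np.clip(y, 0, None),
                                    condition=condition, replicate_id=rep))
    return traces


def render_kinetics_stack(params: KineticsParams, sim: SimParams,
                          n_aggregates: int = 3,
                          rng: np.random.Generator | None = None,
                          ) -> tuple[list[Image], np.ndarray]:
    """Optional time-lapse stack: puncta whose brightness follows the sigmoid.

    Returns the frames and the time grid (min). Aggregate pixel
    brightness is scaled so the summed above-threshold intensity tracks
    the logistic curve.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    t = np.arange(0.0, params.duration + params.sampling_interval / 2,
                  params.sampling_interval)
    frac = (logistic(t, 0.0, 1.0, params.growth_rate, params.t_mid)
            - logistic(np.array([0.0]), 0.0, 1.0, params.growth_rate, params.t_mid))
    frac = np.clip(frac, 0, None)
    frac /= frac.max() if frac.max() > 0 else 1.0
    truths = [simulate_fractal_aggregate(sim, stage=1, rng=rng)
              for _ in range(n_aggregates)]
    scene = assemble_scene(truths, sim, rng=rng)
    frames = []
    for f in frac:
        p = SimParams(**{**asdict(sim), "punctum_photons": sim.punctum_photons * float(f),
                         "chromatic_shift": tuple(sim.chromatic_shift)})
        img, _, _ = render_scene(scene, p, noise=params.replicate_noise_sigma > 0, rng=rng)
        frames.append(img)
    return frames, t


# ---------------------------------------------------------------------------
# TEM


def render_tem_fibril(width: float, length: float, params: SimParams,
                      polyline: np.ndarray | None = None,
                      twist_amplitude: float = 0.0,
                      twist_period: float | None = None,
                      edge_sigma_px: float = 2.0,
                      edge_amplitude: float = 2000.0,
                      noise_sigma: float = 0.0,
                      rng: np.random.Generator | None = None,
                      ) -> tuple[Image, np.ndarray]:
    """Render a negative-stain-style TEM fibril as an edge-bright ribbon.

    The perpendicular intensity profile has two Gaussian maxima at the
    ribbon edges, i.e. at distance width/2 either side of the backbone,
    so the peak-to-peak distance equals ``width`` in calibrated units.
    ``twist_amplitude`` (fraction of width) modulates the local width
    sinusoidally along the arc with period ``twist_period`` (same units
    as length). Returns the image and the backbone polyline in pixels.

    ``width``, ``length`` and ``params.pixel_size`` must share one unit
    (use µm with pixel_size in µm/px, e.g. 0.001 for 1 nm/px).
    """
    if rng is None:
        rng = params.rng()
    px = params.pixel_size
    if width < 3 * px:
        raise ValueError(f"width {width} is unresolvable at {px} per px (needs >= 3 px)")
    if twist_period is None:
        twist_period = length / 3 if length > 0 else 1.0

    if polyline is None:
        n = max(2, int(round(length / px)) + 1)
        xs = np.linspace(0, length / px, n)
        polyline = np.column_stack([np.zeros(n), xs])
    polyline = np.asarray(polyline, dtype=float)

    half_w_max = width * (1 + abs(twist_amplitude)) / 2 / px
    # generous margin so downstream straightening can use a half-window
    # comfortably wider than the ribbon itself
    pad = 1.8 * half_w_max + 6 * edge_sigma_px + 4
    lo = polyline.min(axis=0) - pad
    poly = polyline - lo
    shape = tuple((poly.max(axis=0) + pad).astype(int) + 1)

    # dense backbone samples with arc-length
    seg = np.hypot(*np.diff(poly, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n_samp = max(2, int(s[-1] / 0.25))
    si = np.linspace(0, s[-1], n_samp)
    dense = np.column_stack([np.interp(si, s, poly[:, 0]), np.interp(si, s, poly[:, 1])])
    tree = cKDTree(dense)

    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    dist, idx = tree.query(pts)
    arc = si[idx] * px
    local_w = width * (1 + twist_amplitude * np.sin(2 * math.pi * arc / twist_period))
    half = local_w / 2 / px
    profile = edge_amplitude * np.exp(-0.5 * ((dist - half) / edge_sigma_px) ** 2)
    # faint interior plateau (stain-excluded body); the smooth step is
    # retracted 4 edge-sigmas inside the rim so it cannot move the peaks
    from scipy.special import erf
    interior = 0.5 * (1.0 + erf((half - 4 * edge_sigma_px - dist)
                                / (edge_sigma_px * math.sqrt(2.0))))
    profile += 0.15 * edge_amplitude * interior
    img = params.background_level + profile.reshape(shape)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return Image(np.clip(img, 0, 65535), pixel_size=px, channel="TEM"), poly


# ---------------------------------------------------------------------------
# writers


def write_scene(dirpath: str | Path, name: str, img_a: Image, img_b: Image,
                mask: np.ndarray, truth: GroundTruth, params: SimParams) -> None:
    """Persist a rendered scene: multi-page 16-bit TIFF (mCherry, ThT),
    label-mask TIFF, ground-truth CSV and a JSON metadata sidecar."""
    import tifffile

    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    stack = np.stack([np.round(img_a.pixels), np.round(img_b.pixels)]).astype(np.uint16)
    tifffile.imwrite(dirpath / f"{name}.tif", stack, photometric="minisblack")
    tifffile.imwrite(dirpath / f"{name}_mask.tif", mask.astype(np.uint16),
                     photometric="minisblack")
    rows = []
    for i, t in enumerate(truth.aggregates, start=1):
        rows.append({
            "aggregate_id": i,
            "class_label": t.class_label,
            "n_puncta": len(t.punctum_centers),
            "true_longest_chain_um": t.true_longest_chain,
            "true_branch_points": t.true_branch_points,
            "true_width_um": t.true_width,
        })
    pd.DataFrame(rows).to_csv(dirpath / f"{name}_truth.csv", index=False)
    meta = asdict(params)
    meta["chromatic_shift"] = list(params.chromatic_shift)
    (dirpath / f"{name}_meta.json").write_text(json.dumps(meta, indent=2))


def traces_to_frame(traces: list[KineticsTrace]) -> pd.DataFrame:
    """Long-format kinetics table: time_min, replicate_id, intensity_au, condition."""
    frames = [pd.DataFrame({
        "time_min": tr.times,
        "replicate_id": tr.replicate_id,
        "intensity_au": tr.intensity,
        "condition": tr.condition,
    }) for tr in traces]
    return pd.concat(frames, ignore_index=True)
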