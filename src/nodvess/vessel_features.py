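"""Centerline extraction and tortuosity features of the attached vessels.

Each labeled vessel component is skeletonized; the skeleton is decomposed
into branches at junction voxels; branch polylines are converted to physical
(mm) coordinates, lightly smoothed, and characterized by discrete Frenet
curvature and torsion, the arc/chord distance metric, and a box-counting
fractal dimension.

The case-level tortuosity block holds the three means (curvature, fractal
dimension, distance metric) plus the attached-vessel count, and the two
auxiliary comparison features: the maximum over branches of the per-branch
maximum curvature, and the 4th bin of the pooled |torsion| histogram
(10 equal-width bins on [0, 0.5] 1/mm, reported as a proportion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.morphology import skeletonize

from .errors import InsufficientDataError
from .segmentation import SegmentationResult

__all__ = [
    "Branch",
    "TortuosityFeatures",
    "extract_centerlines",
    "branch_curvature_torsion",
    "distance_metric",
    "fractal_dimension",
    "tortuosity_block",
    "VESSEL_FEATURE_NAMES",
]

log = logging.getLogger(__name__)

VESSEL_FEATURE_NAMES = (
    "curvature_mean", "fractal_dimension_mean", "distance_metric_mean",
    "n_attached_vessels",
)
AUX_VESSEL_FEATURE_NAMES = ("fsv_max_max_curvature", "fsv_torsion_hist_bin4")

MIN_BRANCH_POINTS = 5
MIN_BRANCH_ARC_MM = 3.0
_SMOOTH_SIGMA_POINTS = 2.0
_TORSION_HIST_BINS = 10
_TORSION_HIST_RANGE = (0.0, 0.5)  # |tau| in 1/mm
_CROSS_TOL = 1e-10


@dataclass(frozen=True)
class Branch:
    """One centerline segment as an ordered polyline in mm coordinates."""

    points: np.ndarray  # (n, 3) physical (z, y, x) in mm
    component_id: int = 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise ValueError("branch needs >= 2 points of dimension 3")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("consecutive branch points must be distinct")
        object.__setattr__(self, "points", pts)

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def chord_length(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


@dataclass(frozen=True)
class TortuosityFeatures:
    """Case-level vessel feature block."""

    curvature_mean: float
    fractal_dimension_mean: float
    distance_metric_mean: float
    n_attached_vessels: int
    fsv_max_max_curvature: float
    fsv_torsion_hist_bin4: float
    flags: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {
            "curvature_mean": self.curvature_mean,
            "fractal_dimension_mean": self.fractal_dimension_mean,
            "distance_metric_mean": self.distance_metric_mean,
            "n_attached_vessels": float(self.n_attached_vessels),
            "fsv_max_max_curvature": self.fsv_max_max_curvature,
            "fsv_torsion_hist_bin4": self.fsv_torsion_hist_bin4,
        }


# ---------------------------------------------------------------------------
# centerlines
# ---------------------------------------------------------------------------

def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    """26-connectivity graph over skeleton voxels."""
    g = nx.Graph()
    voxels = list(map(tuple, np.argwhere(skel)))
    vox_set = set(voxels)
    g.add_nodes_from(voxels)
    for z, y, x in voxels:
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if (dz, dy, dx) <= (0, 0, 0):
                        continue
                    nb = (z + dz, y + dy, x + dx)
                    if nb in vox_set:
                        g.add_edge((z, y, x), nb)
    return g


def _split_branches(g: nx.Graph) -> list[list[tuple[int, int, int]]]:
    """Decompose a skeleton graph into paths split at junction voxels."""
    if g.number_of_nodes() == 0:
        return []
    junctions = {n for n in g if g.degree(n) >= 3}
    chains = g.subgraph(n for n in g if n not in junctions)
    branches: list[list[tuple]] = []
    for comp in nx.connected_components(chains):
        sub = chains.subgraph(comp)
        ends = [n for n in comp if sub.degree(n) <= 1]
        if len(ends) >= 2:
            path = nx.shortest_path(sub, ends[0], ends[1])
        elif len(comp) >= 3:  # cycle: break one edge and walk it end to end
            cut = nx.Graph(sub)
            u = next(iter(comp))
            v = next(iter(cut[u]))
            cut.remove_edge(u, v)
            path = nx.shortest_path(cut, u, v)
        else:
            path = list(comp)
        # re-attach adjacent junction voxels at each free end
        for end_idx in (0, -1):
            for j in junctions:
                if g.has_edge(path[end_idx], j):
                    path = ([j] + path) if end_idx == 0 else (path + [j])
                    break
        branches.append(path)
    if not branches and junctions:
        # pathological: skeleton is junctions only
        branches.append(list(junctions))
    return branches


def extract_centerlines(vessels: np.ndarray, spacing) -> list[Branch]:
    """Skeletonize each vessel component and split into smoothed branches.

    Branches with fewer than 5 skeleton voxels, or shorter than 3 mm of
    arc, are dropped (logged): the derivative stencils are undefined on the
    former, and the latter are skeletonization spurs near junctions whose
    spurious curvature would dominate the pooled statistics. An empty
    vessel mask yields an empty list.
    """
    spacing = np.asarray(spacing, dtype=float)
    out: list[Branch] = []
    labels = np.unique(vessels[vessels > 0])
    for lab in labels:
        comp = vessels == lab
        skel = skeletonize(comp)
        if not skel.any():
            # a component too small to skeletonize; use its voxels directly
            skel = comp
        for path in _split_branches(_skeleton_graph(skel)):
            if len(path) < MIN_BRANCH_POINTS:
                log.debug("dropping %d-point branch of component %d",
                          len(path), int(lab))
                continue
            pts = np.asarray(path, dtype=np.float64) * spacing
            sm = gaussian_filter1d(pts, sigma=_SMOOTH_SIGMA_POINTS, axis=0,
                                   mode="nearest")
            # remove accidental duplicates after smoothing
            keep = np.ones(len(sm), dtype=bool)
            keep[1:] = np.linalg.norm(np.diff(sm, axis=0), axis=1) > 1e-9
            sm = sm[keep]
            arc = float(np.linalg.norm(np.diff(sm, axis=0), axis=1).sum())
            if arc < MIN_BRANCH_ARC_MM or len(sm) < 2:
                log.debug("dropping %.1f mm spur of component %d", arc, int(lab))
                continue
            out.append(Branch(sm, component_id=int(lab)))
    return out


# ---------------------------------------------------------------------------
# differential geometry
# ---------------------------------------------------------------------------

def branch_curvature_torsion(b: Branch) -> tuple[np.ndarray, np.ndarray]:
    """Discrete Frenet curvature and torsion along a branch.

    Derivatives are central differences with respect to arc length:
    kappa = |r' x r''| / |r'|^3 and tau = (r' x r'') . r''' / |r' x r''|^2.
    The three points at each end are excluded from the returned arrays: the
    third derivative reaches three stencils deep, so one-sided boundary
    differences contaminate exactly that many points. Torsion is set to 0 where the curve is locally
    straight (|r' x r''| below tolerance); a fully collinear branch returns
    all zeros.
    """
    pts = b.points
    if len(pts) < MIN_BRANCH_POINTS:
        raise InsufficientDataError("need >= 5 points for curvature/torsion")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    r1 = np.gradient(pts, s, axis=0)
    r2 = np.gradient(r1, s, axis=0)
    r3 = np.gradient(r2, s, axis=0)
    cross = np.cross(r1, r2)
    cross_norm2 = np.einsum("ij,ij->i", cross, cross)
    speed = np.linalg.norm(r1, axis=1)
    kappa = np.sqrt(cross_norm2) / np.maximum(speed, 1e-12) ** 3
    tau = np.zeros(len(pts))
    ok = cross_norm2 > _CROSS_TOL
    tau[ok] = np.einsum("ij,ij->i", cross[ok], r3[ok]) / cross_norm2[ok]
    sl = slice(3, max(len(pts) - 3, 3))
    return kappa[sl], tau[sl]


def distance_metric(b: Branch) -> float:
    """Arc length over chord length (>= 1); the classic tortuosity index.

    Raises
    ------
    InsufficientDataError
        For (near-)closed branches, whose chord is below tolerance; callers
        exclude such loop branches from the mean with a log entry.
    """
    chord = b.chord_length
    if chord < 1e-6:
        raise InsufficientDataError("closed-loop branch: chord below tolerance")
    return max(b.arc_length / chord, 1.0)


def _resample(pts: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length step."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(np.ceil(total / step)) + 1, 2)
    si = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(si, s, pts[:, k]) for k in range(3)])


def fractal_dimension(b: Branch, n_scales: int = 8) -> float:
    """Box-counting dimension of the branch curve.

    Occupied-box counts are taken on a geometric ladder of box sizes between
    twice the mean point spacing and half the branch extent; the dimension
    is the least-squares slope of log N(eps) against log(1/eps). The curve
    is densely resampled first so counts are not limited by point sparsity,
    and counts are averaged over four fixed grid offsets per scale to damp
    the grid-phase (and hence orientation) dependence of box counting.
    """
    pts = b.points
    if len(pts) < 16:
        raise InsufficientDataError("need >= 16 points for box counting")
    spacing = float(np.mean(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    extent = float(np.max(pts.max(axis=0) - pts.min(axis=0)))
    eps_min, eps_max = 2.0 * spacing, extent / 2.0
    if eps_max <= eps_min * 1.1:
        raise InsufficientDataError("branch extent too small for a scale ladder")
    eps = np.geomspace(eps_min, eps_max, n_scales)
    dense = _resample(pts, eps_min / 4.0)
    origin = dense.min(axis=0)
    counts = []
    for e in eps:
        n_occ = [
            len(np.unique(np.floor((dense - origin) / e + phase).astype(np.int64),
                          axis=0))
            for phase in (0.0, 0.25, 0.5, 0.75)
        ]
        counts.append(np.mean(n_occ))
    slope = np.polyfit(np.log(1.0 / eps), np.log(counts), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# case-level block
# ---------------------------------------------------------------------------

def tortuosity_block(seg: SegmentationResult, spacing) -> TortuosityFeatures:
    """Compute the vessel feature block for one segmented case.

    ``curvature_mean`` pools curvature over all points of all branches (long
    vessels weigh proportionally); the fractal-dimension and distance-metric
    means are per-branch means. A case with no usable vessels returns zeros
    with flags rather than failing.
    """
    branches = extract_centerlines(seg.vessels, spacing)
    flags: set[str] = set()
    kappas: list[np.ndarray] = []
    taus: list[np.ndarray] = []
    dms: list[float] = []
    fds: list[float] = []
    max_max_k = 0.0
    for b in branches:
        k, t = branch_curvature_torsion(b)
        if len(k):
            kappas.append(k)
            taus.append(t)
            max_max_k = max(max_max_k, float(k.max()))
        try:
            dms.append(distance_metric(b))
        except InsufficientDataError:
            log.info("excluding loop branch (component %d) from distance metric",
                     b.component_id)
        try:
            fds.append(fractal_dimension(b))
        except InsufficientDataError:
            pass

    if kappas:
        all_k = np.concatenate(kappas)
        all_t = np.abs(np.concatenate(taus))
        curvature_mean = float(all_k.mean())
        hist, _ = np.histogram(all_t, bins=_TORSION_HIST_BINS,
                               range=_TORSION_HIST_RANGE)
        bin4 = float(hist[3] / len(all_t)) if len(all_t) else 0.0
    else:
        curvature_mean, bin4 = 0.0, 0.0
        flags.update({"curvature_mean", "fsv_max_max_curvature",
                      "fsv_torsion_hist_bin4"})
    if not dms:
        flags.add("distance_metric_mean")
    if not fds:
        flags.add("fractal_dimension_mean")

    return TortuosityFeatures(
        curvature_mean=curvature_mean,
        fractal_dimension_mean=float(np.mean(fds)) if fds else 0.0,
        distance_metric_mean=float(np.mean(dms)) if dms else 0.0,
        n_attached_vessels=seg.n_vessel_components,
        fsv_max_max_curvature=max_max_k,
        fsv_torsion_hist_bin4=bin4,
        flags=frozenset(flags),
    )
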