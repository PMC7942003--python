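"""Radiomic features of the segmented nodule.

Three blocks are computed from the nodule mask and the underlying HU volume:

* **texture** — 830 features from a versioned bank: first-order intensity
  statistics, 3D gray-level co-occurrence (GLCM/Haralick) statistics over the
  13 unique distance-1 directions (and their distance-2 counterparts),
  gradient-image statistics including the axial diagonal difference kernels,
  multi-scale Gaussian / Laplacian-of-Gaussian / difference-of-Gaussian
  responses, and single-level 3D wavelet subbands;
* **shape** — 13 spacing-aware descriptors from a marching-cubes surface
  mesh and its convex hull (sphericity, convexity, roughness, ...);
* **sharpness** — 12 statistics of the HU gradient magnitude over the nodule
  margin at several smoothing scales.

Two texture features have first-class names because the classifier's
four-feature set uses them: ``correlation_std`` (dispersion of the Haralick
correlation across the 13 distance-1 directions) and
``diagonal_gradient_kurtosis`` (Pearson kurtosis of the pooled responses of
the four axial-plane diagonal difference kernels).

Degenerate inputs (constant intensity, empty response sets) never shorten
the feature vector: the affected features carry a sentinel value of 0 and
their names are recorded in the vector's ``flags`` set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage, stats
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from .errors import EmptyMaskError, InsufficientDataError
from .volume_io import BinaryMask, Volume

__all__ = [
    "GLCMatrix",
    "FeatureVector",
    "TextureBankConfig",
    "quantize",
    "compute_glcm",
    "glcm_correlation",
    "correlation_std",
    "diagonal_gradient_kurtosis",
    "shape_features",
    "sharpness_features",
    "extract_texture_bank",
    "bank_manifest",
    "DIRECTIONS_13",
]

# The 13 unique 3D offset directions at Chebyshev distance 1 (one per
# +/- direction pair).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

STAT12 = (
    "mean", "std", "min", "max", "median", "p10", "p90",
    "skewness", "kurtosis", "energy", "entropy", "range",
)

_FO_EXTRA = (
    "variance", "p25", "p75", "iqr", "mean_abs_dev", "median_abs_dev",
    "rms", "uniformity", "coeff_variation", "total_energy",
)

_HARALICK = (
    "contrast", "dissimilarity", "homogeneity", "energy", "entropy",
    "correlation", "autocorrelation", "cluster_shade", "cluster_prominence",
    "max_probability", "sum_average", "sum_entropy", "difference_entropy",
    "variance",
)

_GRAD_IMAGES = ("z", "y", "x", "mag", "diag_p45", "diag_m45", "diag_pooled",
                "laplacian")

_WAVELET_SUBBANDS = ("aaa", "aad", "ada", "add", "daa", "dad", "dda", "ddd")


@dataclass(frozen=True)
class GLCMatrix:
    """Normalized, symmetrized gray-level co-occurrence matrix."""

    p: np.ndarray
    offset: tuple[int, int, int]
    ng: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=np.float64)
        if p.shape != (self.ng, self.ng):
            raise ValueError("GLCM shape does not match Ng")
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("GLCM must be nonnegative and sum to 1")
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class FeatureVector:
    """An ordered, fixed-length name -> value map for one case."""

    names: tuple[str, ...]
    values: np.ndarray
    flags: frozenset[str] = frozenset()
    bank_version: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if len(values) != len(self.names):
            raise ValueError("names/values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate feature names")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "flags", frozenset(self.flags))

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def to_series(self):
        import pandas as pd

        return pd.Series(self.values, index=list(self.names))


@dataclass(frozen=True)
class TextureBankConfig:
    """Configuration of the 830-feature texture bank.

    The default configuration emits exactly 830 features; the manifest is
    hashed into ``bank_version`` so results always carry the bank identity.
    """

    ng: int = 32
    distances: tuple[int, ...] = (1, 2)
    log_sigmas_mm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    gauss_sigmas_mm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    wavelet: str = "haar"

    def __post_init__(self) -> None:
        if self.ng < 2:
            raise ValueError("ng must be >= 2")


def bank_manifest(config: TextureBankConfig | None = None) -> list[tuple[str, str]]:
    """Deterministic (family, feature name) list defining the texture bank."""
    cfg = config or TextureBankConfig()
    out: list[tuple[str, str]] = []
    for s in STAT12:
        out.append(("first_order", f"fo_{s}"))
    for s in _FO_EXTRA:
        out.append(("first_order", f"fo_{s}"))
    for d in cfg.distances:
        for stat in _HARALICK:
            for i in range(len(DIRECTIONS_13)):
                out.append(("glcm", f"glcm_d{d}_{stat}_dir{i:02d}"))
            for agg in ("mean", "std", "range"):
                if d == 1 and stat == "correlation" and agg == "std":
                    out.append(("glcm", "correlation_std"))
                else:
                    out.append(("glcm", f"glcm_d{d}_{stat}_{agg}"))
    for img in _GRAD_IMAGES:
        for s in STAT12:
            if img == "diag_pooled" and s == "kurtosis":
                out.append(("gradient", "diagonal_gradient_kurtosis"))
            else:
                out.append(("gradient", f"grad_{img}_{s}"))
    for sig in cfg.log_sigmas_mm:
        for s in STAT12:
            out.append(("log", f"log_{sig:g}mm_{s}"))
    for sig in cfg.gauss_sigmas_mm:
        for s in STAT12:
            out.append(("gauss", f"gauss_{sig:g}mm_{s}"))
    for s1, s2 in zip(cfg.gauss_sigmas_mm[:-1], cfg.gauss_sigmas_mm[1:]):
        for s in STAT12:
            out.append(("dog", f"dog_{s1:g}_{s2:g}mm_{s}"))
    for band in _WAVELET_SUBBANDS:
        for s in STAT12:
            out.append(("wavelet", f"wav_{band}_{s}"))
    return out


def bank_version(config: TextureBankConfig | None = None) -> str:
    cfg = config or TextureBankConfig()
    doc = {"manifest": bank_manifest(cfg), "ng": cfg.ng, "wavelet": cfg.wavelet}
    return hashlib.sha256(json.dumps(doc).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# statistics helpers
# ---------------------------------------------------------------------------

def _stat12(values: np.ndarray) -> tuple[dict[str, float], bool]:
    """The 12 standard statistics of a 1D sample; flags degenerate samples."""
    out = {s: 0.0 for s in STAT12}
    if values.size == 0:
        return out, True
    v = np.asarray(values, dtype=np.float64)
    out["mean"] = float(v.mean())
    out["std"] = float(v.std())
    out["min"] = float(v.min())
    out["max"] = float(v.max())
    out["median"] = float(np.median(v))
    out["p10"] = float(np.percentile(v, 10))
    out["p90"] = float(np.percentile(v, 90))
    out["energy"] = float(np.mean(v**2))
    out["range"] = float(v.max() - v.min())
    degenerate = out["std"] < 1e-12
    if not degenerate:
        out["skewness"] = float(stats.skew(v))
        out["kurtosis"] = float(stats.kurtosis(v, fisher=False))
        counts, _ = np.histogram(v, bins=32)
        p = counts[counts > 0] / v.size
        out["entropy"] = float(-np.sum(p * np.log2(p)))
    return out, degenerate


def _first_order(values: np.ndarray) -> tuple[dict[str, float], bool]:
    base, degenerate = _stat12(values)
    out = {f"fo_{k}": val for k, val in base.items()}
    extra = {k: 0.0 for k in _FO_EXTRA}
    if values.size:
        v = np.asarray(values, dtype=np.float64)
        med = np.median(v)
        extra["variance"] = float(v.var())
        extra["p25"] = float(np.percentile(v, 25))
        extra["p75"] = float(np.percentile(v, 75))
        extra["iqr"] = extra["p75"] - extra["p25"]
        extra["mean_abs_dev"] = float(np.mean(np.abs(v - v.mean())))
        extra["median_abs_dev"] = float(np.median(np.abs(v - med)))
        extra["rms"] = float(np.sqrt(np.mean(v**2)))
        extra["total_energy"] = float(np.sum(v**2))
        counts, _ = np.histogram(v, bins=32)
        extra["uniformity"] = float(np.sum((counts / v.size) ** 2))
        if abs(v.mean()) > 1e-12:
            extra["coeff_variation"] = float(v.std() / abs(v.mean()))
    out.update({f"fo_{k}": val for k, val in extra.items()})
    return out, degenerate


# ---------------------------------------------------------------------------
# quantization and GLCM
# ---------------------------------------------------------------------------

def quantize(volume: Volume, mask: BinaryMask, ng: int = 32) -> tuple[np.ndarray, bool]:
    """Equal-width quantization of in-mask HU into ``{0..ng-1}``.

    Bin edges span the in-mask min..max; upper edges are inclusive, so with
    ng=2 the mid-range value falls in bin 0. Out-of-mask voxels are set to -1.
    Returns ``(quantized, zero_variance_flag)``; a constant region maps
    entirely to bin 0 with the flag set.
    """
    if ng < 2:
        raise ValueError("ng must be >= 2")
    m = mask.data
    if not m.any():
        raise EmptyMaskError("cannot quantize an empty mask")
    vals = volume.data[m]
    lo, hi = float(vals.min()), float(vals.max())
    q = np.full(volume.shape, -1, dtype=np.int32)
    if hi - lo < 1e-12:
        q[m] = 0
        return q, True
    width = (hi - lo) / ng
    bins = np.ceil((volume.data[m] - lo) / width).astype(np.int64) - 1
    q[m] = np.clip(bins, 0, ng - 1)
    return q, False


def compute_glcm(quantized: np.ndarray, offset, ng: int) -> GLCMatrix:
    """Co-occurrence matrix for one 3D offset, symmetrized and normalized.

    A voxel pair is counted only when both ends lie inside the mask (value
    >= 0 in the quantized grid).
    """
    off = tuple(int(o) for o in offset)
    src = [slice(max(0, -o), quantized.shape[a] - max(0, o))
           for a, o in enumerate(off)]
    dst = [slice(max(0, o), quantized.shape[a] + min(0, o))
           for a, o in enumerate(off)]
    a = quantized[tuple(src)]
    b = quantized[tuple(dst)]
    valid = (a >= 0) & (b >= 0)
    if not valid.any():
        raise InsufficientDataError(f"no valid voxel pairs for offset {off}")
    counts = np.bincount(a[valid].astype(np.int64) * ng + b[valid],
                         minlength=ng * ng).reshape(ng, ng).astype(np.float64)
    p = counts + counts.T
    p /= p.sum()
    return GLCMatrix(p, off, ng)


def _glcm_stats(g: GLCMatrix) -> tuple[dict[str, float], bool]:
    """All Haralick statistics of one GLCM; flags zero marginal variance."""
    p = g.p
    ng = g.ng
    i = np.arange(ng, dtype=np.float64)[:, None]
    j = np.arange(ng, dtype=np.float64)[None, :]
    px = p.sum(axis=1)
    mu = float(np.sum(np.arange(ng) * px))
    sigma2 = float(np.sum((np.arange(ng) - mu) ** 2 * px))
    diff = i - j
    out: dict[str, float] = {}
    out["contrast"] = float(np.sum(diff**2 * p))
    out["dissimilarity"] = float(np.sum(np.abs(diff) * p))
    out["homogeneity"] = float(np.sum(p / (1.0 + diff**2)))
    out["energy"] = float(np.sum(p**2))
    nz = p[p > 0]
    out["entropy"] = float(-np.sum(nz * np.log2(nz)))
    out["autocorrelation"] = float(np.sum(i * j * p))
    out["cluster_shade"] = float(np.sum((i + j - 2 * mu) ** 3 * p))
    out["cluster_prominence"] = float(np.sum((i + j - 2 * mu) ** 4 * p))
    out["max_probability"] = float(p.max())
    out["variance"] = sigma2
    ksum = np.arange(2 * ng - 1)
    psum = np.array([np.trace(np.fliplr(p), offset=ng - 1 - k) for k in ksum])
    out["sum_average"] = float(np.sum(ksum * psum))
    nzs = psum[psum > 0]
    out["sum_entropy"] = float(-np.sum(nzs * np.log2(nzs)))
    pdiff = np.array([np.trace(p, offset=k) * (2.0 if k else 1.0)
                      for k in range(ng)])
    nzd = pdiff[pdiff > 0]
    out["difference_entropy"] = float(-np.sum(nzd * np.log2(nzd)))
    degenerate = sigma2 < 1e-12
    out["correlation"] = 0.0 if degenerate else float(
        np.sum((i - mu) * (j - mu) * p) / sigma2
    )
    return out, degenerate


def glcm_correlation(g: GLCMatrix) -> float:
    """Haralick correlation in [-1, 1]; 0 (sentinel) at zero marginal variance."""
    return _glcm_stats(g)[0]["correlation"]


def correlation_std(volume: Volume, mask: BinaryMask,
                    config: TextureBankConfig | None = None) -> float:
    """Population std of GLCM correlation over the 13 distance-1 directions.

    This is the dispersion of the Haralick correlation statistic across all
    unique 3D voxel-pair directions — a measure of texture anisotropy.
    """
    cfg = config or TextureBankConfig()
    q, _ = quantize(volume, mask, cfg.ng)
    vals = []
    for off in DIRECTIONS_13:
        try:
            vals.append(glcm_correlation(compute_glcm(q, off, cfg.ng)))
        except InsufficientDataError:
            continue
    if len(vals) < 2:
        raise InsufficientDataError("fewer than 2 directions with valid GLCMs")
    return float(np.std(vals))


# ---------------------------------------------------------------------------
# gradient images
# ---------------------------------------------------------------------------

def _diagonal_responses(data: np.ndarray, spacing) -> list[np.ndarray]:
    """Responses of the four axial-plane diagonal difference kernels.

    The kernels differentiate along the in-plane (y, x) diagonals at +/-45
    and +/-135 degrees; steps are corrected for physical pixel size.
    """
    dz, dy, dx = spacing
    ds = 2.0 * float(np.hypot(dy, dx))
    pad = np.pad(data, ((0, 0), (1, 1), (1, 1)), mode="edge")
    # central differences along the two diagonal axes
    d45 = (pad[:, 2:, 2:] - pad[:, :-2, :-2]) / ds     # +45 deg
    d135 = (pad[:, 2:, :-2] - pad[:, :-2, 2:]) / ds    # +135 deg
    return [d45, d135, -d45, -d135]


def diagonal_gradient_kurtosis(volume: Volume, mask: BinaryMask) -> float:
    """Pearson kurtosis (normal = 3) of pooled diagonal-kernel responses.

    The responses of the four axial-plane diagonal difference kernels are
    pooled over all in-mask voxels before the kurtosis is taken. Returns the
    sentinel 0.0 when the pooled responses have zero variance.
    """
    m = mask.data
    if m.sum() < 4:
        raise InsufficientDataError("need >= 4 in-mask voxels")
    responses = _diagonal_responses(volume.data, volume.spacing)
    pooled = np.concatenate([r[m] for r in responses])
    if pooled.std() < 1e-12:
        return 0.0
    return float(stats.kurtosis(pooled, fisher=False))


def _gradient_images(data: np.ndarray, spacing) -> dict[str, np.ndarray]:
    dz, dy, dx = spacing
    gz, gy, gx = np.gradient(data, dz, dy, dx)
    d45, d135, _, _ = _diagonal_responses(data, spacing)
    lap = ndimage.laplace(data) / float(np.mean(spacing)) ** 2
    return {
        "z": gz, "y": gy, "x": gx,
        "mag": np.sqrt(gz**2 + gy**2 + gx**2),
        "diag_p45": d45, "diag_m45": d135,
        "laplacian": lap,
    }


# ---------------------------------------------------------------------------
# texture bank
# ---------------------------------------------------------------------------

def _crop_to_mask(volume: Volume, mask: BinaryMask, pad_vox: int = 6):
    idx = np.argwhere(mask.data)
    lo = np.maximum(idx.min(axis=0) - pad_vox, 0)
    hi = np.minimum(idx.max(axis=0) + pad_vox + 1, np.asarray(mask.shape))
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return volume.data[sl], mask.data[sl]


def extract_texture_bank(volume: Volume, mask: BinaryMask,
                         config: TextureBankConfig | None = None) -> FeatureVector:
    """Compute the full texture block (830 features under the default bank).

    The vector length is invariant: any sub-feature that is undefined on the
    given input is emitted as sentinel 0 and listed in ``flags``.
    """
    cfg = config or TextureBankConfig()
    if not mask.data.any():
        raise EmptyMaskError("cannot extract texture from an empty mask")
    manifest = bank_manifest(cfg)
    values: dict[str, float] = {}
    flags: set[str] = set()

    data, m = _crop_to_mask(volume, mask, pad_vox=6)
    spacing = volume.spacing
    in_mask = data[m]

    fo, deg = _first_order(in_mask)
    values.update(fo)
    if deg:
        flags.update(k for k in fo if fo[k] == 0.0)

    # GLCM block
    crop_vol = Volume(data, spacing)
    crop_mask = BinaryMask(m, spacing)
    q, qflag = quantize(crop_vol, crop_mask, cfg.ng)
    for d in cfg.distances:
        per_dir: dict[str, list[float]] = {s: [] for s in _HARALICK}
        for i, base in enumerate(DIRECTIONS_13):
            off = tuple(o * d for o in base)
            try:
                g = compute_glcm(q, off, cfg.ng)
                st, gdeg = _glcm_stats(g)
            except InsufficientDataError:
                st, gdeg = {s: 0.0 for s in _HARALICK}, True
            for s in _HARALICK:
                name = f"glcm_d{d}_{s}_dir{i:02d}"
                values[name] = st[s]
                per_dir[s].append(st[s])
                if gdeg and s == "correlation":
                    flags.add(name)
        for s in _HARALICK:
            arr = np.asarray(per_dir[s])
            aggs = {"mean": float(arr.mean()), "std": float(arr.std()),
                    "range": float(arr.max() - arr.min())}
            for agg, val in aggs.items():
                if d == 1 and s == "correlation" and agg == "std":
                    values["correlation_std"] = val
                else:
                    values[f"glcm_d{d}_{s}_{agg}"] = val
        if qflag:
            flags.add("correlation_std" if d == 1 else f"glcm_d{d}_correlation_std")

    # gradient block
    gimg = _gradient_images(data, spacing)
    pooled = np.concatenate([r[m] for r in _diagonal_responses(data, spacing)])
    for img in _GRAD_IMAGES:
        vals = pooled if img == "diag_pooled" else gimg[img][m]
        st, gdeg = _stat12(vals)
        for s in STAT12:
            name = (
                "diagonal_gradient_kurtosis"
                if (img == "diag_pooled" and s == "kurtosis")
                else f"grad_{img}_{s}"
            )
            values[name] = st[s]
            if gdeg and s in ("skewness", "kurtosis", "entropy"):
                flags.add(name)

    # multi-scale filters (sigma in mm, converted per axis)
    spacing_arr = np.asarray(spacing)
    gauss_cache: dict[float, np.ndarray] = {}
    for sig in sorted(set(cfg.gauss_sigmas_mm) | set(cfg.log_sigmas_mm)):
        gauss_cache[sig] = ndimage.gaussian_filter(data, sigma=sig / spacing_arr)
    for sig in cfg.log_sigmas_mm:
        resp = ndimage.gaussian_laplace(data, sigma=sig / spacing_arr)
        st, gdeg = _stat12(resp[m])
        for s in STAT12:
            values[f"log_{sig:g}mm_{s}"] = st[s]
            if gdeg and s in ("skewness", "kurtosis", "entropy"):
                flags.add(f"log_{sig:g}mm_{s}")
    for sig in cfg.gauss_sigmas_mm:
        st, gdeg = _stat12(gauss_cache[sig][m])
        for s in STAT12:
            values[f"gauss_{sig:g}mm_{s}"] = st[s]
            if gdeg and s in ("skewness", "kurtosis", "entropy"):
                flags.add(f"gauss_{sig:g}mm_{s}")
    for s1, s2 in zip(cfg.gauss_sigmas_mm[:-1], cfg.gauss_sigmas_mm[1:]):
        st, gdeg = _stat12((gauss_cache[s1] - gauss_cache[s2])[m])
        for s in STAT12:
            values[f"dog_{s1:g}_{s2:g}mm_{s}"] = st[s]
            if gdeg and s in ("skewness", "kurtosis", "entropy"):
                flags.add(f"dog_{s1:g}_{s2:g}mm_{s}")

    # wavelet block: single-level 3D DWT; the mask is decimated to the
    # subband grid
    coeffs = pywt.dwtn(data, cfg.wavelet)
    sub_mask = m[::2, ::2, ::2]
    for band in _WAVELET_SUBBANDS:
        arr = coeffs[band]
        bm = sub_mask[: arr.shape[0], : arr.shape[1], : arr.shape[2]]
        vals = arr[: bm.shape[0], : bm.shape[1], : bm.shape[2]][bm]
        st, gdeg = _stat12(vals)
        for s in STAT12:
            values[f"wav_{band}_{s}"] = st[s]
            if gdeg:
                flags.add(f"wav_{band}_{s}")

    names = tuple(name for _, name in manifest)
    missing = [n for n in names if n not in values]
    if missing:  # contract safeguard; should be unreachable
        raise RuntimeError(f"bank manifest mismatch: {missing[:5]}")
    vec = np.array([values[n] for n in names])
    return FeatureVector(names, vec, frozenset(flags & set(names)),
                         bank_version(cfg))


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

SHAPE_NAMES = (
    "volume_mm3", "surface_area_mm2", "surface_to_volume_ratio",
    "sphericity", "compactness", "convexity", "roughness",
    "equivalent_diameter_mm", "max_3d_diameter_mm",
    "major_axis_mm", "least_axis_mm", "elongation", "flatness",
)


def shape_features(mask: BinaryMask, spacing=None) -> dict[str, float]:
    """13 spacing-aware shape descriptors of a single-component mask.

    Volume is voxel-counted; surface area comes from a marching-cubes mesh
    in mm; convexity is the mesh volume over the volume of the convex hull
    of the mesh vertices. Roughness is the coefficient of variation of the
    surface radial distance from the centroid — a dimensionless radial
    irregularity index that grows with spiculation (a surface-to-hull area
    ratio does not: the hull area inflates along with the spicules). Axis
    lengths derive from the principal components of the voxel cloud.
    """
    spacing = np.asarray(spacing if spacing is not None else mask.spacing,
                         dtype=float)
    m = mask.data
    if not m.any():
        raise EmptyMaskError("empty mask has no shape")
    _, ncomp = ndimage.label(m, structure=np.ones((3, 3, 3)))
    if ncomp != 1:
        raise ValueError(f"mask must be a single connected component, got {ncomp}")

    vol = float(m.sum()) * float(np.prod(spacing))
    # a light pre-mesh smoothing (0.8 voxel) suppresses the staircase facets
    # that would otherwise inflate the marching-cubes surface area ~8%
    padded = ndimage.gaussian_filter(np.pad(m, 2).astype(np.float64), 0.8)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=tuple(spacing))
    area = float(measure.mesh_surface_area(verts, faces))
    mesh_vol = float(np.abs(np.einsum(
        "ij,ij->i", verts[faces[:, 0]],
        np.cross(verts[faces[:, 1]], verts[faces[:, 2]])).sum()) / 6.0)
    hull = ConvexHull(verts)
    hull_pts = verts[hull.vertices]

    radial = np.linalg.norm(verts - verts.mean(axis=0), axis=1)

    pts = np.argwhere(m) * spacing
    centered = pts - pts.mean(axis=0)
    if len(pts) > 3:
        ev = np.sort(np.linalg.eigvalsh(np.cov(centered.T)))[::-1]
        ev = np.maximum(ev, 0.0)
    else:
        ev = np.zeros(3)

    out = {
        "volume_mm3": vol,
        "surface_area_mm2": area,
        "surface_to_volume_ratio": area / vol,
        "sphericity": float(np.pi ** (1 / 3) * (6 * vol) ** (2 / 3) / area),
        "compactness": float(36 * np.pi * vol**2 / area**3),
        "convexity": mesh_vol / float(hull.volume),
        "roughness": float(radial.std() / radial.mean()),
        "equivalent_diameter_mm": float((6 * vol / np.pi) ** (1 / 3)),
        "max_3d_diameter_mm": float(pdist(hull_pts).max()) if len(hull_pts) > 1 else 0.0,
        "major_axis_mm": float(4 * np.sqrt(ev[0])),
        "least_axis_mm": float(4 * np.sqrt(ev[2])),
        "elongation": float(np.sqrt(ev[1] / ev[0])) if ev[0] > 0 else 0.0,
        "flatness": float(np.sqrt(ev[2] / ev[0])) if ev[0] > 0 else 0.0,
    }
    return out


# ---------------------------------------------------------------------------
# margin sharpness
# ---------------------------------------------------------------------------

SHARPNESS_NAMES = (
    "sharpness_mean", "sharpness_std", "sharpness_min", "sharpness_max",
    "sharpness_median", "sharpness_p25", "sharpness_p75",
    "sharpness_skewness", "sharpness_kurtosis",
    "sharpness_mean_0.5mm", "sharpness_mean_2mm", "sharpness_mean_4mm",
)

_SHARPNESS_BASE_SIGMA_MM = 1.0
_SHARPNESS_EXTRA_SIGMAS_MM = (0.5, 2.0, 4.0)


def sharpness_features(volume: Volume, nodule_mask: BinaryMask,
                       spacing=None) -> tuple[dict[str, float], set[str]]:
    """12 margin-sharpness statistics and the set of degenerate-feature flags.

    The HU gradient magnitude (Gaussian derivative, sigma in mm) is sampled
    on the one-voxel surface shell of the nodule; nine statistics are taken
    at the base scale and the mean is repeated at three more window scales.
    """
    spacing = np.asarray(spacing if spacing is not None else volume.spacing,
                         dtype=float)
    m = nodule_mask.data
    if not m.any():
        raise EmptyMaskError("empty nodule mask has no margin")
    shell = m & ~ndimage.binary_erosion(m)
    if not shell.any():
        raise EmptyMaskError("nodule has no surface shell")

    pad = int(np.ceil(4 * max(_SHARPNESS_EXTRA_SIGMAS_MM) / spacing.min())) + 1
    data, mc = _crop_to_mask(volume, nodule_mask, pad_vox=pad)
    shell_c = mc & ~ndimage.binary_erosion(mc)

    def gmag(sigma_mm: float) -> np.ndarray:
        return ndimage.gaussian_gradient_magnitude(data, sigma=sigma_mm / spacing)

    base = gmag(_SHARPNESS_BASE_SIGMA_MM)[shell_c]
    flags: set[str] = set()
    out = {k: 0.0 for k in SHARPNESS_NAMES}
    out["sharpness_mean"] = float(base.mean())
    out["sharpness_std"] = float(base.std())
    out["sharpness_min"] = float(base.min())
    out["sharpness_max"] = float(base.max())
    out["sharpness_median"] = float(np.median(base))
    out["sharpness_p25"] = float(np.percentile(base, 25))
    out["sharpness_p75"] = float(np.percentile(base, 75))
    if base.std() > 1e-12:
        out["sharpness_skewness"] = float(stats.skew(base))
        out["sharpness_kurtosis"] = float(stats.kurtosis(base, fisher=False))
    else:
        flags.update({"sharpness_skewness", "sharpness_kurtosis"})
    for sig in _SHARPNESS_EXTRA_SIGMAS_MM:
        out[f"sharpness_mean_{sig:g}mm"] = float(gmag(sig)[shell_c].mean())
    return out, flags
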