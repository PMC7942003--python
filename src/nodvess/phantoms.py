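"""Synthetic chest-CT phantoms with known ground truth.

Each case is a lung-window-like volume (background around -900 HU) holding
one soft-tissue nodule — a sphere with optional Gaussian-bump spiculations
and a textured interior — plus tubular vessels attached to it, drawn as
straight lines or helices, and optional Gaussian HU noise. The generator
also writes a ground-truth label image (1 = nodule, 2 = vessels) and places
the seed point at the nodule centroid, so every pipeline stage can be
validated against a known answer.

Two-class cohorts emulate an adenocarcinoma-vs-granuloma study: 22 cases
per class, nodule diameters drawn from Normal(11.91, 4.36) mm truncated
below at 4 mm, with class-dependent vessel tortuosity (helix curvature),
vessel counts (Poisson) and texture heterogeneity (impulse rate and
anisotropic correlation length). The malignant-like class pulls more, and
more tortuous, vessels and has a more heterogeneous interior.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .errors import SpecError
from .volume_io import SeedPoint, Volume

__all__ = [
    "PhantomSpec",
    "ClassEffect",
    "CohortSpec",
    "CohortCase",
    "generate_case",
    "generate_cohort",
    "realize_case",
    "DEFAULT_ADENO_EFFECT",
    "DEFAULT_GRANULOMA_EFFECT",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic case.

    Helix curvature follows the analytic value a / (a^2 + b^2) with
    a = ``helix_radius_mm`` and b = ``helix_pitch_mm`` (the curve is
    (a cos t, a sin t, b t) in the vessel's local frame); ``helix_radius_mm
    = 0`` gives a straight vessel.
    """

    nodule_diameter_mm: float = 11.91
    spiculation_count: int = 0
    spiculation_amplitude: float = 0.0       # fraction of nodule radius
    spiculation_width_rad: float = 0.3
    n_vessels: int = 2
    vessel_radius_mm: float = 1.0
    vessel_kind: Literal["straight", "helix"] = "helix"
    helix_radius_mm: float = 0.5
    helix_pitch_mm: float = 4.0
    helix_turns: float = 1.0
    nodule_hu: float = -30.0
    texture_std_hu: float = 20.0
    texture_corr_len_mm: float = 1.0
    texture_aniso: float = 1.0               # z correlation-length multiplier
    impulse_rate: float = 0.0
    impulse_amp_hu: float = 150.0
    background_hu: float = -900.0
    vessel_hu: float = 50.0
    noise_sigma_hu: float = 10.0
    spacing_mm: tuple[float, float, float] = (0.7, 0.7, 0.7)
    volume_shape: tuple[int, int, int] = (96, 96, 96)

    def __post_init__(self) -> None:
        if self.nodule_diameter_mm <= 0:
            raise SpecError("nodule diameter must be positive")
        if self.n_vessels < 0 or self.vessel_radius_mm <= 0:
            raise SpecError("invalid vessel parameters")
        if any(s <= 0 for s in self.spacing_mm):
            raise SpecError("spacing must be positive")
        half_extent = min(
            n * s for n, s in zip(self.volume_shape, self.spacing_mm)
        ) / 2.0
        max_r = self.nodule_diameter_mm / 2 * (1 + self.spiculation_amplitude)
        if max_r + 2 * max(self.spacing_mm) > half_extent:
            raise SpecError(
                f"nodule radius {max_r:.1f} mm does not fit half-extent "
                f"{half_extent:.1f} mm"
            )


@dataclass(frozen=True)
class ClassEffect:
    """Per-class distributions over phantom parameters."""

    diameter_mean_mm: float = 11.91
    diameter_sd_mm: float = 4.36
    diameter_min_mm: float = 4.0
    diameter_max_mm: float = 22.0
    vessel_poisson_mean: float = 2.0
    vessel_count_min: int = 0
    helix_radius_range_mm: tuple[float, float] = (0.2, 0.8)
    helix_pitch_mm: float = 4.0
    helix_turns_range: tuple[float, float] = (0.6, 1.2)
    impulse_rate: float = 0.002
    texture_aniso: float = 1.0
    texture_std_hu: float = 20.0
    spiculation_count: int = 2
    spiculation_amplitude: float = 0.1


DEFAULT_ADENO_EFFECT = ClassEffect(
    vessel_poisson_mean=3.0,
    vessel_count_min=1,
    helix_radius_range_mm=(2.0, 3.5),
    helix_pitch_mm=1.5,
    helix_turns_range=(1.5, 3.0),
    impulse_rate=0.02,
    texture_aniso=2.5,
    texture_std_hu=35.0,
    spiculation_count=8,
    spiculation_amplitude=0.25,
)

DEFAULT_GRANULOMA_EFFECT = ClassEffect()


@dataclass(frozen=True)
class CohortSpec:
    """Two-class cohort description; the defaults emulate the 22+22 study."""

    n_per_class: int = 22
    master_seed: int = 1234
    class_effects: dict[str, ClassEffect] = field(default_factory=lambda: {
        "adenocarcinoma": DEFAULT_ADENO_EFFECT,
        "granuloma": DEFAULT_GRANULOMA_EFFECT,
    })
    noise_sigma_hu: float = 10.0
    spacing_mm: tuple[float, float, float] = (0.7, 0.7, 0.7)
    volume_shape: tuple[int, int, int] = (96, 96, 96)

    def __post_init__(self) -> None:
        if self.n_per_class < 3:
            raise SpecError("need at least 3 cases per class for threefold CV")
        if set(self.class_effects) != {"adenocarcinoma", "granuloma"}:
            raise SpecError("class_effects must cover both classes")


@dataclass(frozen=True)
class CohortCase:
    """Manifest row: everything needed to regenerate one case."""

    case_id: str
    label: str       # "adenocarcinoma" | "granuloma"
    y: int           # 1 = adenocarcinoma, 0 = granuloma
    seed: int
    spec: PhantomSpec


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _orthonormal_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(u, a))
    return e1, np.cross(u, e1)


def generate_case(
    spec: PhantomSpec, seed: int
) -> tuple[Volume, np.ndarray, SeedPoint]:
    """Render one phantom; fully deterministic given ``(spec, seed)``.

    Returns the HU volume, the truth label image (1 = nodule, 2 = vessels,
    disjoint, vessels 26-adjacent to the nodule), and the seed point at the
    nodule centroid.
    """
    rng = np.random.default_rng(seed)
    shape = np.asarray(spec.volume_shape)
    spacing = np.asarray(spec.spacing_mm)
    center = (shape - 1) / 2.0

    zz, yy, xx = np.meshgrid(
        (np.arange(shape[0]) - center[0]) * spacing[0],
        (np.arange(shape[1]) - center[1]) * spacing[1],
        (np.arange(shape[2]) - center[2]) * spacing[2],
        indexing="ij",
    )
    pos = np.stack([zz, yy, xx], axis=-1)
    rho = np.linalg.norm(pos, axis=-1)

    # --- nodule: sphere with Gaussian radial bumps ---
    r0 = spec.nodule_diameter_mm / 2.0
    r_mod = np.full(shape, r0)
    if spec.spiculation_count > 0 and spec.spiculation_amplitude > 0:
        dirs = rng.standard_normal((spec.spiculation_count, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        near = rho <= r0 * (1 + spec.spiculation_amplitude) + spacing.max()
        p = pos[near] / np.maximum(rho[near, None], 1e-9)
        cosang = np.clip(p @ dirs.T, -1.0, 1.0)
        ang = np.arccos(cosang)
        bump = np.exp(-(ang**2) / (2 * spec.spiculation_width_rad**2)).sum(axis=1)
        r_mod[near] = r0 * (1 + spec.spiculation_amplitude * bump)
    nodule = rho <= r_mod

    # --- vessels: tubes of constant radius around sampled curves ---
    centerline = np.zeros(shape, dtype=bool)
    margin = 1.5 * spacing
    lo_mm = -center * spacing + margin
    hi_mm = center * spacing - margin
    for _ in range(spec.n_vessels):
        u = _unit(rng.standard_normal(3))
        phase = rng.uniform(0, 2 * np.pi)
        start = 0.6 * r0 * u
        if spec.vessel_kind == "helix" and spec.helix_radius_mm > 0:
            a, b = spec.helix_radius_mm, spec.helix_pitch_mm
            e1, e2 = _orthonormal_frame(u)
            t_max = 2 * np.pi * spec.helix_turns
            step = 0.2 / np.sqrt(a * a + b * b)  # ~0.2 mm arc steps
            t = np.arange(0.0, t_max, step)
            pts = (start[None, :]
                   + b * t[:, None] * u[None, :]
                   + a * (np.cos(t + phase) - np.cos(phase))[:, None] * e1
                   + a * (np.sin(t + phase) - np.sin(phase))[:, None] * e2)
        else:
            length = 2 * np.pi * spec.helix_turns * spec.helix_pitch_mm
            t = np.arange(0.0, length, 0.2)
            pts = start[None, :] + t[:, None] * u[None, :]
        inside = np.all((pts >= lo_mm) & (pts <= hi_mm), axis=1)
        if not inside.all():
            pts = pts[: int(np.argmin(inside))]  # stop at first exit
        if len(pts) == 0:
            continue
        idx = np.rint(pts / spacing + center).astype(int)
        centerline[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    if centerline.any():
        dist = ndimage.distance_transform_edt(~centerline, sampling=spacing)
        tube = dist <= spec.vessel_radius_mm
    else:
        tube = np.zeros(shape, dtype=bool)
    vessels = tube & ~nodule

    # --- intensities ---
    vol = np.full(shape, spec.background_hu)
    field_ = rng.standard_normal(shape)
    sig = np.array([spec.texture_corr_len_mm * spec.texture_aniso,
                    spec.texture_corr_len_mm, spec.texture_corr_len_mm]) / spacing
    smooth = ndimage.gaussian_filter(field_, sigma=sig)
    smooth /= max(smooth.std(), 1e-12)
    texture = spec.nodule_hu + smooth * spec.texture_std_hu
    impulses = rng.random(shape) < spec.impulse_rate
    texture = texture + impulses * spec.impulse_amp_hu
    vol[nodule] = texture[nodule]
    vol[vessels] = spec.vessel_hu
    if spec.noise_sigma_hu > 0:
        vol = vol + rng.standard_normal(shape) * spec.noise_sigma_hu

    labels = np.zeros(shape, dtype=np.uint8)
    labels[nodule] = 1
    labels[vessels] = 2

    centroid = np.rint(np.argwhere(nodule).mean(axis=0)).astype(int)
    volume = Volume(vol, tuple(spacing), (0.0, 0.0, 0.0))
    seed_pt = SeedPoint(tuple(centroid))
    return volume, labels, seed_pt


def _draw_spec(effect: ClassEffect, cohort: CohortSpec,
               rng: np.random.Generator) -> PhantomSpec:
    d = float(np.clip(
        rng.normal(effect.diameter_mean_mm, effect.diameter_sd_mm),
        effect.diameter_min_mm, effect.diameter_max_mm,
    ))
    n_vessels = max(int(rng.poisson(effect.vessel_poisson_mean)),
                    effect.vessel_count_min)
    a = float(rng.uniform(*effect.helix_radius_range_mm))
    turns = float(rng.uniform(*effect.helix_turns_range))
    return PhantomSpec(
        nodule_diameter_mm=d,
        spiculation_count=effect.spiculation_count,
        spiculation_amplitude=effect.spiculation_amplitude,
        n_vessels=n_vessels,
        vessel_kind="helix",
        helix_radius_mm=a,
        helix_pitch_mm=effect.helix_pitch_mm,
        helix_turns=turns,
        impulse_rate=effect.impulse_rate,
        texture_aniso=effect.texture_aniso,
        texture_std_hu=effect.texture_std_hu,
        noise_sigma_hu=cohort.noise_sigma_hu,
        spacing_mm=cohort.spacing_mm,
        volume_shape=cohort.volume_shape,
    )


def generate_cohort(spec: CohortSpec) -> list[CohortCase]:
    """Draw the per-case specs and seeds for a two-class cohort.

    Cases are returned as lightweight manifest rows; call
    :func:`realize_case` to render the voxel data. Reproducible: the same
    ``CohortSpec`` always yields the same cases.
    """
    rng = np.random.default_rng(spec.master_seed)
    cases: list[CohortCase] = []
    for label, y in (("adenocarcinoma", 1), ("granuloma", 0)):
        effect = spec.class_effects[label]
        for i in range(spec.n_per_class):
            ps = _draw_spec(effect, spec, rng)
            case_seed = int(rng.integers(0, 2**31 - 1))
            cases.append(CohortCase(
                case_id=f"{label[:5]}_{i:03d}", label=label, y=y,
                seed=case_seed, spec=ps,
            ))
    return cases


def realize_case(case: CohortCase) -> tuple[Volume, np.ndarray, SeedPoint]:
    """Render the voxel data for one manifest row."""
    vol, labels, seed_pt = generate_case(case.spec, case.seed)
    return vol, labels, SeedPoint(seed_pt.index, case_id=case.case_id,
                                  label=case.label)


def spec_as_dict(spec: PhantomSpec) -> dict:
    return asdict(spec)
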