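"""Shared fixtures and analytic-curve helpers for the test suite."""

import numpy as np
import pytest

from nodvess.phantoms import PhantomSpec, generate_case
from nodvess.vessel_features import Branch
from nodvess.volume_io import BinaryMask, Volume


def helix_branch(a=5.0, b=2.0, turns=3.0, n=400) -> Branch:
    """Analytic helix (a cos t, a sin t, b t); kappa = a/(a^2+b^2),
    tau = b/(a^2+b^2)."""
    t = np.linspace(0, 2 * np.pi * turns, n)
    pts = np.column_stack([b * t, a * np.cos(t), a * np.sin(t)])
    return Branch(pts)


def arc_branch(radius=10.0, angle=np.pi, n=200) -> Branch:
    """Planar circular arc of given radius and subtended angle."""
    t = np.linspace(0, angle, n)
    pts = np.column_stack([np.zeros(n), radius * np.sin(t), radius * np.cos(t)])
    return Branch(pts)


def line_branch(length=30.0, n=100, direction=(0.0, 0.0, 1.0)) -> Branch:
    d = np.asarray(direction) / np.linalg.norm(direction)
    t = np.linspace(0, length, n)
    return Branch(t[:, None] * d[None, :])


def digital_sphere(radius_mm=10.0, spacing=0.5, pad_mm=3.0):
    """Binary sphere on an isotropic grid; returns (BinaryMask, spacing)."""
    half = int(np.ceil((radius_mm + pad_mm) / spacing))
    n = 2 * half + 1
    c = half
    zz, yy, xx = np.ogrid[:n, :n, :n]
    dist2 = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) * spacing**2
    return BinaryMask(dist2 <= radius_mm**2, (spacing,) * 3)


CLEAN_SPEC = PhantomSpec(
    nodule_diameter_mm=12.0,
    n_vessels=3,
    vessel_kind="straight",
    helix_pitch_mm=4.0,
    helix_turns=1.0,
    noise_sigma_hu=0.0,
    texture_std_hu=0.0,
    spiculation_count=0,
    spiculation_amplitude=0.0,
    volume_shape=(64, 64, 64),
)


@pytest.fixture(scope="session")
def clean_case():
    """Noise-free sphere + three straight tubes; ground truth known."""
    return generate_case(CLEAN_SPEC, seed=11)


@pytest.fixture(scope="session")
def textured_case():
    """Noisy, textured, spiculated nodule with two helical vessels."""
    spec = PhantomSpec(
        nodule_diameter_mm=12.0,
        n_vessels=2,
        helix_radius_mm=2.5,
        helix_pitch_mm=1.5,
        helix_turns=2.0,
        noise_sigma_hu=10.0,
        texture_std_hu=25.0,
        impulse_rate=0.01,
        spiculation_count=6,
        spiculation_amplitude=0.2,
        volume_shape=(64, 64, 64),
    )
    return generate_case(spec, seed=5)


@pytest.fixture()
def aniso_volume():
    """Small anisotropic-grid volume for coordinate-convention checks."""
    rng = np.random.default_rng(0)
    return Volume(rng.normal(size=(8, 10, 12)) * 100, (2.0, 0.7, 0.7),
                  origin=(5.0, -3.0, 1.0))
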