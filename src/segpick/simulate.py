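"""Synthetic micrograph generation and SNR-controlled noise injection.

The generator emulates the gross appearance of a motion-corrected cryo-EM
micrograph: darker, roughly convex particles on a brighter noisy
background, a smooth illumination gradient standing in for variable ice
thickness, bright crystalline-ice blobs, and a dark carbon edge along one
border.  It returns exact per-pixel class masks and particle centre lists
as ground truth, so segmentation and picking can be scored without manual
annotation.

SNR here is the power ratio Var(signal) / Var(noise), expressed in
decibels as ``10 * log10(ratio)``.  Gaussian noise is additive with the
variance chosen from the target SNR; Poisson noise scales the image to a
mean photon count at which the shot-noise variance yields the target SNR,
samples counts, and rescales back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io_formats import (
    CLASS_BACKGROUND,
    CLASS_CARBON,
    CLASS_ICE,
    CLASS_PROTEIN,
    ClassMask,
    Micrograph,
    ParticleSet,
)

__all__ = [
    "SceneSpec",
    "NoiseSpec",
    "PlacementError",
    "make_micrograph",
    "db_to_linear",
    "linear_to_db",
    "add_gaussian_noise",
    "add_poisson_noise",
    "measure_snr",
]

BACKGROUND_LEVEL = 0.7
ICE_LEVEL = 0.95
CARBON_LEVEL = 0.35
CARBON_WIDTH_FRACTION = 0.08  # width of the carbon border band


class PlacementError(RuntimeError):
    """Raised when particles cannot be placed without overlap."""


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    ``particle_contrast`` is the fractional intensity dip of a particle
    below the background (particles are darker, as in cryo-EM).
    ``illumination_gradient`` is the total linear intensity change across
    the image, as a fraction of the background level.
    """

    image_size: tuple[int, int] = (256, 256)
    n_particles: int = 10
    particle_radius_px: int = 8
    particle_contrast: float = 0.5
    shape: Literal["disk", "annulus", "blob"] = "disk"
    ice_blobs: int = 0
    carbon_edge: bool = False
    illumination_gradient: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        if self.particle_radius_px < 3:
            raise ValueError("particle_radius_px must be >= 3")
        if not (0.0 < self.particle_contrast <= 1.0):
            raise ValueError("particle_contrast must be in (0, 1]")
        if self.shape not in ("disk", "annulus", "blob"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.ice_blobs < 0:
            raise ValueError("ice_blobs must be >= 0")
        if self.illumination_gradient < 0:
            raise ValueError("illumination_gradient must be >= 0")


@dataclass
class NoiseSpec:
    kind: Literal["gaussian", "poisson"]
    snr_db: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if not math.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


def _particle_stamp(shape: str, r: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean stamp of a particle within a (2r+1)^2 window."""
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    dist = np.hypot(yy, xx)
    if shape == "disk":
        return dist <= r
    if shape == "annulus":
        return (dist <= r) & (dist >= 0.55 * r)
    # blob: disk with an angularly perturbed radius (roughly convex)
    theta = np.arctan2(yy, xx)
    k = rng.integers(2, 5)
    phase = rng.uniform(0, 2 * np.pi)
    wobble = 1.0 + 0.18 * np.sin(k * theta + phase)
    return dist <= r * wobble


def make_micrograph(spec: SceneSpec) -> tuple[Micrograph, ClassMask, ParticleSet]:
    """Render a scene; returns the image, its class mask and true centres.

    Particles are placed uniformly at random without overlap and with at
    least a 2 px margin between stamps; a bounded number of rejection
    retries is attempted before a :class:`PlacementError` is raised.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    img = np.full((h, w), BACKGROUND_LEVEL, dtype=np.float64)
    labels = np.full((h, w), CLASS_BACKGROUND, dtype=np.uint8)

    if spec.illumination_gradient > 0:
        ramp = np.linspace(0, 1, w)[None, :] * np.ones((h, 1))
        angle = rng.uniform(0, 2 * np.pi)
        gy, gx = np.sin(angle), np.cos(angle)
        ramp = (np.arange(h)[:, None] * gy + np.arange(w)[None, :] * gx)
        ramp = (ramp - ramp.min()) / max(ramp.max() - ramp.min(), 1e-12)
        img += BACKGROUND_LEVEL * spec.illumination_gradient * (ramp - 0.5)

    if spec.carbon_edge:
        band = max(2, int(round(CARBON_WIDTH_FRACTION * min(h, w))))
        img[:, :band] = CARBON_LEVEL
        labels[:, :band] = CLASS_CARBON

    r = spec.particle_radius_px
    margin = 2
    occupied = np.zeros((h, w), dtype=bool)
    occupied[labels != CLASS_BACKGROUND] = True
    centers: list[tuple[float, float]] = []
    particle_level_scale = 1.0 - spec.particle_contrast

    max_tries = 200 * max(spec.n_particles, 1)
    tries = 0
    while len(centers) < spec.n_particles:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {spec.n_particles} particles of radius {r} "
                f"in a {h}x{w} image after {max_tries} tries"
            )
        cy = int(rng.integers(r + margin, h - r - margin))
        cx = int(rng.integers(r + margin, w - r - margin))
        y0, y1 = cy - r - margin, cy + r + margin + 1
        x0, x1 = cx - r - margin, cx + r + margin + 1
        if occupied[y0:y1, x0:x1].any():
            continue
        stamp = _particle_stamp(spec.shape, r, rng)
        sy, sx = np.nonzero(stamp)
        img[cy - r + sy, cx - r + sx] *= particle_level_scale
        labels[cy - r + sy, cx - r + sx] = CLASS_PROTEIN
        occupied[y0:y1, x0:x1] = True
        centers.append((float(cx), float(cy)))

    # bright crystalline-ice blobs (may touch anything but particles)
    ice_r = max(3, int(round(1.2 * r)))
    placed_ice = 0
    tries = 0
    while placed_ice < spec.ice_blobs:
        tries += 1
        if tries > 200 * max(spec.ice_blobs, 1):
            raise PlacementError("could not place ice blobs without overlap")
        cy = int(rng.integers(ice_r, h - ice_r))
        cx = int(rng.integers(ice_r, w - ice_r))
        y0, y1 = cy - ice_r - margin, cy + ice_r + margin + 1
        x0, x1 = cx - ice_r - margin, cx + ice_r + margin + 1
        if occupied[max(y0, 0):y1, max(x0, 0):x1].any():
            continue
        yy, xx = np.mgrid[-ice_r : ice_r + 1, -ice_r : ice_r + 1]
        stamp = np.hypot(yy, xx) <= ice_r
        sy, sx = np.nonzero(stamp)
        img[cy - ice_r + sy, cx - ice_r + sx] = ICE_LEVEL
        labels[cy - ice_r + sy, cx - ice_r + sx] = CLASS_ICE
        occupied[max(y0, 0):y1, max(x0, 0):x1] = True
        placed_ice += 1

    micrograph = Micrograph(pixels=img.astype(np.float32))
    mask = ClassMask(labels=labels)
    particles = ParticleSet(
        centers=np.array(centers, dtype=float).reshape(-1, 2),
        radius_px=r,
        image_shape=(h, w),
    )
    return micrograph, mask, particles


# ---------------------------------------------------------------------------
# SNR conversions and noise injection
# ---------------------------------------------------------------------------


def db_to_linear(snr_db: float) -> float:
    """Power-ratio SNR from decibels: ``10 ** (snr_db / 10)``."""
    if not math.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    return 10.0 ** (snr_db / 10.0)


def linear_to_db(snr: float) -> float:
    """Decibels from a positive power-ratio SNR: ``10 * log10(snr)``."""
    if not (snr > 0):
        raise ValueError("snr must be > 0")
    return 10.0 * math.log10(snr)


def add_gaussian_noise(micrograph: Micrograph, spec: NoiseSpec) -> Micrograph:
    """Additive zero-mean Gaussian noise at the requested SNR (dB).

    Noise variance = Var(signal) / 10^(snr_db/10).  Values are not
    clipped internally; clipping happens only at 8-bit export.
    """
    if spec.kind != "gaussian":
        raise ValueError("spec.kind must be 'gaussian'")
    px = np.asarray(micrograph.pixels, dtype=np.float64)
    var_signal = px.var()
    if var_signal == 0:
        raise ValueError("constant image: SNR is undefined")
    sigma = math.sqrt(var_signal / db_to_linear(spec.snr_db))
    rng = np.random.default_rng(spec.seed)
    noisy = px + rng.normal(0.0, sigma, size=px.shape)
    return Micrograph(
        pixels=noisy.astype(np.float32),
        pixel_size_angstrom=micrograph.pixel_size_angstrom,
    )


def add_poisson_noise(micrograph: Micrograph, spec: NoiseSpec) -> Micrograph:
    """Poisson (shot) noise at the requested SNR (dB).

    The image is shifted to be nonnegative and scaled so the mean photon
    count gives shot-noise power Var(signal) * lam / mean(signal) equal to
    the target linear SNR; counts are sampled and rescaled back.
    """
    if spec.kind != "poisson":
        raise ValueError("spec.kind must be 'poisson'")
    px = np.asarray(micrograph.pixels, dtype=np.float64)
    shifted = px - px.min()
    mean = shifted.mean()
    var_signal = shifted.var()
    if mean == 0:
        raise ValueError("all-zero image after shifting: SNR is undefined")
    if var_signal == 0:
        raise ValueError("constant image: SNR is undefined")
    # counts = Poisson(alpha * s), rescaled back by 1/alpha: per-pixel noise
    # variance s/alpha, mean noise power mean/alpha, so SNR = alpha*var/mean.
    lam_scale = db_to_linear(spec.snr_db) * mean / var_signal
    rng = np.random.default_rng(spec.seed)
    counts = rng.poisson(shifted * lam_scale)
    noisy = counts / lam_scale + px.min()
    return Micrograph(
        pixels=noisy.astype(np.float32),
        pixel_size_angstrom=micrograph.pixel_size_angstrom,
    )


def measure_snr(clean: Micrograph, noisy: Micrograph) -> float:
    """Empirical SNR in dB: ``10*log10(Var(clean) / Var(noisy - clean))``.

    Returns ``math.inf`` when the two images are identical.
    """
    a = np.asarray(clean.pixels, dtype=np.float64)
    b = np.asarray(noisy.pixels, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    noise_var = (b - a).var()
    if noise_var == 0:
        return math.inf
    return linear_to_db(a.var() / noise_var)
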