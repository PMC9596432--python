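"""Synthetic inputs with known ground truth for every pipeline stage.

Validation runs entirely on generated inputs with known ground truth: binary fields with controllable correlation
structure, phase-contrast-like micrographs with paired ground-truth masks,
and exact offset-exponential correlation profiles for fit-recovery checks.
All generators are deterministic functions of their spec (seed mandatory).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .aggstats import CorrelationProfile
from .imaging import BinaryImage, project_points_to_binary

__all__ = [
    "FixtureSpec",
    "make_correlated_binary",
    "make_micrograph",
    "make_exponential_profile",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture.

    ``kind`` selects the generator: ``bernoulli`` (iid pixels), or
    ``smoothed_noise`` (thresholded Gaussian-filtered white noise, correlation
    length monotone in ``kernel_scale``), or ``disks`` (uniform or clustered
    disk placement), or ``micrograph`` (grayscale phase-contrast emulation).
    """

    kind: str
    size: int = 512
    seed: int = 0
    area_fraction: float = 0.3
    kernel_scale: float = 8.0
    disk_radius: float = 7.5
    n_disks: int = 30
    n_parents: int = 0  # 0 = uniform placement; > 0 = clustered around parents
    cluster_spread: float = 25.0
    noise_sd: float = 0.02
    salt_pepper: float = 0.002
    gradient_amplitude: float = 0.15

    def __post_init__(self) -> None:
        if self.kind not in ("bernoulli", "smoothed_noise", "disks", "micrograph", "profile"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if not 0.0 < self.area_fraction < 1.0:
            raise ValueError("area_fraction must be in (0, 1)")


def _disk_centers(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    L = float(spec.size)
    if spec.n_parents <= 0:
        return rng.random((spec.n_disks, 2)) * L
    parents = rng.random((spec.n_parents, 2)) * L
    which = rng.integers(0, spec.n_parents, size=spec.n_disks)
    jitter = rng.normal(scale=spec.cluster_spread, size=(spec.n_disks, 2))
    return np.mod(parents[which] + jitter, L)


def make_correlated_binary(spec: FixtureSpec) -> tuple[BinaryImage, dict]:
    """Binary field with known generative structure; returns (image, metadata)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    meta: dict = {"kind": spec.kind, "seed": spec.seed}
    if spec.kind == "bernoulli":
        img = BinaryImage(rng.random((n, n)) < spec.area_fraction, periodic=True)
        meta["p"] = spec.area_fraction
    elif spec.kind == "smoothed_noise":
        white = rng.standard_normal((n, n))
        smooth = ndimage.gaussian_filter(white, spec.kernel_scale, mode="wrap")
        thresh = np.quantile(smooth, 1.0 - spec.area_fraction)
        img = BinaryImage(smooth > thresh, periodic=True)
        meta.update(kernel_scale=spec.kernel_scale, target_fraction=spec.area_fraction)
    elif spec.kind == "disks":
        centers = _disk_centers(spec, rng)
        img = project_points_to_binary(centers, (float(n), float(n)), spec.disk_radius)
        meta.update(
            n_disks=spec.n_disks, disk_radius=spec.disk_radius,
            n_parents=spec.n_parents, centers=centers,
        )
    else:
        raise ValueError(f"kind {spec.kind!r} is not a binary-field generator")
    meta["area_fraction"] = img.area_fraction
    return img, meta


def make_micrograph(spec: FixtureSpec) -> tuple[np.ndarray, BinaryImage]:
    """Phase-contrast-like grayscale image plus its ground-truth mask.

    Cell bodies are dark disks (~15 px across at a 100x / 0.065 um-per-px
    scale for 1 um cocci) with a bright halo ring on a bright background; the
    clean render is degraded by a multiplicative illumination gradient,
    additive Gaussian noise, and salt-and-pepper outliers.  The ground truth
    is the noise-free disk mask itself.
    """
    if spec.kind != "micrograph":
        raise ValueError("spec.kind must be 'micrograph'")
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    centers = _disk_centers(spec, rng)
    mask = project_points_to_binary(
        centers, (float(n), float(n)), spec.disk_radius
    )
    truth = BinaryImage(mask.pixels.copy(), periodic=False)
    halo = project_points_to_binary(
        centers, (float(n), float(n)), spec.disk_radius + 2.0
    ).pixels & ~mask.pixels
    clean = np.full((n, n), 0.75)
    clean[mask.pixels] = 0.30
    clean[halo] = 0.88
    if spec.gradient_amplitude > 0:
        yy, xx = np.meshgrid(np.linspace(-1, 1, n), np.linspace(-1, 1, n), indexing="ij")
        clean = clean * (1.0 + spec.gradient_amplitude * 0.5 * (xx + 0.6 * yy))
    noisy = clean + rng.normal(scale=spec.noise_sd, size=clean.shape)
    if spec.salt_pepper > 0:
        u = rng.random(clean.shape)
        noisy[u < spec.salt_pepper] = clean.min()
        noisy[u > 1.0 - spec.salt_pepper] = clean.max()
    return np.clip(noisy, 0.0, 1.2), truth


def make_exponential_profile(
    C_inf: float,
    a: float,
    r_max: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    pair_count: float = 1.0e4,
) -> CorrelationProfile:
    """Exact offset-exponential profile, optionally with Gaussian noise.

    Used for fit-recovery calibration: the model is evaluated on integer
    radii 0..r_max; ``C(0) = 1`` exactly by construction.
    """
    if not 0.0 <= C_inf < 1.0:
        raise ValueError("C_inf must be in [0, 1)")
    if a <= 0:
        raise ValueError("a must be positive")
    r = np.arange(0.0, float(r_max) + 0.5)
    C = C_inf + (1.0 - C_inf) * np.exp(-r / a)
    if noise_sd > 0:
        C = C + np.random.default_rng(seed).normal(scale=noise_sd, size=C.shape)
    return CorrelationProfile(r, C, np.full(r.shape, float(pair_count)))
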