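"""Cell geometry and pair interactions.

A cell is a rigid body: one large body sphere (the ``B`` atom, radius
``sigma_B``) decorated with ``n_adhesins`` small adhesin spheres (``P`` atoms,
radius ``sigma_P``) whose centers sit on a sphere of radius
``sigma_B + sigma_P`` around the body center, i.e. tangent to the body
surface.  Two placement patterns are supported:

``localized``
    adhesins hexagonally close-packed into a patch on one side of the body
    (the wild-type polar/long-axis arrangement),
``dispersed``
    adhesins spread near-uniformly over the whole surface (the mutant with
    delocalized pili).

Interactions between atoms of *different* cells:

* body-body and body-adhesin pairs repel through a truncated, shifted
  Lennard-Jones (WCA-type) potential
  ``E(r) = eps + 4 eps [ (s/r)^12 - (s/r)^6 ]`` for ``r < 2^(1/6) s`` with
  ``s = sigma_X + sigma_Y``, zero beyond;
* adhesin-adhesin pairs bind through a soft cosine well
  ``E(r) = A [1 + cos(pi r / r_c)]`` for ``r < r_c``, zero beyond, with
  binding strength ``A <= 0`` (``A = -8`` for adhesive strains, ``A = 0``
  for the non-adhesive control).

Both potentials and their first derivatives vanish continuously at their
cutoffs, so forces are smooth everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Pattern",
    "PairPotentialParams",
    "CellTemplate",
    "GeometricInfeasibilityError",
    "build_cell_template",
    "pair_energy_repulsive",
    "pair_energy_adhesin",
    "pair_force",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class Pattern(str, Enum):
    """Adhesin placement pattern."""

    LOCALIZED = "localized"
    DISPERSED = "dispersed"


class GeometricInfeasibilityError(ValueError):
    """Requested adhesin count cannot be placed without sphere overlap."""


@dataclass(frozen=True)
class PairPotentialParams:
    """Interaction parameters in simulation units (adhesin radius = 1, kBT = 1).

    Attributes
    ----------
    sigma_B : float
        Body-sphere radius.
    sigma_P : float
        Adhesin-sphere radius; defines the unit of length.
    epsilon : float
        Repulsion energy scale of the truncated-shifted LJ pairs.
    A : float
        Adhesin-adhesin binding strength, ``A <= 0`` (0 disables binding).
    r_c : float
        Adhesin-adhesin cutoff of the cosine well.
    """

    sigma_B: float = 5.0
    sigma_P: float = 1.0
    epsilon: float = 1.0
    A: float = -8.0
    r_c: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_P <= 0 or self.sigma_B <= self.sigma_P:
            raise ValueError("require sigma_B > sigma_P > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.A > 0:
            raise ValueError("binding strength A must be <= 0")
        if self.r_c <= 0:
            raise ValueError("r_c must be positive")

    @property
    def contact_radius(self) -> float:
        """Distance of adhesin centers from the body center (tangent spheres)."""
        return self.sigma_B + self.sigma_P


@dataclass(frozen=True)
class CellTemplate:
    """Rigid-body local geometry of one cell (body frame, body center at origin)."""

    pattern: Pattern
    n_adhesins: int
    local_coords: np.ndarray  # (n_adhesins, 3)
    contact_radius: float

    def __post_init__(self) -> None:
        coords = np.asarray(self.local_coords, dtype=float)
        if coords.shape != (self.n_adhesins, 3):
            raise ValueError("local_coords must have shape (n_adhesins, 3)")
        object.__setattr__(self, "local_coords", coords)
        radii = np.linalg.norm(coords, axis=1)
        if not np.allclose(radii, self.contact_radius, atol=1e-9):
            raise ValueError("all adhesin centers must lie at contact_radius")


def _hex_lattice_points(n: int) -> np.ndarray:
    """First ``n`` points of the unit-spacing planar hexagonal lattice.

    Points are ordered by distance from the origin (angle as tie-break), so
    n = 1, 7, 19 give the closed shells 1, 1+6, 1+6+12.
    """
    m = 4 + int(np.ceil(np.sqrt(n)))
    pts = []
    for a in range(-m, m + 1):
        for b in range(-m, m + 1):
            x = a + 0.5 * b
            y = (np.sqrt(3.0) / 2.0) * b
            pts.append((x, y))
    pts = np.array(pts)
    r = np.hypot(pts[:, 0], pts[:, 1])
    ang = np.arctan2(pts[:, 1], pts[:, 0])
    order = np.lexsort((ang, np.round(r, 12)))
    return pts[order][:n]


def _project_patch(lattice: np.ndarray, spacing: float, radius: float) -> np.ndarray:
    """Azimuthal-equidistant wrap of a planar patch onto a sphere.

    A planar point at distance ``rho`` from the patch center maps to polar
    angle ``rho / radius`` from the +z pole, preserving arc length radially.
    """
    xy = lattice * spacing
    rho = np.hypot(xy[:, 0], xy[:, 1])
    theta = rho / radius
    if np.any(theta >= np.pi):
        raise GeometricInfeasibilityError("patch wraps past the antipode")
    phi = np.arctan2(xy[:, 1], xy[:, 0])
    sin_t = np.sin(theta)
    return radius * np.column_stack(
        (sin_t * np.cos(phi), sin_t * np.sin(phi), np.cos(theta))
    )


def _min_pairwise_distance(coords: np.ndarray) -> float:
    if len(coords) < 2:
        return np.inf
    d = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(d, axis=-1)
    iu = np.triu_indices(len(coords), k=1)
    return float(dist[iu].min())


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform unit-sphere point set (Fibonacci spiral)."""
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    phi = k * _GOLDEN_ANGLE
    return np.column_stack((rho * np.cos(phi), rho * np.sin(phi), z))


def _relax_on_sphere(points: np.ndarray, n_iter: int = 200, step: float = 0.05) -> np.ndarray:
    """Deterministic pairwise-repulsion relaxation constrained to the unit sphere.

    Pushes points toward the maximin (Tammes-like) arrangement; inverse-square
    repulsion, tangent-projected gradient steps, renormalization each sweep.
    """
    p = points.copy()
    n = len(p)
    if n < 2:
        return p
    for _ in range(n_iter):
        diff = p[:, None, :] - p[None, :, :]
        d2 = np.sum(diff * diff, axis=-1)
        np.fill_diagonal(d2, np.inf)
        force = np.sum(diff / (d2[..., None] ** 1.5), axis=1)
        # project onto tangent plane
        force -= p * np.sum(force * p, axis=1, keepdims=True)
        p = p + step * force / n
        p /= np.linalg.norm(p, axis=1, keepdims=True)
    return p


def build_cell_template(
    pattern: Pattern | str,
    params: PairPotentialParams | None = None,
    n_adhesins: int = 19,
) -> CellTemplate:
    """Construct the rigid local geometry of a cell.

    For ``localized``, a hexagonal patch (closed shells 1/6/12 for n = 19)
    is wrapped onto the contact sphere around the +z pole, with the lattice
    spacing chosen (bisection, deterministic) as the smallest spacing at
    which no two adhesin spheres overlap — "closely packed" means tangent.
    For ``dispersed``, a Fibonacci-spiral point set is relaxed by pairwise
    repulsion on the sphere, giving a near-uniform covering.

    Raises
    ------
    GeometricInfeasibilityError
        if ``n_adhesins`` spheres cannot be placed without overlap.
    """
    params = params or PairPotentialParams()
    pattern = Pattern(pattern)
    if n_adhesins < 1:
        raise ValueError("n_adhesins must be >= 1")
    R = params.contact_radius
    d_min = 2.0 * params.sigma_P

    if n_adhesins == 1:
        coords = np.array([[0.0, 0.0, R]])
    elif pattern is Pattern.LOCALIZED:
        lattice = _hex_lattice_points(n_adhesins)
        lo, hi = d_min, 4.0 * params.sigma_P
        # min pairwise distance grows monotonically with spacing
        if _min_pairwise_distance(_project_patch(lattice, hi, R)) < d_min:
            raise GeometricInfeasibilityError(
                f"cannot place {n_adhesins} adhesins as a patch at contact radius {R}"
            )
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if _min_pairwise_distance(_project_patch(lattice, mid, R)) < d_min:
                lo = mid
            else:
                hi = mid
        coords = _project_patch(lattice, hi, R)
    else:
        # hex-packing bound on spherical caps: even perfect packing cannot
        # place more than ~4 (R/sigma_P)^2 tangent spheres; reject early so
        # absurd counts fail fast instead of after a full relaxation
        if n_adhesins > int(np.ceil(4.0 * (R / params.sigma_P) ** 2)):
            raise GeometricInfeasibilityError(
                f"cannot place {n_adhesins} non-overlapping adhesins at contact radius {R}"
            )
        unit = _relax_on_sphere(_fibonacci_sphere(n_adhesins))
        coords = R * unit
        if _min_pairwise_distance(coords) < d_min - 1e-9:
            raise GeometricInfeasibilityError(
                f"cannot place {n_adhesins} non-overlapping adhesins at contact radius {R}"
            )
    return CellTemplate(
        pattern=pattern,
        n_adhesins=n_adhesins,
        local_coords=coords,
        contact_radius=R,
    )


def pair_energy_repulsive(r, sigma_X: float, sigma_Y: float, epsilon: float = 1.0):
    """Truncated-shifted LJ repulsion between spheres of radii sigma_X, sigma_Y.

    ``E = eps + 4 eps [ (s/r)^12 - (s/r)^6 ]`` for ``r < 2^(1/6) s`` (with
    ``s = sigma_X + sigma_Y``), zero beyond; continuous with zero slope at
    the cutoff.  Accepts scalars or arrays; ``r`` must be positive.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    s = sigma_X + sigma_Y
    cutoff = 2.0 ** (1.0 / 6.0) * s
    sr6 = (s / r) ** 6
    e = epsilon + 4.0 * epsilon * (sr6 * sr6 - sr6)
    out = np.where(r < cutoff, e, 0.0)
    return float(out) if out.ndim == 0 else out


def pair_energy_adhesin(r, A: float = -8.0, r_c: float = 1.0):
    """Soft cosine binding well between two adhesins.

    ``E = A [1 + cos(pi r / r_c)]`` for ``r < r_c``, zero beyond.  Deepest
    (``2A``) at full overlap r = 0; no short-range repulsion, so bound
    adhesins sit coincident.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation must be non-negative")
    e = A * (1.0 + np.cos(np.pi * r / r_c))
    out = np.where(r < r_c, e, 0.0)
    return float(out) if out.ndim == 0 else out


def _repulsive_force_mag(r: float, s: float, epsilon: float) -> float:
    """-dE/dr of the truncated-shifted LJ (positive = repulsive)."""
    cutoff = 2.0 ** (1.0 / 6.0) * s
    if r >= cutoff:
        return 0.0
    sr6 = (s / r) ** 6
    return 24.0 * epsilon * (2.0 * sr6 * sr6 - sr6) / r


def _adhesin_force_mag(r: float, A: float, r_c: float) -> float:
    """-dE/dr of the cosine well (negative = attractive for A < 0)."""
    if r >= r_c or r == 0.0:
        return 0.0
    return A * np.pi / r_c * np.sin(np.pi * r / r_c)


def pair_force(
    r_vec: np.ndarray,
    kind: str,
    params: PairPotentialParams | None = None,
    f_cap: float | None = None,
) -> np.ndarray:
    """Force on the first atom of a pair separated by ``r_vec`` (first -> second).

    ``kind`` is one of ``"BB"``, ``"BP"``, ``"PP"``.  The force is the exact
    analytic gradient of the corresponding pair energy, antisymmetric under
    ``r_vec -> -r_vec``, and vanishes continuously at each cutoff.  For the
    repulsive kinds a zero separation is singular: it raises unless ``f_cap``
    is given, in which case the magnitude is clamped to ``f_cap``.
    """
    params = params or PairPotentialParams()
    r_vec = np.asarray(r_vec, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if kind == "PP":
        mag = _adhesin_force_mag(r, params.A, params.r_c)
        if r == 0.0:
            return np.zeros(3)
    elif kind in ("BB", "BP"):
        if r == 0.0:
            if f_cap is None:
                raise ValueError(f"zero separation is singular for {kind} pair")
            return np.array([f_cap, 0.0, 0.0])
        s = (
            2.0 * params.sigma_B
            if kind == "BB"
            else params.sigma_B + params.sigma_P
        )
        mag = _repulsive_force_mag(r, s, params.epsilon)
    else:
        raise ValueError(f"unknown pair kind {kind!r}")
    if f_cap is not None and abs(mag) > f_cap:
        mag = np.sign(mag) * f_cap
    # repulsive (mag > 0) pushes atom 1 along -r_hat, away from atom 2
    return -mag * r_vec / max(r, 1e-300)
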