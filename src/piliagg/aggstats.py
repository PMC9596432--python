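"""Aggregate-size statistic from binary images, plus a particle-space oracle.

The size of multicellular aggregates is quantified from the occupancy field
``phi`` through its normalized spatial autocorrelation

    C(r) = <phi(0) phi(r)> / <phi^2>,

averaged over all pixel pairs and radially binned, then fitted with an
offset exponential ``C(r) = C_inf + (1 - C_inf) exp(-r/a)``.  The reported
aggregate size is ``2a``, twice the correlation length.  For binary fields
``C(0) = 1`` identically and ``C(r -> inf) -> <phi>``, so ``C_inf``
approximates the foreground area fraction.

``cluster_cells`` is an independent particle-space cross-check: connected
components of the adhesin contact graph (inter-cell adhesin pairs closer
than the binding cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .imaging import BinaryImage

__all__ = [
    "CorrelationProfile",
    "CorrelationFit",
    "AggregateSizeResult",
    "UndefinedNormalizationError",
    "autocorrelation",
    "fit_correlation",
    "aggregate_size",
    "cluster_cells",
]


class UndefinedNormalizationError(ValueError):
    """Autocorrelation of an all-zero image: <phi^2> = 0."""


@dataclass
class CorrelationProfile:
    """Radially averaged autocorrelation with per-bin pair counts."""

    r: np.ndarray
    C: np.ndarray
    pair_count: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.pair_count = np.asarray(self.pair_count, dtype=float)
        if not (len(self.r) == len(self.C) == len(self.pair_count)):
            raise ValueError("r, C, pair_count must have equal length")
        if np.any(~np.isfinite(self.C)):
            raise ValueError("C values must be finite")


@dataclass
class CorrelationFit:
    """Fitted offset-exponential parameters and diagnostics."""

    C_inf: float
    a: float
    covariance: np.ndarray | None
    converged: bool
    message: str = ""


@dataclass
class AggregateSizeResult:
    """Aggregate size 2a with full fit provenance."""

    size: float  # = 2 * fit.a
    fit: CorrelationFit
    metadata: dict = field(default_factory=dict)


def _radial_bins(shape: tuple[int, int], periodic: bool) -> np.ndarray:
    """Integer radial bin index (rounded lag magnitude) for each FFT lag."""
    ny, nx = shape
    if periodic:
        ly = np.minimum(np.arange(ny), ny - np.arange(ny))
        lx = np.minimum(np.arange(nx), nx - np.arange(nx))
    else:
        ly = np.abs(np.fft.fftfreq(ny, 1.0 / ny))
        lx = np.abs(np.fft.fftfreq(nx, 1.0 / nx))
    r = np.hypot(ly[:, None], lx[None, :])
    return np.rint(r).astype(np.int64)


def autocorrelation(image: BinaryImage, max_r: float | None = None) -> CorrelationProfile:
    """Radially averaged ``C(r)`` of a binary image, computed by FFT.

    Periodic images use circular correlation (every lag has N pixel pairs);
    non-periodic images use zero-padded correlation with per-lag valid-pair
    normalization.  Lags are binned into unit-pixel radial shells (bin =
    rounded lag magnitude), pair-count weighted; radii are returned in
    physical units (``pixel_size`` per pixel).
    """
    phi = image.pixels.astype(float)
    n_pix = phi.size
    mean_sq = phi.mean()  # <phi^2> = <phi> for binary fields
    if mean_sq == 0.0:
        raise UndefinedNormalizationError("all-zero image: <phi^2> = 0")
    ny, nx = phi.shape
    if image.periodic:
        fhat = np.fft.rfft2(phi)
        num = np.fft.irfft2(fhat * np.conj(fhat), s=phi.shape)  # sum phi(x)phi(x+r)
        cnt = np.full(phi.shape, float(n_pix))
    else:
        shape = (2 * ny - 1, 2 * nx - 1)
        fhat = np.fft.rfft2(phi, s=shape)
        num_full = np.fft.irfft2(fhat * np.conj(fhat), s=shape)
        ones = np.fft.rfft2(np.ones_like(phi), s=shape)
        cnt_full = np.fft.irfft2(ones * np.conj(ones), s=shape)
        num, cnt = num_full, cnt_full
    bins = _radial_bins(num.shape, image.periodic)
    n_bins = bins.max() + 1
    num_b = np.bincount(bins.ravel(), weights=num.ravel(), minlength=n_bins)
    cnt_b = np.bincount(bins.ravel(), weights=cnt.ravel(), minlength=n_bins)
    r = np.arange(n_bins, dtype=float)
    keep = cnt_b > 0.5
    if max_r is not None:
        keep &= r * image.pixel_size <= max_r
    r = r[keep]
    # pair-weighted radial average of <phi(0)phi(r)>, then normalize
    C = (num_b[keep] / cnt_b[keep]) / mean_sq
    return CorrelationProfile(
        r * image.pixel_size, C, cnt_b[keep], image.pixel_size
    )


def _model(r: np.ndarray, C_inf: float, a: float) -> np.ndarray:
    return C_inf + (1.0 - C_inf) * np.exp(-r / a)


def fit_correlation(
    profile: CorrelationProfile,
    fit_range: tuple[float, float] | None = None,
    min_pairs: float = 100.0,
    a_bounds: tuple[float, float] | None = None,
) -> CorrelationFit:
    """Weighted least-squares fit of ``C_inf + (1 - C_inf) exp(-r/a)``.

    Bins outside ``fit_range`` or with fewer than ``min_pairs`` pixel pairs
    are excluded; weights scale with ``sqrt(pair_count)``.  Initial guesses:
    ``C_inf`` from the large-r plateau, ``a`` from the first 1/e crossing.
    Non-convergence or a parameter pinned at its bound is flagged, never
    silently returned as success.
    """
    r, C, w = profile.r, profile.C, profile.pair_count
    sel = w >= min_pairs
    if fit_range is not None:
        sel &= (r >= fit_range[0]) & (r <= fit_range[1])
    r, C, w = r[sel], C[sel], w[sel]
    if len(r) < 4:
        raise ValueError("need at least 4 usable radii to fit")
    if a_bounds is None:
        a_bounds = (0.1 * profile.pixel_size, float(r.max()) * 4.0)
    n_tail = max(len(r) // 4, 1)
    c0 = float(np.clip(np.mean(C[-n_tail:]), 0.0, 0.998))
    thresh = c0 + (1.0 - c0) / np.e
    below = np.nonzero(C < thresh)[0]
    a0 = float(r[below[0]]) if len(below) and r[below[0]] > 0 else float(r.max()) / 4.0
    a0 = float(np.clip(a0, a_bounds[0] * 1.01, a_bounds[1] * 0.99))
    sigma = 1.0 / np.sqrt(np.maximum(w, 1.0))
    try:
        popt, pcov = optimize.curve_fit(
            _model, r, C, p0=(c0, a0),
            bounds=([0.0, a_bounds[0]], [0.999, a_bounds[1]]),
            sigma=sigma, maxfev=10_000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        return CorrelationFit(np.nan, np.nan, None, False, f"fit failed: {exc}")
    C_inf, a = float(popt[0]), float(popt[1])
    converged = True
    message = "ok"
    rel = 1e-6
    if a <= a_bounds[0] * (1 + rel) or a >= a_bounds[1] * (1 - rel):
        converged, message = False, "correlation length pinned at bound"
    if C_inf >= 0.999 * (1 - rel):
        converged, message = False, "offset pinned at bound (flat profile?)"
    if not np.all(np.isfinite(pcov)):
        converged, message = False, "singular covariance"
    return CorrelationFit(C_inf, a, pcov, converged, message)


def aggregate_size(
    image: BinaryImage,
    fit_range: tuple[float, float] | None = None,
    max_r: float | None = None,
    min_pairs: float = 100.0,
    metadata: dict | None = None,
) -> AggregateSizeResult:
    """Full image-to-size pipeline: autocorrelate, fit, report ``2a``.

    Default fit range is ``[0, min(L/4, 150 px)]`` (in physical units), which
    keeps boundary-starved bins out of the fit.
    """
    ny, nx = image.shape
    if fit_range is None:
        fit_range = (0.0, min(min(ny, nx) / 4.0, 150.0) * image.pixel_size)
    profile = autocorrelation(image, max_r=max_r if max_r is not None else fit_range[1])
    fit = fit_correlation(profile, fit_range=fit_range, min_pairs=min_pairs)
    meta = dict(metadata or {})
    meta.update(
        fit_range=fit_range, min_pairs=min_pairs,
        area_fraction=image.area_fraction, n_pixels=image.pixels.size,
        weighting="sqrt(pair_count)",
    )
    return AggregateSizeResult(size=2.0 * fit.a, fit=fit, metadata=meta)


def cluster_cells(
    state, template, r_c: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Contact clusters: union of cells linked by close adhesin pairs.

    Two cells are linked when any inter-cell adhesin pair is closer than
    ``r_c`` (minimum image).  Returns ``(labels, sizes)`` where ``labels[i]``
    is the cluster id of cell i and ``sizes`` the cluster size histogram
    (sizes[k] = number of cells in cluster k).
    """
    N = state.n_cells
    na = template.n_adhesins
    coords = state.adhesin_world_coords(template).reshape(N * na, 3)
    box = np.asarray(state.box, dtype=float)
    coords = np.mod(coords, box)
    # guard against coordinates landing exactly on the upper boundary
    coords = np.where(coords >= box, 0.0, coords)
    tree = cKDTree(coords, boxsize=box)
    pairs = tree.query_pairs(r_c, output_type="ndarray")
    if len(pairs):
        ci = pairs[:, 0] // na
        cj = pairs[:, 1] // na
        inter = ci != cj
        rows, cols = ci[inter], cj[inter]
    else:
        rows = cols = np.empty(0, dtype=np.int64)
    graph = coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(N, N)
    )
    n_comp, labels = connected_components(graph, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    return labels, sizes
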