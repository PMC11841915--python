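"""Spatial statistics of phase point patterns on the hexagonal torus.

Phases of a grid module live on the hexagonal unit cell with periodic
boundaries.  This module quantifies their arrangement: Ripley's K/H
functions with periodic (tiling) edge correction, a Monte-Carlo CSR
baseline with significance bands, a permutation test for group differences,
wrapped-Gaussian kernel density estimates, a rotational grid score of the
phase density, and a direct hexagon fit for seven-phase solutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import UnitCellGeometry, hex_cdist, hex_mesh, sample_uniform, wrap

__all__ = [
    "RipleyCurve",
    "KDEMap",
    "HexagonFit",
    "default_ripley_radii",
    "ripley_k",
    "ripley_h",
    "csr_baseline",
    "attach_baseline",
    "permutation_test",
    "phase_kde",
    "kde_grid_score",
    "fit_hexagon",
]


@dataclass(frozen=True)
class RipleyCurve:
    """Ripley H values over radii, optionally with a CSR baseline ensemble."""

    radii: np.ndarray
    H: np.ndarray
    K: np.ndarray
    baseline: np.ndarray | None = None  # (n_trials, n_radii) H curves
    significant: np.ndarray | None = None  # per-radius flags vs the baseline band

    def __post_init__(self):
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")


@dataclass(frozen=True)
class KDEMap:
    """Gaussian phase density on an evaluation grid (absolute bandwidth)."""

    points: np.ndarray
    values: np.ndarray
    bandwidth: float
    normalised: bool = True


def default_ripley_radii(cell: UnitCellGeometry, n: int = 20) -> np.ndarray:
    """n evenly spaced radii up to, but not including, the circumradius."""
    return cell.circumradius * np.arange(1, n + 1) / (n + 1)


def _tiled(phases: np.ndarray, cell: UnitCellGeometry, rings: int = 1) -> np.ndarray:
    """Wrapped phases copied to the lattice tiles within ``rings`` rings."""
    w = wrap(phases, cell)
    a1, a2 = cell.lattice_vectors
    tiles = []
    for m1 in range(-rings, rings + 1):
        for m2 in range(-rings, rings + 1):
            tiles.append(w + m1 * a1 + m2 * a2)
    return np.vstack(tiles)


def ripley_k(
    phases: np.ndarray, radii: np.ndarray, cell: UnitCellGeometry
) -> np.ndarray:
    """Ripley K with periodic edge correction by neighbour duplication.

    Phases are wrapped and copied to the six adjacent unit cells; for each
    radius, ``K = |cell| / (N (N-1)) * (sum_i B(phi_i, eps) - N)`` where B
    counts the (duplicated) points within the ball around each original
    phase, self-counts removed.
    """
    phases = np.atleast_2d(phases)
    N = len(phases)
    if N < 2:
        raise ValueError("Ripley statistics require at least 2 phases")
    w = wrap(phases, cell)
    copies = (w[None, :, :] + cell.torus_translates[:, None, :]).reshape(-1, 2)
    d = np.linalg.norm(w[:, None, :] - copies[None, :, :], axis=2)  # (N, 7N)
    counts = (d[:, :, None] <= radii[None, None, :]).sum(axis=(0, 1)) - N
    return cell.area / (N * (N - 1)) * counts


def ripley_h(
    phases: np.ndarray,
    radii: np.ndarray | None = None,
    cell: UnitCellGeometry | None = None,
) -> RipleyCurve:
    """Ripley H: ``sqrt(K / pi) - eps`` (zero-mean under CSR).

    Negative values indicate dispersion (fewer close pairs than random),
    positive values clustering.
    """
    from .geometry import WaveBasis, make_unit_cell

    cell = cell or make_unit_cell(WaveBasis())
    radii = default_ripley_radii(cell) if radii is None else np.asarray(radii)
    K = ripley_k(phases, radii, cell)
    return RipleyCurve(radii, np.sqrt(K / np.pi) - radii, K)


def csr_baseline(
    n_phases: int,
    radii: np.ndarray,
    cell: UnitCellGeometry,
    n_trials: int = 100,
    seed: int | None = 0,
) -> np.ndarray:
    """H curves of ``n_trials`` uniform (CSR) phase sets, shape (trials, radii)."""
    rng = np.random.default_rng(seed)
    out = np.empty((n_trials, len(radii)))
    for t in range(n_trials):
        ph = sample_uniform(n_phases, cell, rng)
        out[t] = np.sqrt(ripley_k(ph, radii, cell) / np.pi) - radii
    return out


def attach_baseline(
    curve: RipleyCurve, baseline: np.ndarray, n_sd: float = 2.0
) -> RipleyCurve:
    """Flag radii where the curve leaves the baseline mean +/- n_sd band."""
    mu, sd = baseline.mean(axis=0), baseline.std(axis=0)
    sig = np.abs(curve.H - mu) > n_sd * sd
    return RipleyCurve(curve.radii, curve.H, curve.K, baseline, sig)


def permutation_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_perms: int = 1000,
    alpha: float = 0.01,
    seed: int | None = 0,
) -> tuple[float, bool]:
    """Two-sided permutation test on the difference of group means.

    Pools both groups, redraws the group labels ``n_perms`` times and
    returns the two-sided percentile of the observed mean difference plus
    the rejection flag at ``alpha``.  Deterministic given ``seed``.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    obs = a.mean() - b.mean()
    pool = np.concatenate([a, b])
    na = len(a)
    hits = 0
    for _ in range(n_perms):
        perm = rng.permutation(pool)
        stat = perm[:na].mean() - perm[na:].mean()
        if abs(stat) >= abs(obs) - 1e-15:
            hits += 1
    p = (hits + 1) / (n_perms + 1)
    return float(p), bool(p < alpha)


def _wrapped_gaussian_density(
    points: np.ndarray,
    phases: np.ndarray,
    bandwidth: float,
    cell: UnitCellGeometry,
    rings: int = 2,
) -> np.ndarray:
    """Gaussian KDE over phases duplicated to a ``rings``-ring tiling.

    The bandwidth is the kernel standard deviation in absolute length
    units; the duplication (default a double tiling) approximates the
    wrapped-Gaussian kernel of the torus.
    """
    tiles = _tiled(phases, cell, rings)
    pts = np.atleast_2d(points)
    k = np.empty(len(pts))
    step = max(1, int(4e6 / max(len(tiles), 1)))  # bound temporary size
    for lo in range(0, len(pts), step):
        chunk = pts[lo : lo + step]
        d2 = ((chunk[:, None, :] - tiles[None, :, :]) ** 2).sum(axis=2)
        k[lo : lo + len(chunk)] = np.exp(-0.5 * d2 / bandwidth**2).sum(axis=1)
    return k / (2.0 * np.pi * bandwidth**2 * len(np.atleast_2d(phases)))


def phase_kde(
    phases: np.ndarray,
    bandwidth: float,
    points: np.ndarray,
    cell: UnitCellGeometry,
    rings: int = 2,
    normalise: bool = True,
) -> KDEMap:
    """Phase density at the requested points, unit integral within the cell.

    Normalisation uses a quasi-uniform quadrature mesh over the hexagon, so
    the returned values integrate to one over the unit cell (within mesh
    accuracy) regardless of the evaluation grid.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    vals = _wrapped_gaussian_density(points, phases, bandwidth, cell, rings)
    if normalise:
        quad = hex_mesh(64, cell)
        integral = (
            _wrapped_gaussian_density(quad, phases, bandwidth, cell, rings).mean()
            * cell.area
        )
        vals = vals / integral
    return KDEMap(np.atleast_2d(points), vals, bandwidth, normalise)


def _pearson_valid_correlate(small: np.ndarray, large: np.ndarray) -> np.ndarray:
    """Sliding-window Pearson correlation of ``small`` against ``large``."""
    from scipy.signal import fftconvolve

    tpl = small - small.mean()
    n = small.size
    flip = tpl[::-1, ::-1]
    s_xy = fftconvolve(large, flip, mode="valid")
    ones = np.ones_like(small)
    s_y = fftconvolve(large, ones[::-1, ::-1], mode="valid")
    s_yy = fftconvolve(large * large, ones[::-1, ::-1], mode="valid")
    var_y = s_yy - s_y**2 / n
    var_x = (tpl**2).sum()
    denom = np.sqrt(np.maximum(var_x * var_y, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = s_xy / denom
    return np.nan_to_num(corr, nan=0.0)


def _rotational_score(acorr: np.ndarray, mask: np.ndarray) -> float:
    """Mean 60/120/180-degree correlation minus mean 30/90/150-degree."""
    base = acorr[mask]
    if base.std() == 0:
        return 0.0
    corrs = {}
    for ang in (30, 60, 90, 120, 150, 180):
        rot = ndimage.rotate(acorr, ang, reshape=False, order=1)
        rmask = ndimage.rotate(mask.astype(float), ang, reshape=False, order=1) > 0.5
        both = mask & rmask
        x, y = acorr[both], rot[both]
        if len(x) < 8 or x.std() == 0 or y.std() == 0:
            corrs[ang] = 0.0
        else:
            corrs[ang] = float(np.corrcoef(x, y)[0, 1])
    return float(
        np.mean([corrs[60], corrs[120], corrs[180]])
        - np.mean([corrs[30], corrs[90], corrs[150]])
    )


def kde_grid_score(
    phases: np.ndarray, bandwidth: float, cell: UnitCellGeometry
) -> float:
    """Hexagonality score of the phase density.

    The phase KDE is evaluated on a 64x64 grid over ``[-r, r]^2`` and a
    127x127 grid over ``[-3r/2, 3r/2]^2`` (r = circumradius); their
    valid-mode sliding Pearson correlation gives a 64x64 autocorrelogram
    interpreted on the unit-cell enclosing square.  An annulus mask (outer
    radius r, inner radius the kernel bandwidth) selects the first ring of
    density peaks, and the score contrasts rotational correlations at
    hexagonal angles (60/120/180 degrees) with off angles (30/90/150).
    Positive scores indicate hexagonal arrangement; this differs from
    conventional ratemap gridness scores by including 180 degrees in the
    peak group.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    r = cell.circumradius
    # one shared pixel scale: the 64-pixel window spans the cell's minimum
    # enclosing square [-r, r]; the 127-pixel map extends it so that the
    # valid-mode correlation yields displacements covering that same square.
    px = 2.0 * r / 64.0
    ax_l = (np.arange(127) - 63) * px
    large_pts = np.stack(np.meshgrid(ax_l, ax_l, indexing="ij"), -1).reshape(-1, 2)
    large = _wrapped_gaussian_density(large_pts, phases, bandwidth, cell).reshape(127, 127)
    small = large[32:96, 32:96]  # central 64x64 window
    acorr = _pearson_valid_correlate(small, large)
    # crop to 63x63 so zero displacement sits exactly on the rotation centre
    acorr = acorr[1:, 1:]
    ax = (np.arange(63) - 31) * px
    dx, dy = np.meshgrid(ax, ax, indexing="ij")
    rho = np.hypot(dx, dy)
    mask = (rho >= bandwidth) & (rho <= r)
    return _rotational_score(acorr, mask)


@dataclass(frozen=True)
class HexagonFit:
    centre: np.ndarray
    radius: float
    angle: float  # radians, circular mean with 60-degree period
    residual: float

    @property
    def angle_folded_deg(self) -> float:
        """Angle folded into [0, 30] degrees (hexagon mirror symmetry)."""
        a = np.degrees(self.angle) % 60.0
        return float(min(a, 60.0 - a))


def fit_hexagon(phases: np.ndarray, cell: UnitCellGeometry) -> HexagonFit:
    """Fit centre + hexagon to exactly seven phases on the torus.

    The centre is the phase minimising the summed torus distance to the
    others; the radius is the mean distance from the centre to the six
    remaining phases, and the angle the 60-degree-periodic circular mean of
    their bearings (measured in the pattern frame, so 0 points at a
    unit-cell vertex).
    """
    phases = np.atleast_2d(phases)
    if len(phases) != 7:
        raise ValueError("hexagon fit expects exactly 7 phases")
    w = wrap(phases, cell)
    D = hex_cdist(w, w, cell)
    if np.any(D[~np.eye(7, dtype=bool)] < 1e-12):
        raise ValueError("degenerate phase set (coincident phases)")
    ci = int(np.argmin(D.sum(axis=1)))
    centre = w[ci]
    others = np.delete(w, ci, axis=0)
    # torus displacement: nearest translate of each outer phase to the centre
    t7 = cell.torus_translates
    cand = others[:, None, :] + t7[None, :, :] - centre[None, None, :]
    k = np.argmin(np.linalg.norm(cand, axis=2), axis=1)
    disp = cand[np.arange(6), k]
    radii = np.linalg.norm(disp, axis=1)
    bearings = np.arctan2(disp[:, 1], disp[:, 0]) - cell.orientation_offset
    mean_angle = np.angle(np.exp(1j * 6.0 * bearings).mean()) / 6.0
    radius = float(radii.mean())
    ang_dev = np.angle(np.exp(1j * 6.0 * (bearings - mean_angle))) / 6.0
    residual = float(
        np.sqrt(np.mean((radii - radius) ** 2 + (radius * ang_dev) ** 2))
    )
    return HexagonFit(centre, radius, float(mean_angle), residual)
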