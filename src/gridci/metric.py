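"""Metric tensors of the population map and conformal-isometry objectives.

The population map r -> g(r) of a grid module pulls back the Euclidean metric
of rate space to the 2-D environment through the metric tensor

    G(r) = J(r)^T J(r),   J_ia = dg_i / dr_a,

a 2x2 positive semidefinite matrix at every position.  The module is a
*conformal isometry* (CI) of flat 2-D space when G(r) = sigma * I everywhere:
local distances are preserved up to the single conformal scale sigma.

This module provides the metric field, the CI training loss (Monte-Carlo
integral of the componentwise deviation from sigma * I), the scale-free
conformal isometry score (CIS), the closed-form conformal scale for hexagonal
and square patterns, a generalised loss against an arbitrary SPD target
metric, trajectory-length bookkeeping, and a constrained least-squares
ellipse fit used to quantify pattern distortion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .model import GridModule, _dJ_dphase, activity, jacobian

__all__ = [
    "MetricField",
    "ConformalScale",
    "metric_tensor",
    "ci_loss",
    "ci_loss_and_grad",
    "ci_loss_general",
    "cis",
    "conformal_scale_theory",
    "fit_conformal_scale",
    "trajectory_lengths",
    "ellipse_fit",
    "EllipseFit",
]


@dataclass(frozen=True)
class MetricField:
    """Per-position metric tensor components of the population map."""

    positions: np.ndarray
    Gxx: np.ndarray
    Gxy: np.ndarray
    Gyy: np.ndarray

    @property
    def det(self) -> np.ndarray:
        return self.Gxx * self.Gyy - self.Gxy**2

    def as_matrices(self) -> np.ndarray:
        G = np.empty((len(self.Gxx), 2, 2))
        G[:, 0, 0] = self.Gxx
        G[:, 0, 1] = G[:, 1, 0] = self.Gxy
        G[:, 1, 1] = self.Gyy
        return G

    def to_array(self) -> np.ndarray:
        """Columns x, y, Gxx, Gxy, Gyy (CSV/NPZ-friendly layout)."""
        return np.column_stack([self.positions, self.Gxx, self.Gxy, self.Gyy])


@dataclass(frozen=True)
class ConformalScale:
    """Conformal scale sigma with its provenance."""

    sigma: float
    provenance: str = "theoretical"  # theoretical | fitted | trainable

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError(f"conformal scale must be positive, got {self.sigma}")


def metric_tensor(module: GridModule, positions: np.ndarray) -> MetricField:
    """G(r) = J(r)^T J(r) from the analytic Jacobian."""
    positions = np.atleast_2d(positions)
    J = jacobian(module, positions)  # (S, N, 2)
    G = np.einsum("sia,sib->sab", J, J)
    return MetricField(positions, G[:, 0, 0], G[:, 0, 1], G[:, 1, 1])


def _as_sigma(scale: ConformalScale | float) -> float:
    s = scale.sigma if isinstance(scale, ConformalScale) else float(scale)
    if not s > 0:
        raise ValueError(f"conformal scale must be positive, got {s}")
    return s


def ci_loss(
    module: GridModule, samples: np.ndarray, scale: ConformalScale | float
) -> float:
    """Monte-Carlo CI loss: mean of (Gxx-s)^2 + (Gyy-s)^2 + 2 Gxy^2.

    Non-negative; zero iff G = sigma * I at every sample.
    """
    s = _as_sigma(scale)
    f = metric_tensor(module, samples)
    return float(np.mean((f.Gxx - s) ** 2 + (f.Gyy - s) ** 2 + 2.0 * f.Gxy**2))


def _target_matrices(
    target_metric: Callable[[np.ndarray], np.ndarray] | np.ndarray,
    samples: np.ndarray,
) -> np.ndarray:
    Gt = target_metric(samples) if callable(target_metric) else np.asarray(target_metric)
    Gt = np.broadcast_to(np.asarray(Gt, dtype=float), (len(samples), 2, 2))
    tr_pos = (Gt[:, 0, 0] > 0) & (Gt[:, 1, 1] > 0)
    if not np.all(tr_pos & (np.linalg.det(Gt) > 0)):
        raise ValueError("target metric must be SPD at every sample")
    return Gt


def ci_loss_general(
    module: GridModule,
    samples: np.ndarray,
    target_metric: Callable[[np.ndarray], np.ndarray] | np.ndarray,
) -> float:
    """Componentwise loss against a position-dependent SPD target metric.

    Reduces exactly to :func:`ci_loss` when the target is ``sigma * I``.
    The off-diagonal deviation is counted twice, matching the symmetric
    component count of the 2x2 tensor.
    """
    samples = np.atleast_2d(samples)
    Gt = _target_matrices(target_metric, samples)
    f = metric_tensor(module, samples)
    return float(
        np.mean(
            (f.Gxx - Gt[:, 0, 0]) ** 2
            + (f.Gyy - Gt[:, 1, 1]) ** 2
            + 2.0 * (f.Gxy - 0.5 * (Gt[:, 0, 1] + Gt[:, 1, 0])) ** 2
        )
    )


def ci_loss_and_grad(
    module: GridModule,
    samples: np.ndarray,
    sigma: float,
    target_metric: Callable[[np.ndarray], np.ndarray] | np.ndarray | None = None,
) -> tuple[float, np.ndarray, float]:
    """CI loss with closed-form gradients.

    Returns ``(loss, dloss/dphases, dloss/dsigma)``.  With ``target_metric``
    given, the deviation target is that field instead of ``sigma * I`` and
    the sigma gradient is zero.  The phase gradient uses

        dJ[s,i,a]/dphi[i,b] = (2 pi f)^2 A sum_j cos(theta_sij) k_ja k_jb,

    i.e. minus the spatial Hessian of the tuning curve.
    """
    samples = np.atleast_2d(samples)
    J = jacobian(module, samples)  # (S, N, 2)
    G = np.einsum("sia,sib->sab", J, J)  # (S, 2, 2)
    if target_metric is None:
        Gt = np.zeros_like(G)
        Gt[:, 0, 0] = Gt[:, 1, 1] = sigma
    else:
        Gt = _target_matrices(target_metric, samples)
        Gt = 0.5 * (Gt + np.swapaxes(Gt, 1, 2))
    D = G - Gt
    loss = float(np.mean(D[:, 0, 0] ** 2 + D[:, 1, 1] ** 2 + 2.0 * D[:, 0, 1] ** 2))
    # dL/dG as a symmetric weight matrix: each of the two off-diagonal slots
    # carries half of the 4*Gxy sensitivity.
    W = 2.0 * D  # (S, 2, 2)
    H = _dJ_dphase(module, samples)  # (S, N, 2, 2): dJ[s,i,a]/dphi[i,b]
    V = np.einsum("sab,sib->sia", W, J)  # (S, N, 2)
    dphases = 2.0 * np.einsum("sia,siab->ib", V, H) / len(samples)
    if target_metric is None:
        dsigma = float(np.mean(-2.0 * D[:, 0, 0] - 2.0 * D[:, 1, 1]))
    else:
        dsigma = 0.0
    return loss, dphases, dsigma


def cis(field: MetricField) -> float:
    """Conformal isometry score (scale-free deviation from G = sigma I):

        Var(Gxx) + Var(Gyy) + E[(Gxx - Gyy)^2] + 2 E[Gxy^2]

    computed with plain sample moments (denominator n).  Zero iff the metric
    field is a constant multiple of the identity on the samples.
    """
    if len(field.Gxx) < 2:
        raise ValueError("CIS requires at least 2 positions (variance undefined)")
    return float(
        np.var(field.Gxx)
        + np.var(field.Gyy)
        + np.mean((field.Gxx - field.Gyy) ** 2)
        + 2.0 * np.mean(field.Gxy**2)
    )


def conformal_scale_theory(
    A: float, N: int, f: float = 1.0, pattern: str = "hexagonal"
) -> ConformalScale:
    """Closed-form conformal scale of an ideal CI module.

    sigma_hexagon = 3 pi^2 A^2 N f^2 and sigma_square = 2 pi^2 A^2 N f^2;
    their ratio 3/2 reflects the hexagonal pattern's larger encoding
    manifold at matched amplitude and cell count.
    """
    if A <= 0 or N < 1 or f <= 0:
        raise ValueError("require A > 0, N >= 1, f > 0")
    factor = {"hexagonal": 3.0, "square": 2.0}[pattern]
    return ConformalScale(factor * np.pi**2 * A**2 * N * f**2, "theoretical")


def fit_conformal_scale(field: MetricField) -> ConformalScale:
    """Least-squares sigma given a metric field: mean of the diagonal parts."""
    return ConformalScale(float(np.mean(0.5 * (field.Gxx + field.Gyy))), "fitted")


def trajectory_lengths(
    module: GridModule, path: np.ndarray
) -> tuple[float, float]:
    """(physical, neural) length of an ordered path.

    Physical length is the summed Euclidean step length; neural length is the
    summed population-vector displacement.  For a CI module and fine steps
    the ratio neural/physical approaches sqrt(sigma).
    """
    path = np.atleast_2d(path)
    if len(path) < 2:
        raise ValueError("path needs at least 2 points")
    phys = float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))
    g = activity(module, path)
    neural = float(np.sum(np.linalg.norm(np.diff(g, axis=0), axis=1)))
    return phys, neural


@dataclass(frozen=True)
class EllipseFit:
    centre: np.ndarray
    semi_major: float
    semi_minor: float
    orientation: float  # radians, direction of the major axis
    eccentricity: float


def ellipse_fit(points: np.ndarray) -> EllipseFit:
    """Direct algebraic least-squares ellipse fit (Fitzgibbon/Halir-Flusser).

    Fits the conic a x^2 + b x y + c y^2 + d x + e y + f = 0 under the
    ellipse constraint 4ac - b^2 = 1 and returns geometric parameters with
    eccentricity in [0, 1).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 5:
        raise ValueError("ellipse fit needs at least 5 points")
    mu = pts.mean(axis=0)
    x, y = (pts - mu).T  # centring improves conditioning
    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1, S2, S3 = D1.T @ D1, D1.T @ D2, D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as err:
        raise ValueError("degenerate conic (collinear or coincident points)") from err
    M = S1 + S2 @ T
    C = np.array([[0.0, 0.0, 2.0], [0.0, -1.0, 0.0], [2.0, 0.0, 0.0]])
    evals, evecs = np.linalg.eig(np.linalg.solve(C, M))
    cond = 4.0 * evecs[0] * evecs[2] - evecs[1] ** 2
    ok = np.where(np.isreal(evals) & (cond > 0))[0]
    if len(ok) == 0:
        raise ValueError("no ellipse solution found (degenerate conic)")
    a1 = np.real(evecs[:, ok[0]])
    coef = np.concatenate([a1, T @ a1])  # a, b, c, d, e, f on centred data
    a, b, c, d, e, f0 = coef
    # geometric parameters of the centred conic
    den = b * b - 4.0 * a * c
    cx = (2.0 * c * d - b * e) / den
    cy = (2.0 * a * e - b * d) / den
    q = a * e * e + c * d * d - b * d * e + (b * b - 4.0 * a * c) * f0
    s = np.sqrt((a - c) ** 2 + b * b)
    ax1 = -np.sqrt(abs(2.0 * q * ((a + c) + s))) / den
    ax2 = -np.sqrt(abs(2.0 * q * ((a + c) - s))) / den
    semi_major, semi_minor = max(ax1, ax2), min(ax1, ax2)
    # major axis = eigenvector of the quadratic form with smallest |eigenvalue|
    lam, vec = np.linalg.eigh(np.array([[a, b / 2.0], [b / 2.0, c]]))
    v = vec[:, np.argmin(np.abs(lam))]
    theta = np.arctan2(v[1], v[0])
    ecc = np.sqrt(max(0.0, 1.0 - (semi_minor / semi_major) ** 2))
    return EllipseFit(
        centre=np.array([cx, cy]) + mu,
        semi_major=float(semi_major),
        semi_minor=float(semi_minor),
        orientation=float((theta + np.pi / 2.0) % np.pi - np.pi / 2.0),
        eccentricity=float(ecc),
    )
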