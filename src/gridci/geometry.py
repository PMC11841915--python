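"""Hexagonal-lattice and hexagonal-torus geometry.

A grid pattern built from three plane waves at 60 degrees repeats on a
triangular lattice of firing fields.  Its smallest repeating region -- the
Wigner-Seitz hexagon of that lattice -- is the *unit cell*, and quantities
defined modulo the lattice (phases, wrapped positions) live on the hexagonal
torus obtained by identifying opposite hexagon edges.

This module provides the unit-cell construction, wrapping of arbitrary points
into the cell, the shortest (periodic) distance on the torus, quasi-uniform
meshes, uniform rejection sampling, and Voronoi partitions with respect to a
set of phases.

Conventions
-----------
* The origin sits on a firing-field peak of a zero-phase cell; phases are
  expressed in the same frame.
* The unrotated hexagon has vertices on the x-axis (circumradius direction
  at 0 degrees); an ``orientation_offset`` rotates the whole construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WaveBasis",
    "UnitCellGeometry",
    "make_unit_cell",
    "wrap",
    "hex_distance",
    "hex_cdist",
    "hex_mesh",
    "sample_uniform",
    "voronoi_labels",
    "rotation_matrix",
]


def rotation_matrix(theta: float) -> np.ndarray:
    """2x2 counter-clockwise rotation by ``theta`` radians."""
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class WaveBasis:
    """Wave vectors of the three-plane-wave grid model.

    Parameters
    ----------
    f : float
        Spatial frequency of each plane wave (cycles per unit length).
    orientation_offset : float
        Rigid rotation of the whole pattern, radians.
    """

    f: float = 1.0
    orientation_offset: float = 0.0

    def __post_init__(self):
        if self.f <= 0:
            raise ValueError(f"spatial frequency must be positive, got {self.f}")

    @property
    def wave_vectors(self) -> np.ndarray:
        """Three unit wave vectors separated by 60 degrees, shape (3, 2)."""
        r60 = rotation_matrix(np.pi / 3)
        k1 = np.array([1.0, 0.0])
        ks = np.stack([k1, r60 @ k1, r60 @ r60 @ k1])
        return ks @ rotation_matrix(self.orientation_offset).T

    def to_dict(self) -> dict:
        return {"f": self.f, "orientation_offset": self.orientation_offset}


@dataclass(frozen=True)
class UnitCellGeometry:
    """Wigner-Seitz hexagon of the firing-field lattice.

    Attributes
    ----------
    lattice_vectors : (2, 2) array
        Primitive translations of the firing-field lattice (rows a1, a2).
    circumradius : float
        Centre-to-vertex distance of the hexagon, ``2 / (3 f)``.
    rhombus_basis : (2, 2) array
        Change-of-basis matrix T with rows e1 and its 60-degree rotation
        (in the pattern frame), used by :func:`hex_mesh`.
    """

    lattice_vectors: np.ndarray
    circumradius: float
    rhombus_basis: np.ndarray
    orientation_offset: float = 0.0
    f: float = field(default=1.0)

    @property
    def lattice_constant(self) -> float:
        """Nearest-neighbour distance of the firing-field lattice, 2/(sqrt(3) f)."""
        return float(np.linalg.norm(self.lattice_vectors[0]))

    @property
    def inradius(self) -> float:
        return self.lattice_constant / 2.0

    @property
    def area(self) -> float:
        """Hexagon area, (sqrt(3)/2) * lattice_constant**2."""
        return float(abs(np.linalg.det(self.lattice_vectors)))

    @property
    def neighbor_translates(self) -> np.ndarray:
        """The six lattice translations to adjacent unit cells, shape (6, 2)."""
        a1, a2 = self.lattice_vectors
        return np.stack([a1, -a1, a2, -a2, a1 - a2, a2 - a1])

    @property
    def torus_translates(self) -> np.ndarray:
        """Zero plus the six neighbour translates, shape (7, 2)."""
        return np.vstack([np.zeros((1, 2)), self.neighbor_translates])

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """True where each point lies in the closed Wigner-Seitz hexagon."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        t = self.neighbor_translates
        # closer to the origin than to any neighbouring lattice point
        ok = np.all(p @ t.T <= 0.5 * np.sum(t * t, axis=1) + tol, axis=1)
        return ok if np.ndim(points) > 1 else bool(ok[0])

    def to_json(self) -> str:
        return json.dumps(
            {
                "f": self.f,
                "orientation_offset": self.orientation_offset,
                "lattice_vectors": self.lattice_vectors.tolist(),
                "circumradius": self.circumradius,
            }
        )


def make_unit_cell(basis: WaveBasis) -> UnitCellGeometry:
    """Construct the Wigner-Seitz unit cell of the grid pattern.

    The primitive lattice vectors ``a`` satisfy ``f * k_j . a`` integer for
    all three wave vectors, so the activity of every cell is invariant under
    lattice translations.  For ``f = 1`` the lattice constant is
    ``2/sqrt(3)`` and the circumradius ``2/3``.
    """
    f = basis.f
    R = rotation_matrix(basis.orientation_offset)
    # f*k1.a1 = 1, f*k2.a1 = 1, f*k3.a1 = 0 ; f*k.a2 analogous with (1, 0, -1)
    a1 = R @ np.array([1.0, 1.0 / np.sqrt(3.0)]) / f
    a2 = R @ np.array([1.0, -1.0 / np.sqrt(3.0)]) / f
    e1 = np.array([1.0, 0.0])
    T = np.stack([e1, rotation_matrix(np.pi / 3) @ e1])
    return UnitCellGeometry(
        lattice_vectors=np.stack([a1, a2]),
        circumradius=2.0 / (3.0 * f),
        rhombus_basis=T,
        orientation_offset=basis.orientation_offset,
        f=f,
    )


def _lattice_inverse(cell: UnitCellGeometry) -> np.ndarray:
    # columns of A are the lattice vectors; c = A^-1 p gives lattice coords
    A = cell.lattice_vectors.T
    return np.linalg.inv(A)


def wrap(points: np.ndarray, cell: UnitCellGeometry) -> np.ndarray:
    """Wrap points into the Wigner-Seitz hexagon.

    The returned point is the lattice translate closest to the origin; on
    hexagon-boundary ties the lexicographically smallest (x, then y)
    translate is chosen so that ``wrap`` is a function.  ``wrap(p) - p`` is
    always a lattice translation and ``wrap`` is idempotent.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    Ainv = _lattice_inverse(cell)
    A = cell.lattice_vectors.T
    n0 = np.rint(p @ Ainv.T)  # nearest lattice coords, (m, 2)
    # candidate integer offsets around the rounded solution
    offs = np.array([[i, j] for i in (-1, 0, 1) for j in (-1, 0, 1)], dtype=float)
    cand = p[:, None, :] - (n0[:, None, :] + offs[None, :, :]) @ A.T  # (m, 9, 2)
    d2 = np.sum(cand * cand, axis=2)
    dmin = d2.min(axis=1)
    # lexicographic tie-break among near-minimal candidates
    tol = 1e-12 * (1.0 + dmin[:, None])
    big = 1e18
    masked_x = np.where(d2 <= (dmin[:, None] + tol), cand[:, :, 0], big)
    xmin = masked_x.min(axis=1)
    masked_y = np.where(
        (d2 <= (dmin[:, None] + tol)) & (np.abs(cand[:, :, 0] - xmin[:, None]) <= 1e-12),
        cand[:, :, 1],
        big,
    )
    ymin = masked_y.min(axis=1)
    out = np.stack([xmin, ymin], axis=1)
    return out if np.ndim(points) > 1 else out[0]


def hex_distance(p: np.ndarray, q: np.ndarray, cell: UnitCellGeometry) -> np.ndarray:
    """Shortest distance on the hexagonal torus.

    Both points are wrapped; the second is replicated in the six adjacent
    unit cells and the minimum Euclidean distance over the seven copies is
    returned.  Broadcasts over leading dimensions.
    """
    wp = np.atleast_2d(wrap(p, cell))
    wq = np.atleast_2d(wrap(q, cell))
    t = cell.torus_translates  # (7, 2)
    diff = wp[:, None, :] - (wq[:, None, :] + t[None, :, :])
    d = np.sqrt(np.sum(diff * diff, axis=2)).min(axis=1)
    return d if (np.ndim(p) > 1 or np.ndim(q) > 1) else float(d[0])


def hex_cdist(P: np.ndarray, Q: np.ndarray, cell: UnitCellGeometry) -> np.ndarray:
    """All-pairs shortest torus distance, shape (len(P), len(Q))."""
    wp = np.atleast_2d(wrap(P, cell))
    wq = np.atleast_2d(wrap(Q, cell))
    t = cell.torus_translates
    # (m, n, 7, 2)
    diff = wp[:, None, None, :] - (wq[None, :, None, :] + t[None, None, :, :])
    return np.sqrt(np.sum(diff * diff, axis=3)).min(axis=2)


def hex_mesh(resolution: int, cell: UnitCellGeometry) -> np.ndarray:
    """Quasi-uniform mesh covering the unit cell, shape (resolution**2, 2).

    A square mesh on ``[0, 3R/2)^2`` is interpreted in the 60-degree rhombus
    basis, mapped to the standard basis with the inverse of the rhombus
    change-of-basis matrix, and wrapped into the hexagon.  The shear map is
    area-preserving, so the mesh covers the cell uniformly.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    side = 1.5 * cell.circumradius
    u = np.arange(resolution) * (side / resolution)
    U = np.stack(np.meshgrid(u, u, indexing="ij"), axis=-1).reshape(-1, 2)
    Tinv = np.linalg.inv(cell.rhombus_basis)
    pts = U @ Tinv.T
    pts = pts @ rotation_matrix(cell.orientation_offset).T
    return wrap(pts, cell)


def sample_uniform(
    n: int,
    cell: UnitCellGeometry,
    rng: np.random.Generator | int | None = None,
    return_acceptance: bool = False,
):
    """I.i.d. uniform points in the hexagon via rejection sampling.

    Proposals are drawn from the minimum enclosing square (side twice the
    circumradius, aligned with the hexagon vertices) and accepted when they
    fall inside the hexagon; the acceptance probability is the hexagon/square
    area ratio ``3 sqrt(3) / 8``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    R = cell.circumradius
    # hexagon in the unrotated frame; rotate accepted samples at the end
    frame = make_unit_cell(WaveBasis(f=cell.f, orientation_offset=0.0))
    out = np.empty((n, 2))
    got, proposed, accepted = 0, 0, 0
    while got < n:
        m = max(int((n - got) / 0.6) + 16, 32)
        cand = rng.uniform(-R, R, size=(m, 2))
        proposed += m
        keep = cand[frame.contains(cand)]
        accepted += len(keep)
        take = min(n - got, len(keep))
        out[got : got + take] = keep[:take]
        got += take
    out = out @ rotation_matrix(cell.orientation_offset).T
    if return_acceptance:
        return out, accepted / proposed
    return out


def voronoi_labels(
    mesh: np.ndarray, phases: np.ndarray, cell: UnitCellGeometry
) -> np.ndarray:
    """Label each mesh point by its torus-nearest phase (ties: lowest index)."""
    phases = np.atleast_2d(phases)
    if phases.size == 0:
        raise ValueError("phase set must be non-empty")
    return np.argmin(hex_cdist(mesh, phases, cell), axis=1)
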