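"""Topology of grid-module population activity.

The population activity of a grid module over its unit cell traces out a
point cloud in rate space whose shape, for a well-arranged module, is a
2-torus: one connected component, two independent 1-D holes and one 2-D
void.  This module computes Vietoris-Rips persistence diagrams of such
clouds, decides whether the dominant features are torus-like, exposes a
differentiable toroidal objective built from squared persistences, and maps
representational ambiguities (distinct locations with near-identical
population activity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._rips import rips_pairs
from .geometry import hex_cdist, wrap
from .model import GridModule, activity

__all__ = [
    "PersistenceDiagram",
    "TorusVerdict",
    "AmbiguityMap",
    "maxmin_subsample",
    "rips_persistence",
    "detect_torus",
    "toroidal_loss",
    "toroidal_loss_terms",
    "ambiguity_map",
]


@dataclass(frozen=True)
class PersistenceDiagram:
    """Birth-death features of a Rips filtration.

    ``birth_edges``/``death_edges`` hold the vertex pairs (indices into the
    *original* cloud) whose distance realises each birth/death value; they
    carry the subgradient of persistence with respect to the points and are
    (-1, -1) where undefined (H0 births, essential deaths).
    """

    dims: np.ndarray
    births: np.ndarray
    deaths: np.ndarray
    birth_edges: np.ndarray
    death_edges: np.ndarray
    subsample_indices: np.ndarray
    threshold: float = np.nan

    @property
    def persistences(self) -> np.ndarray:
        return self.deaths - self.births

    def features(self, dim: int) -> np.ndarray:
        """(birth, death) rows of one dimension, sorted by persistence desc."""
        sel = np.where(self.dims == dim)[0]
        order = np.argsort(self.persistences[sel])[::-1]
        return np.column_stack([self.births[sel][order], self.deaths[sel][order]])

    def top_persistences(self, dim: int, k: int, finite: bool = True) -> np.ndarray:
        p = self.persistences[self.dims == dim]
        if finite:
            p = p[np.isfinite(p)]
        p = np.sort(p)[::-1]
        out = np.zeros(k)
        out[: min(k, len(p))] = p[:k]
        return out

    def to_array(self) -> np.ndarray:
        """Columns dim, birth, death (CSV-friendly)."""
        return np.column_stack([self.dims, self.births, self.deaths])


@dataclass(frozen=True)
class TorusVerdict:
    """Decision on toroidal topology from dominance gaps in the barcode."""

    is_torus: bool
    h1_top2: np.ndarray
    h2_top1: float
    h1_gap: float  # 2nd H1 persistence / 3rd H1 persistence
    h2_gap: float  # 1st H2 persistence / 2nd H2 persistence
    gap_factor: float


def maxmin_subsample(cloud: np.ndarray, k: int, seed: int | None = 0) -> np.ndarray:
    """Greedy farthest-point (maxmin) subsample indices, deterministic given seed."""
    n = len(cloud)
    if k >= n:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    idx = np.empty(k, dtype=np.int64)
    idx[0] = rng.integers(n)
    d = np.linalg.norm(cloud - cloud[idx[0]], axis=1)
    for i in range(1, k):
        idx[i] = np.argmax(d)
        d = np.minimum(d, np.linalg.norm(cloud - cloud[idx[i]], axis=1))
    return idx


def rips_persistence(
    cloud: np.ndarray,
    maxdim: int = 2,
    subsample: int = 150,
    seed: int | None = 0,
    threshold: float | None = None,
) -> PersistenceDiagram:
    """Vietoris-Rips persistence of a point cloud (Euclidean distances).

    The cloud is reduced to ``subsample`` points by greedy maxmin sampling
    (all points are used when there are fewer).  The default distance
    threshold is the enclosing radius, at which the complex becomes a cone;
    every H1/H2 class dies at or below it, so the finite diagram is complete.
    """
    cloud = np.asarray(cloud, dtype=float)
    if len(cloud) < 4:
        raise ValueError("need at least 4 points")
    sub = maxmin_subsample(cloud, subsample, seed)
    D = squareform(pdist(cloud[sub]))
    recs = rips_pairs(D, maxdim=maxdim, threshold=threshold)
    dims = np.array([r[0] for r in recs], dtype=np.int64)
    births = np.array([r[1] for r in recs])
    deaths = np.array([r[2] for r in recs])

    def _map(e):
        return (-1, -1) if e[0] < 0 else (int(sub[e[0]]), int(sub[e[1]]))

    be = np.array([_map(r[3]) for r in recs], dtype=np.int64)
    de = np.array([_map(r[4]) for r in recs], dtype=np.int64)
    thr = threshold if threshold is not None else float(np.min(np.max(D, axis=1)))
    return PersistenceDiagram(dims, births, deaths, be, de, sub, thr)


def detect_torus(diagram: PersistenceDiagram, gap_factor: float = 3.0) -> TorusVerdict:
    """Torus test: two dominant H1 bars and one dominant H2 bar.

    ``is_torus`` requires the 2nd-largest H1 persistence to exceed
    ``gap_factor`` times the 3rd-largest, and the largest H2 persistence to
    exceed ``gap_factor`` times the 2nd-largest (or be the only H2 bar).
    Raw persistences are exposed so callers can apply their own criterion.
    """
    h1 = diagram.top_persistences(1, 3)
    h2 = diagram.top_persistences(2, 2)
    h1_gap = h1[1] / h1[2] if h1[2] > 0 else np.inf if h1[1] > 0 else 0.0
    h2_gap = h2[0] / h2[1] if h2[1] > 0 else np.inf if h2[0] > 0 else 0.0
    ok = (h1[1] > 0) and (h1_gap >= gap_factor) and (h2[0] > 0) and (h2_gap >= gap_factor)
    return TorusVerdict(bool(ok), h1[:2], float(h2[0]), float(h1_gap), float(h2_gap), gap_factor)


def toroidal_loss_terms(diagram: PersistenceDiagram):
    """Signed squared-persistence terms of the toroidal objective.

    Rewards the two most persistent 1-D features and the single most
    persistent 2-D feature (negative squared persistence) and penalises all
    remaining finite 1-D/2-D features (positive squared persistence).
    Returns ``(loss, records)`` where each record is
    ``(feature index in diagram, coefficient of its persistence**2)``.
    """
    loss = 0.0
    records = []
    for dim, n_top in ((1, 2), (2, 1)):
        sel = np.where((diagram.dims == dim) & np.isfinite(diagram.deaths))[0]
        order = sel[np.argsort(diagram.persistences[sel])[::-1]]
        for rank, fi in enumerate(order):
            coef = -1.0 if rank < n_top else 1.0
            loss += coef * diagram.persistences[fi] ** 2
            records.append((int(fi), coef))
    return float(loss), records


def toroidal_loss(
    module_or_cloud,
    mesh: np.ndarray | None = None,
    subsample: int = 150,
    seed: int | None = 0,
) -> float:
    """Toroidal objective of a module's activity cloud (or a raw cloud)."""
    if isinstance(module_or_cloud, GridModule):
        if mesh is None:
            raise ValueError("a mesh of positions is required with a GridModule")
        cloud = activity(module_or_cloud, mesh)
    else:
        cloud = np.asarray(module_or_cloud, dtype=float)
    diagram = rips_persistence(cloud, maxdim=2, subsample=subsample, seed=seed)
    return toroidal_loss_terms(diagram)[0]


def toroidal_loss_edge_grads(diagram: PersistenceDiagram):
    """Subgradient of the toroidal objective through critical distances.

    Persistence responds to the point coordinates only through the birth and
    death critical edges; this returns ``(loss, edges, dloss_ddist)`` where
    ``edges`` is an (m, 2) array of cloud-point index pairs and
    ``dloss_ddist`` the derivative of the loss with respect to each edge's
    Euclidean length.
    """
    loss, records = toroidal_loss_terms(diagram)
    edges, grads = [], []
    for fi, coef in records:
        p = diagram.persistences[fi]
        if diagram.death_edges[fi, 0] >= 0:
            edges.append(diagram.death_edges[fi])
            grads.append(2.0 * coef * p)  # d(p^2)/d(death)
        if diagram.birth_edges[fi, 0] >= 0:
            edges.append(diagram.birth_edges[fi])
            grads.append(-2.0 * coef * p)  # d(p^2)/d(birth)
    if not edges:
        return loss, np.empty((0, 2), dtype=np.int64), np.empty(0)
    return loss, np.vstack(edges), np.array(grads)


@dataclass(frozen=True)
class AmbiguityMap:
    """Population-vector distance to a reference and its ambiguous points."""

    mesh: np.ndarray
    distances: np.ndarray
    ambiguous: np.ndarray  # mesh points matching the reference away from it
    reference: np.ndarray
    epsilon: float
    marked: np.ndarray = field(repr=False, default=None)


def ambiguity_map(
    module: GridModule,
    mesh: np.ndarray,
    reference: np.ndarray,
    epsilon: float = 1e-2,
) -> AmbiguityMap:
    """Locations whose population activity matches a reference point's.

    Mesh points with ``||g(r) - g(ref)|| < epsilon`` are marked; the
    connected neighbourhood of the reference (marked points reachable within
    two mesh spacings of each other, starting from the reference) is
    excluded, leaving the genuinely ambiguous set.  For a single cell this
    set is a 1-D contour; for three generically-phased cells it is empty.
    """
    cell = module.unit_cell
    ref = wrap(np.asarray(reference, dtype=float), cell)
    g = activity(module, mesh)
    gref = activity(module, ref[None, :])[0]
    dist = np.linalg.norm(g - gref[None, :], axis=1)
    marked = dist < epsilon
    spacing = np.sqrt(cell.area / len(mesh))
    radius = 2.0 * spacing
    idx = np.where(marked)[0]
    excluded = np.zeros(len(mesh), dtype=bool)
    if len(idx) > 0:
        pts = mesh[idx]
        # grow the reference component through chains of marked points
        near = hex_cdist(pts, ref[None, :], cell)[:, 0] <= radius
        frontier = np.where(near)[0]
        comp = set(frontier.tolist())
        dmat = hex_cdist(pts, pts, cell) <= radius
        while len(frontier) > 0:
            reach = np.where(dmat[frontier].any(axis=0))[0]
            frontier = np.array([i for i in reach if i not in comp], dtype=int)
            comp.update(frontier.tolist())
        excluded[idx[list(comp)]] = True
    ambiguous = mesh[marked & ~excluded]
    return AmbiguityMap(mesh, dist, ambiguous, ref, epsilon, marked)
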