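"""Idealised grid-cell activity model.

A grid cell is modelled as a superposition of three plane waves whose wave
vectors are separated by 60 degrees,

    g_i(r) = 1/3 + (2/9) * sum_j cos(2 pi f k_j . (r - phi_i)),

which produces a hexagonal firing pattern of unit peak rate peaking at the
cell's phase offset ``phi_i``.  Cells of one module share frequency ``f`` and
orientation and differ only in phase, so the module's population vector is
periodic on the hexagonal unit cell.  A square-pattern comparator (two
orthogonal waves) and a 1-D ring tuning model are also provided.

All spatial derivatives are closed-form; :func:`jacobian` is the building
block of the metric-tensor machinery and is cross-checked against finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import UnitCellGeometry, WaveBasis, make_unit_cell, rotation_matrix, wrap

__all__ = [
    "GridModule",
    "square_module",
    "activity",
    "jacobian",
    "ring_tuning",
    "energy_map",
    "concatenate",
]


def _square_wave_vectors(basis: WaveBasis) -> np.ndarray:
    R = rotation_matrix(basis.orientation_offset)
    return np.stack([R @ np.array([1.0, 0.0]), R @ np.array([0.0, 1.0])])


@dataclass(frozen=True)
class GridModule:
    """A module of grid cells: shared wave basis, per-cell phase offsets.

    Parameters
    ----------
    phases : (N, 2) array
        Phase offsets; stored wrapped into the unit cell (hexagonal pattern)
        or the square primitive cell.
    basis : WaveBasis
        Frequency and orientation shared by all cells.
    dc_offset, wave_amplitude : float
        Baseline rate and per-plane-wave amplitude.  The defaults 1/3 and 2/9
        give activity in [0, 1] for the hexagonal pattern.
    pattern : {"hexagonal", "square"}
    """

    phases: np.ndarray
    basis: WaveBasis = field(default_factory=WaveBasis)
    dc_offset: float = 1.0 / 3.0
    wave_amplitude: float = 2.0 / 9.0
    pattern: str = "hexagonal"
    # optional linear deformation of the pattern (wave vectors become
    # M^T k_j, i.e. the firing pattern is evaluated in sheared coordinates);
    # used when representing distorted target metrics.  Phases are stored
    # unwrapped in that case since the standard unit cell no longer applies.
    deformation: np.ndarray | None = None

    def __post_init__(self):
        phases = np.atleast_2d(np.asarray(self.phases, dtype=float))
        if phases.ndim != 2 or phases.shape[1] != 2 or len(phases) < 1:
            raise ValueError("phases must be an (N, 2) array with N >= 1")
        if self.pattern not in ("hexagonal", "square"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.deformation is None:
            if self.pattern == "hexagonal":
                phases = wrap(phases, self.unit_cell)
            else:
                phases = phases - np.floor(phases * self.basis.f) / self.basis.f
        object.__setattr__(self, "phases", phases)

    @property
    def n_cells(self) -> int:
        return len(self.phases)

    @property
    def wave_vectors(self) -> np.ndarray:
        K = (
            self.basis.wave_vectors
            if self.pattern == "hexagonal"
            else _square_wave_vectors(self.basis)
        )
        if self.deformation is not None:
            K = K @ self.deformation  # rows become M^T k_j
        return K

    @property
    def unit_cell(self) -> UnitCellGeometry:
        if self.pattern != "hexagonal":
            raise ValueError("unit_cell is defined for the hexagonal pattern")
        return make_unit_cell(self.basis)

    def with_phases(self, phases: np.ndarray) -> "GridModule":
        return replace(self, phases=phases)

    def to_npz(self, path) -> None:
        np.savez(
            path,
            phases=self.phases,
            f=self.basis.f,
            orientation_offset=self.basis.orientation_offset,
            dc_offset=self.dc_offset,
            wave_amplitude=self.wave_amplitude,
            pattern=self.pattern,
        )

    @staticmethod
    def from_npz(path) -> "GridModule":
        d = np.load(path, allow_pickle=False)
        return GridModule(
            phases=d["phases"],
            basis=WaveBasis(float(d["f"]), float(d["orientation_offset"])),
            dc_offset=float(d["dc_offset"]),
            wave_amplitude=float(d["wave_amplitude"]),
            pattern=str(d["pattern"]),
        )


def square_module(
    phases: np.ndarray, basis: WaveBasis | None = None, wave_amplitude: float = 2.0 / 9.0
) -> GridModule:
    """Square-pattern comparator: two orthogonal waves, non-negative rates."""
    return GridModule(
        phases=np.atleast_2d(phases),
        basis=basis or WaveBasis(),
        dc_offset=2.0 * wave_amplitude,
        wave_amplitude=wave_amplitude,
        pattern="square",
    )


def _wave_phases(module: GridModule, positions: np.ndarray) -> np.ndarray:
    """Arguments theta[s, i, j] = 2 pi f k_j . (r_s - phi_i)."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    K = module.wave_vectors  # (J, 2)
    w = 2.0 * np.pi * module.basis.f
    return w * (pos @ K.T)[:, None, :] - w * (module.phases @ K.T)[None, :, :]


def activity(module: GridModule, positions: np.ndarray) -> np.ndarray:
    """Firing rates, shape (n_positions, n_cells).

    Periodic under lattice translations of the positions; with default
    amplitudes the hexagonal pattern spans [0, 1] with maximum at ``phi_i``.
    """
    theta = _wave_phases(module, positions)
    return module.dc_offset + module.wave_amplitude * np.cos(theta).sum(axis=2)


def jacobian(module: GridModule, positions: np.ndarray) -> np.ndarray:
    """Spatial derivative dg_i/dr, shape (n_positions, n_cells, 2).

    Closed form: ``-2 pi f A sum_j sin(theta_ij) k_j``.
    """
    theta = _wave_phases(module, positions)
    K = module.wave_vectors
    w = 2.0 * np.pi * module.basis.f
    return -w * module.wave_amplitude * np.einsum("sij,ja->sia", np.sin(theta), K)


def _dJ_dphase(module: GridModule, positions: np.ndarray) -> np.ndarray:
    """dJ[s,i,a]/dphi[i,b] = (2 pi f)^2 A sum_j cos(theta_ij) k_ja k_jb.

    Equals minus the spatial Hessian of g_i; used for closed-form gradients
    of the metric-based losses with respect to the phases.
    """
    theta = _wave_phases(module, positions)
    K = module.wave_vectors
    w = 2.0 * np.pi * module.basis.f
    return (w * w * module.wave_amplitude) * np.einsum(
        "sij,ja,jb->siab", np.cos(theta), K, K
    )


def ring_tuning(N: int, positions_1d: np.ndarray) -> np.ndarray:
    """1-D comparator: s_i(r) = cos(2 pi r + i pi / N), i = 0..N-1.

    For N >= 2 the population vector traces an isotropic ring of radius
    sqrt(N/2): the squared norm sums to N/2 at every position.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    r = np.atleast_1d(np.asarray(positions_1d, dtype=float))
    i = np.arange(N)
    return np.cos(2.0 * np.pi * r[:, None] + i[None, :] * np.pi / N)


def energy_map(module: GridModule, mesh: np.ndarray) -> np.ndarray:
    """L2 norm of the population activity at each mesh point."""
    return np.linalg.norm(activity(module, mesh), axis=1)


def concatenate(modules: list[GridModule]) -> GridModule:
    """Stack the cells of several modules sharing one basis and pattern."""
    first = modules[0]
    for m in modules[1:]:
        if m.basis != first.basis or m.pattern != first.pattern:
            raise ValueError("modules must share basis and pattern")
    return first.with_phases(np.vstack([m.phases for m in modules]))
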