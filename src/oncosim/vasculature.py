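"""Steady-state glucose transport on the voxel lattice.

Inside the tumor the normalized glucose concentration obeys the
reaction--diffusion balance

    D lap(c) - lambda P c + rho V (cn - c) = 0,

with diffusivity D (mm^2/h), per-cell consumption rate lambda, viable-cell
count P per voxel, lumped vascular delivery efficiency rho V (h^-1) and the
well-vascularized reference concentration cn imposed as a Dirichlet condition
on all non-tumor voxels.  The 7-point finite-difference system is symmetric
positive definite and solved sparsely; the returned field is u = c/cn in
[0, 1] (maximum principle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import VoxelGrid

__all__ = [
    "VasculatureParameters",
    "closed_form_uniform",
    "solve_glucose",
]


@dataclass(frozen=True)
class VasculatureParameters:
    """Glucose-transport constants (defaults: tumor-spheroid literature values).

    ``lam`` is the consumption rate per cell per hour, quoted for 1 mm^3
    voxels; for other voxel volumes the consumption term is computed from the
    cell density per mm^3 so the sink stays per-volume consistent.
    """

    D: float = 0.396  # mm^2 h^-1
    lam: float = 7.6e-10  # (num cells)^-1 h^-1, per mm^3 of tissue
    rhoV: float = 0.25  # h^-1
    cn: float = 0.9  # kg m^-3

    def __post_init__(self):
        if min(self.D, self.lam, self.rhoV) < 0 or self.cn <= 0:
            raise ValueError("invalid vasculature parameters")


def closed_form_uniform(lamP: float, rhoV: float) -> float:
    """Diffusion-free homogeneous fixed point u = rhoV / (lamP + rhoV).

    Serves as the independent oracle for the central voxel of a large
    homogeneous tumor, where boundary influence has decayed away.
    """
    if rhoV < 0 or lamP < 0:
        raise ValueError("rates must be >= 0")
    if lamP + rhoV == 0:
        raise ValueError("lamP + rhoV must be positive")
    return rhoV / (lamP + rhoV)


def solve_glucose(
    grid: VoxelGrid,
    viable_cells: np.ndarray,
    tumor_mask: np.ndarray,
    params: VasculatureParameters = VasculatureParameters(),
    tol: float = 1e-8,
) -> np.ndarray:
    """Normalized glucose field u = c/cn per voxel.

    ``viable_cells`` is the living-cell count P per voxel; ``tumor_mask``
    selects the voxels on which the transport equation is solved (all other
    voxels are held at u = 1).
    """
    P = np.asarray(viable_cells, float).reshape(-1)
    mask = np.asarray(tumor_mask, bool).reshape(-1)
    if P.shape[0] != grid.n_voxels or mask.shape[0] != grid.n_voxels:
        raise ValueError("field shapes do not match the grid")
    if (P < 0).any():
        raise ValueError("viable cell counts must be >= 0")

    u = np.ones(grid.n_voxels)
    ids = np.flatnonzero(mask)
    if ids.size == 0:
        return u

    h = grid.voxel_edge_mm
    # consumption rate per voxel, normalized to cell density per mm^3
    lamP = params.lam * P[ids] / grid.voxel_volume_mm3
    k = params.D / (h * h)

    pos = -np.ones(grid.n_voxels, dtype=np.int64)
    pos[ids] = np.arange(ids.size)
    shape = grid.shape
    coords = np.stack(np.unravel_index(ids, shape), axis=1)

    rows, cols, vals = [], [], []
    diag = lamP + params.rhoV
    b = np.full(ids.size, params.rhoV * params.cn)
    for axis in range(3):
        for sgn in (-1, 1):
            nb = coords.copy()
            nb[:, axis] += sgn
            inside = (nb[:, axis] >= 0) & (nb[:, axis] < shape[axis])
            nb_flat = np.ravel_multi_index(
                (nb[inside, 0], nb[inside, 1], nb[inside, 2]), shape
            )
            diag = diag + k * inside  # each existing face contributes D/h^2
            nb_pos = pos[nb_flat]
            tumor_nb = nb_pos >= 0
            src = np.flatnonzero(inside)
            rows.append(src[tumor_nb])
            cols.append(nb_pos[tumor_nb])
            vals.append(np.full(tumor_nb.sum(), -k))
            # non-tumor neighbors are Dirichlet c = cn
            b[src[~tumor_nb]] += k * params.cn
    # outside the grid the surrounding tissue is also healthy: Dirichlet cn
    # faces on the grid boundary were excluded from `inside`; treat them as cn
    for axis in range(3):
        for sgn in (-1, 1):
            nbv = coords[:, axis] + sgn
            outside = (nbv < 0) | (nbv >= shape[axis])
            diag = diag + k * outside
            b[outside] += k * params.cn

    A = sp.coo_matrix(
        (
            np.concatenate(vals + [diag]),
            (
                np.concatenate(rows + [np.arange(ids.size)]),
                np.concatenate(cols + [np.arange(ids.size)]),
            ),
        ),
        shape=(ids.size, ids.size),
    ).tocsr()

    c = spla.spsolve(A, b)
    resid = np.linalg.norm(A @ c - b) / max(np.linalg.norm(b), 1e-300)
    if resid > tol:
        raise RuntimeError(f"glucose solve did not converge: relative residual {resid:.3e}")
    u[ids] = c / params.cn
    return u
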