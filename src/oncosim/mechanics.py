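"""Tumor mass-effect on the voxel grid.

Local overcrowding relative to a carrying capacity c0 imposes an isotropic
volumetric growth strain eps_growth = (c/c0)^(1/3) - 1.  The strain drives a
static linear-elasticity solve (trilinear hexahedral elements, one element
per voxel, zero displacement on the outer domain boundary) with
stress = C : (eps_total - eps_growth I).  The per-voxel pressure
p = tr(sigma)/3 yields the "least pressure" direction field
d = -grad p / |grad p| that guides cell redistribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import VoxelGrid

__all__ = [
    "MechanicalProperties",
    "growth_strain",
    "solve_pressure",
    "least_pressure_direction",
    "assemble_elasticity",
]

#: default Young's moduli (Pa) and Poisson ratios per tissue label name
WT_TISSUES = {
    "healthy_kidney": (5.3e3, 0.40),
    "bone": (1.0e9, 0.30),
    "other": (5.0e3, 0.40),
    "tumor": (20.0e3, 0.40),
}
NSCLC_TISSUES = {
    "lung": (5.0e3, 0.40),
    "bone": (1.0e9, 0.30),
    "other": (5.0e3, 0.40),
    "inner_organs": (5.0e3, 0.40),
    "bronchi": (5.0e3, 0.40),
    "tumor": (10.0e3, 0.40),
}


@dataclass
class MechanicalProperties:
    """Per-tissue-label Young's modulus E (Pa) and Poisson ratio nu."""

    table: dict  # label (int) -> (E, nu)

    def __post_init__(self):
        for label, (E, nu) in self.table.items():
            if E <= 0:
                raise ValueError(f"label {label}: E must be positive")
            if not -1.0 < nu < 0.5:
                raise ValueError(f"label {label}: nu must be in (-1, 0.5)")

    def lame(self, label) -> tuple[float, float]:
        E, nu = self.table[label]
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        return lam, mu

    @classmethod
    def from_yaml(cls, path) -> "MechanicalProperties":
        """YAML mapping: label (int) -> {E: ..., nu: ...}."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({int(k): (float(v["E"]), float(v["nu"])) for k, v in raw.items()})


def growth_strain(c: np.ndarray, c0: float) -> np.ndarray:
    """Volumetric growth strain (c/c0)^(1/3) - 1 per voxel."""
    if c0 <= 0:
        raise ValueError("carrying capacity must be positive")
    c = np.asarray(c, float)
    if (c < 0).any():
        raise ValueError("negative cell counts")
    return np.cbrt(c / c0) - 1.0


# -- trilinear hexahedral element --------------------------------------------

# local node coordinates in [-1, 1]^3, ordered x fastest
_XI = np.array(
    [[-1, -1, -1], [1, -1, -1], [-1, 1, -1], [1, 1, -1],
     [-1, -1, 1], [1, -1, 1], [-1, 1, 1], [1, 1, 1]],
    float,
)
_GP = np.array([-1.0, 1.0]) / np.sqrt(3.0)
_VOIGT_I = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])


def _dshape(xi) -> np.ndarray:
    """(8, 3) shape-function gradients w.r.t. local coordinates at point xi."""
    g = np.empty((8, 3))
    for i, (a, b, c) in enumerate(_XI):
        g[i, 0] = a * (1 + b * xi[1]) * (1 + c * xi[2]) / 8.0
        g[i, 1] = (1 + a * xi[0]) * b * (1 + c * xi[2]) / 8.0
        g[i, 2] = (1 + a * xi[0]) * (1 + b * xi[1]) * c / 8.0
    return g


def _b_matrix(dndx: np.ndarray) -> np.ndarray:
    """(6, 24) strain-displacement matrix (engineering shear ordering
    xx, yy, zz, xy, yz, xz)."""
    B = np.zeros((6, 24))
    for i in range(8):
        dx, dy, dz = dndx[i]
        c = 3 * i
        B[0, c] = dx
        B[1, c + 1] = dy
        B[2, c + 2] = dz
        B[3, c] = dy
        B[3, c + 1] = dx
        B[4, c + 1] = dz
        B[4, c + 2] = dy
        B[5, c] = dz
        B[5, c + 2] = dx
    return B


def _voigt_C(lam: float, mu: float) -> np.ndarray:
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[3:, 3:] = np.eye(3) * mu
    return C


def _element_matrices(h: float):
    """B matrices and quadrature weights for the cubic element of edge h."""
    detJ = (h / 2.0) ** 3
    Bs = []
    for gx in _GP:
        for gy in _GP:
            for gz in _GP:
                dndx = _dshape((gx, gy, gz)) * (2.0 / h)
                Bs.append(_b_matrix(dndx))
    B_center = _b_matrix(_dshape((0.0, 0.0, 0.0)) * (2.0 / h))
    return Bs, detJ, B_center


def _element_stiffness(lam: float, mu: float, Bs, detJ) -> np.ndarray:
    C = _voigt_C(lam, mu)
    K = np.zeros((24, 24))
    for B in Bs:
        K += B.T @ C @ B * detJ
    return K


def _element_eigenload(lam: float, mu: float, Bs, detJ) -> np.ndarray:
    """Nodal load for a unit isotropic eigenstrain: int B^T C I dV."""
    s = _voigt_C(lam, mu) @ _VOIGT_I  # = (3 lam + 2 mu) on normal components
    f = np.zeros(24)
    for B in Bs:
        f += B.T @ s * detJ
    return f


def _connectivity(grid: VoxelGrid) -> np.ndarray:
    """(n_elements, 8) global node ids per voxel element."""
    nx, ny, nz = grid.shape
    nid = np.arange((nx + 1) * (ny + 1) * (nz + 1)).reshape(nx + 1, ny + 1, nz + 1)
    ex, ey, ez = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    ex, ey, ez = ex.ravel(), ey.ravel(), ez.ravel()
    conn = np.empty((grid.n_voxels, 8), np.int64)
    for i, (a, b, c) in enumerate(((_XI + 1) / 2).astype(int)):
        conn[:, i] = nid[ex + a, ey + b, ez + c]
    return conn


def assemble_elasticity(
    grid: VoxelGrid,
    labels: np.ndarray,
    props: MechanicalProperties,
    strain: np.ndarray,
):
    """Assemble the global stiffness matrix and eigenstrain load vector.

    Returns (K csr, f, free_dof_mask, conn, B_center, per-element (lam, mu)).
    """
    labels = np.asarray(labels).reshape(-1)
    strain = np.asarray(strain, float).reshape(-1)
    if labels.shape[0] != grid.n_voxels or strain.shape[0] != grid.n_voxels:
        raise ValueError("labels/strain do not match the grid")
    present = np.unique(labels)
    missing = [int(l) for l in present if l not in props.table]
    if missing:
        raise KeyError(f"no mechanical properties for labels {missing}")

    h = grid.voxel_edge_mm
    Bs, detJ, B_center = _element_matrices(h)
    conn = _connectivity(grid)
    dof = (conn[:, :, None] * 3 + np.arange(3)).reshape(grid.n_voxels, 24)

    nx, ny, nz = grid.shape
    n_nodes = (nx + 1) * (ny + 1) * (nz + 1)
    f = np.zeros(3 * n_nodes)
    rows, cols, vals = [], [], []
    lam_mu = np.empty((grid.n_voxels, 2))
    for label in present:
        lam, mu = props.lame(int(label))
        sel = labels == label
        lam_mu[sel] = (lam, mu)
        Ke = _element_stiffness(lam, mu, Bs, detJ)
        fe = _element_eigenload(lam, mu, Bs, detJ)
        d = dof[sel]
        rows.append(np.repeat(d, 24, axis=1).ravel())
        cols.append(np.tile(d, (1, 24)).ravel())
        vals.append(np.tile(Ke.ravel(), sel.sum()))
        np.add.at(f, d.ravel(), np.outer(strain[sel], fe).ravel())
    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * n_nodes, 3 * n_nodes),
    ).tocsr()

    # outer-surface nodes fully constrained
    gx, gy, gz = np.meshgrid(
        np.arange(nx + 1), np.arange(ny + 1), np.arange(nz + 1), indexing="ij"
    )
    boundary = (
        (gx == 0) | (gx == nx) | (gy == 0) | (gy == ny) | (gz == 0) | (gz == nz)
    ).ravel()
    free = np.repeat(~boundary, 3)
    return K, f, free, conn, B_center, lam_mu


def solve_pressure(
    grid: VoxelGrid,
    labels: np.ndarray,
    props: MechanicalProperties,
    strain: np.ndarray,
    tol: float = 1e-8,
    compression_positive: bool = False,
) -> np.ndarray:
    """Per-voxel pressure p = tr(sigma)/3 from the eigenstrain elasticity solve.

    With ``compression_positive`` the sign toggle p = -tr(sigma)/3 is applied
    (the direction field is unaffected up to the configured sign).
    """
    K, f, free, conn, B_center, lam_mu = assemble_elasticity(
        grid, labels, props, strain
    )
    strain = np.asarray(strain, float).reshape(-1)
    u = np.zeros(K.shape[0])
    if free.any() and np.abs(f[free]).max() > 0:
        Kff = K[free][:, free].tocsc()
        u_free = spla.spsolve(Kff, f[free])
        resid = np.linalg.norm(Kff @ u_free - f[free]) / np.linalg.norm(f[free])
        if resid > tol:
            raise RuntimeError(f"elasticity solve residual {resid:.3e} > {tol:g}")
        u[free] = u_free

    dof = (conn[:, :, None] * 3 + np.arange(3)).reshape(grid.n_voxels, 24)
    ue = u[dof]  # (n_elements, 24)
    eps = ue @ B_center.T  # total strain at element centers, (n, 6)
    lam = lam_mu[:, 0]
    mu = lam_mu[:, 1]
    e_el = eps[:, :3] - strain[:, None]  # elastic normal strains
    tr = e_el.sum(axis=1)
    p = (lam + 2.0 * mu / 3.0) * tr  # tr(sigma)/3 = (lam + 2mu/3) tr(eps_el)
    return -p if compression_positive else p


def least_pressure_direction(
    p: np.ndarray, grid: VoxelGrid, eps_grad: float = 1e-12
) -> np.ndarray:
    """Unit vectors d = -grad p / |grad p| per voxel ((n_voxels, 3)).

    Central differences in the interior, one-sided at the grid boundary;
    voxels with |grad p| < ``eps_grad`` get the zero vector (isotropic flag).
    """
    p3 = np.asarray(p, float).reshape(grid.shape)
    h = grid.voxel_edge_mm
    if min(grid.shape) > 1:
        g = np.stack(np.gradient(p3, h), axis=-1).reshape(-1, 3)
    else:  # degenerate axes: gradient along singleton dimensions is zero
        g = np.zeros((grid.n_voxels, 3))
        for ax in range(3):
            if grid.shape[ax] > 1:
                g[:, ax] = np.gradient(p3, h, axis=ax).reshape(-1)
    norm = np.linalg.norm(g, axis=1)
    d = np.zeros_like(g)
    ok = norm >= eps_grad
    d[ok] = -g[ok] / norm[ok, None]
    return d
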