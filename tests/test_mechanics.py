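"""Growth-strain elasticity on the voxel grid.

The reference assembly used as oracle is deliberately naive: per-element
Python loops, shape-function gradients obtained by central finite differences
of the trilinear shape functions (independent of the analytic gradients in
the implementation), dense solve.
"""

import numpy as np
import pytest

from oncosim import (
    MechanicalProperties,
    VoxelGrid,
    growth_strain,
    least_pressure_direction,
    solve_pressure,
)

SOFT = MechanicalProperties({0: (5.0e3, 0.40)})


def test_growth_strain_identities():
    assert growth_strain(np.array([1.0]), 1.0)[0] == pytest.approx(0.0)
    assert growth_strain(np.array([8.0]), 1.0)[0] == pytest.approx(1.0)
    assert growth_strain(np.array([0.0]), 1.0)[0] == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        growth_strain(np.array([1.0]), 0.0)
    with pytest.raises(ValueError):
        growth_strain(np.array([-1.0]), 1.0)


def _inclusion(n, value=0.05, half=1):
    grid = VoxelGrid(n, n, n)
    labels = np.zeros(grid.n_voxels, int)
    coords = np.stack(np.unravel_index(np.arange(grid.n_voxels), grid.shape), 1)
    strain = np.zeros(grid.n_voxels)
    strain[(np.abs(coords - n // 2) <= half).all(1)] = value
    return grid, labels, strain


def test_zero_strain_gives_zero_pressure():
    grid, labels, strain = _inclusion(7, value=0.0)
    p = solve_pressure(grid, labels, SOFT, strain)
    assert np.abs(p).max() == 0.0


def test_growing_inclusion_is_compressed():
    grid, labels, strain = _inclusion(9)
    inside = strain > 0
    p = solve_pressure(grid, labels, SOFT, strain, compression_positive=True)
    assert p[inside].mean() > 0  # compression positive under the toggle
    p_default = solve_pressure(grid, labels, SOFT, strain)  # tension-positive
    assert np.allclose(p_default, -p)


def test_pressure_linear_in_eigenstrain():
    grid, labels, strain = _inclusion(8, value=0.02)
    p1 = solve_pressure(grid, labels, SOFT, strain)
    p2 = solve_pressure(grid, labels, SOFT, 2.0 * strain)
    assert np.allclose(p2, 2.0 * p1, rtol=1e-8, atol=1e-12)


def test_solution_invariant_under_grid_rotation():
    grid, labels, strain = _inclusion(9)
    p = solve_pressure(grid, labels, SOFT, strain).reshape(grid.shape)
    for axes in ((0, 1), (1, 2), (0, 2)):
        rotated = np.rot90(p, k=1, axes=axes)
        assert np.allclose(rotated, p, rtol=1e-8, atol=1e-6)


# -- naive dense reference assembly ------------------------------------------


def _shape_value(xi, node):
    signs = np.array(
        [[-1, -1, -1], [1, -1, -1], [-1, 1, -1], [1, 1, -1],
         [-1, -1, 1], [1, -1, 1], [-1, 1, 1], [1, 1, 1]], float
    )
    a, b, c = signs[node]
    return (1 + a * xi[0]) * (1 + b * xi[1]) * (1 + c * xi[2]) / 8.0


def _fd_gradients(xi, h_elem, step=1e-6):
    """Shape-function gradients w.r.t. physical coordinates by central
    differences in the local coordinates (chain rule with dx = h/2 dxi)."""
    g = np.zeros((8, 3))
    for node in range(8):
        for d in range(3):
            up, dn = np.array(xi, float), np.array(xi, float)
            up[d] += step
            dn[d] -= step
            g[node, d] = (_shape_value(up, node) - _shape_value(dn, node)) / (
                2 * step
            ) * (2.0 / h_elem)
    return g


def _voigt(lam, mu):
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[3:, 3:] = np.eye(3) * mu
    return C


def _b_from_grad(g):
    B = np.zeros((6, 24))
    for i in range(8):
        dx, dy, dz = g[i]
        B[0, 3 * i] = dx
        B[1, 3 * i + 1] = dy
        B[2, 3 * i + 2] = dz
        B[3, 3 * i], B[3, 3 * i + 1] = dy, dx
        B[4, 3 * i + 1], B[4, 3 * i + 2] = dz, dy
        B[5, 3 * i], B[5, 3 * i + 2] = dz, dx
    return B


def dense_reference_pressure(grid, labels, props, strain):
    n = grid.nx
    h = grid.voxel_edge_mm
    nn = n + 1
    node_id = np.arange(nn**3).reshape(nn, nn, nn)
    ndof = 3 * nn**3
    K = np.zeros((ndof, ndof))
    f = np.zeros(ndof)
    gp = [-1 / np.sqrt(3), 1 / np.sqrt(3)]
    detJ = (h / 2) ** 3
    m = np.array([1.0, 1, 1, 0, 0, 0])
    elems = []
    for ex in range(n):
        for ey in range(n):
            for ez in range(n):
                e = ex * n * n + ey * n + ez
                nodes = [
                    node_id[ex + a, ey + b, ez + c]
                    for c in (0, 1) for b in (0, 1) for a in (0, 1)
                ]
                # reorder to the x-fastest local convention
                nodes = [
                    node_id[ex + a, ey + b, ez + c]
                    for (a, b, c) in [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
                                      (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)]
                ]
                dofs = np.array([[3 * nd, 3 * nd + 1, 3 * nd + 2] for nd in nodes]).ravel()
                lam, mu = props.lame(int(labels[e]))
                C = _voigt(lam, mu)
                Ke = np.zeros((24, 24))
                fe = np.zeros(24)
                for gx in gp:
                    for gy in gp:
                        for gz in gp:
                            B = _b_from_grad(_fd_gradients((gx, gy, gz), h))
                            Ke += B.T @ C @ B * detJ
                            fe += B.T @ (C @ (strain[e] * m)) * detJ
                K[np.ix_(dofs, dofs)] += Ke
                f[dofs] += fe
                elems.append((e, dofs, C, lam, mu))
    boundary = np.zeros(nn**3, bool)
    gx, gy, gz = np.meshgrid(range(nn), range(nn), range(nn), indexing="ij")
    boundary |= ((gx == 0) | (gx == n) | (gy == 0) | (gy == n)
                 | (gz == 0) | (gz == n)).ravel()
    fixed = np.repeat(boundary, 3)
    free = ~fixed
    u = np.zeros(ndof)
    u[free] = np.linalg.solve(K[np.ix_(free, free)], f[free])
    p = np.zeros(n**3)
    for e, dofs, C, lam, mu in elems:
        B = _b_from_grad(_fd_gradients((0.0, 0.0, 0.0), h))
        eps = B @ u[dofs]
        sigma = C @ (eps - strain[e] * m)
        p[e] = sigma[:3].sum() / 3.0
    return p


def test_voxel_solver_matches_dense_reference():
    rng = np.random.default_rng(2)
    n = 5
    grid = VoxelGrid(n, n, n)
    labels = rng.integers(0, 2, size=grid.n_voxels)
    props = MechanicalProperties({0: (5.0e3, 0.40), 1: (2.0e4, 0.35)})
    strain = rng.normal(0, 0.02, size=grid.n_voxels)
    strain = np.clip(strain, -0.05, 0.05)
    p_ref = dense_reference_pressure(grid, labels, props, strain)
    p = solve_pressure(grid, labels, props, strain)
    scale = np.abs(p_ref).max()
    assert np.abs(p - p_ref).max() / scale < 1e-6


def test_missing_label_properties_rejected():
    grid, labels, strain = _inclusion(5)
    labels[0] = 7
    with pytest.raises(KeyError, match="7"):
        solve_pressure(grid, labels, SOFT, strain)


class TestDirectionField:
    def test_linear_ramp_points_down_gradient(self):
        grid = VoxelGrid(6, 6, 6)
        x = np.stack(np.unravel_index(np.arange(grid.n_voxels), grid.shape), 1)[:, 0]
        d = least_pressure_direction(x.astype(float), grid)
        assert np.allclose(d, [-1.0, 0.0, 0.0])

    def test_uniform_pressure_gives_zero_vectors(self):
        grid = VoxelGrid(5, 5, 5)
        d = least_pressure_direction(np.full(grid.n_voxels, 3.7), grid)
        assert np.abs(d).max() == 0.0

    def test_invariant_to_constant_offset_and_unit_norm(self):
        rng = np.random.default_rng(1)
        grid = VoxelGrid(6, 6, 6)
        p = rng.normal(size=grid.n_voxels)
        d1 = least_pressure_direction(p, grid)
        d2 = least_pressure_direction(p + 100.0, grid)
        assert np.allclose(d1, d2)
        norms = np.linalg.norm(d1, axis=1)
        assert np.all((np.abs(norms - 1.0) < 1e-9) | (norms == 0.0))

    def test_radial_bowl_points_toward_center(self):
        grid = VoxelGrid(9, 9, 9)
        centers = grid.voxel_centers()
        mid = centers.mean(axis=0)
        r = np.linalg.norm(centers - mid, axis=1)
        d = least_pressure_direction(r**2, grid)
        inward = centers - mid
        inward /= np.maximum(np.linalg.norm(inward, axis=1)[:, None], 1e-12)
        interior = (np.abs(centers - mid) < 2.5).all(axis=1) & (r > 0.6)
        cosine = (d[interior] * -inward[interior]).sum(axis=1)
        assert cosine.min() > 0.9
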