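"""Surface generation, stitching, tiling and decomposition."""

import math
from collections import Counter

import numpy as np
import pytest

from cawave.geometry import (CELLS_PER_QUAD, EC_PER_QUAD, SMC_PER_QUAD,
                             BifurcationMesh, GeometrySpec, PatchBoundary,
                             biharmonic_residual, build_bifurcation,
                             build_tube, decompose_domains, solve_biharmonic,
                             tile_cells)


# ---------------------------------------------------------------------------
# biharmonic patch solver


def _planar_patch(m=8, n=6, a=0.5):
    """Boundary of a flat tilted plane z = 0.3 x + 0.1 y."""
    def plane(x, y):
        return np.stack([x, y, 0.3 * x + 0.1 * y], axis=-1)

    iu = np.arange(m + 1, dtype=float)
    jv = np.arange(n + 1, dtype=float)
    dirichlet = {
        "u0": plane(np.zeros(n + 1), jv),
        "u1": plane(np.full(n + 1, float(m)), jv),
        "v0": plane(iu, np.zeros(m + 1)),
        "v1": plane(iu, np.full(m + 1, float(n))),
    }
    du = np.array([1.0, 0.0, 0.3])
    dv = np.array([0.0, 1.0, 0.1])
    neumann = {"u0": np.tile(du, (n + 1, 1)), "u1": np.tile(-du, (n + 1, 1)),
               "v0": np.tile(dv, (m + 1, 1)), "v1": np.tile(-dv, (m + 1, 1))}
    return PatchBoundary(m=m, n=n, dirichlet=dirichlet, neumann=neumann, a=a)


def test_planar_boundary_gives_coplanar_interior():
    grid = solve_biharmonic(_planar_patch())
    z_pred = 0.3 * grid[..., 0] + 0.1 * grid[..., 1]
    assert np.max(np.abs(grid[..., 2] - z_pred)) < 1e-10


def test_interior_satisfies_discrete_operator():
    """Direct stencil residual check, independent of the assembly path."""
    b = _planar_patch(m=10, n=8, a=0.7)
    grid = solve_biharmonic(b)
    assert biharmonic_residual(grid, b.a) < 1e-8


def test_solution_matches_dense_solve_oracle():
    """Sparse solve equals a dense solve of an independently built system.

    The oracle builds the full operator column by column by applying the
    stencil to unit vectors on the padded (ghosted) grid.
    """
    b = _planar_patch(m=5, n=4, a=0.8)
    grid = solve_biharmonic(b)
    m, n, a = b.m, b.n, b.a
    a2, a4 = a * a, a ** 4
    stencil = {(-2, 0): 1, (2, 0): 1, (0, -2): a4, (0, 2): a4,
               (-1, 0): -4 - 4 * a2, (1, 0): -4 - 4 * a2,
               (0, -1): -4 * a4 - 4 * a2, (0, 1): -4 * a4 - 4 * a2,
               (-1, -1): 2 * a2, (-1, 1): 2 * a2, (1, -1): 2 * a2,
               (1, 1): 2 * a2, (0, 0): 6 + 6 * a4 + 8 * a2}

    for coord in range(3):
        def op(phi_int):
            # pad with Dirichlet boundary and Neumann ghosts
            full = np.zeros((m + 3, n + 3))     # index shift +1
            full[1, 1:n + 2] = b.dirichlet["u0"][:, coord]
            full[m + 1, 1:n + 2] = b.dirichlet["u1"][:, coord]
            full[1:m + 2, 1] = b.dirichlet["v0"][:, coord]
            full[1:m + 2, n + 1] = b.dirichlet["v1"][:, coord]
            full[2:m + 1, 2:n + 1] = phi_int
            full[0, 1:n + 2] = full[2, 1:n + 2] \
                - 2 * b.neumann["u0"][:, coord]
            full[m + 2, 1:n + 2] = full[m, 1:n + 2] \
                - 2 * b.neumann["u1"][:, coord]
            full[1:m + 2, 0] = full[1:m + 2, 2] \
                - 2 * b.neumann["v0"][:, coord]
            full[1:m + 2, n + 2] = full[1:m + 2, n] \
                - 2 * b.neumann["v1"][:, coord]
            res = np.zeros((m - 1, n - 1))
            for (di, dj), cfc in stencil.items():
                res += cfc * full[2 + di:m + 1 + di, 2 + dj:n + 1 + dj]
            return res.ravel()

        nunk = (m - 1) * (n - 1)
        A = np.empty((nunk, nunk))
        rhs0 = op(np.zeros((m - 1, n - 1)))
        for k in range(nunk):
            e = np.zeros(nunk)
            e[k] = 1.0
            A[:, k] = op(e.reshape(m - 1, n - 1)) - rhs0
        dense = np.linalg.solve(A, -rhs0).reshape(m - 1, n - 1)
        assert np.allclose(grid[1:m, 1:n, coord], dense, atol=1e-9)


def test_singular_boundary_reported():
    b = _planar_patch()
    b.dirichlet["u0"][:] = np.nan
    with pytest.raises(RuntimeError, match="singular|deficient"):
        solve_biharmonic(b)


# ---------------------------------------------------------------------------
# geometry spec and census


def test_spec_validation():
    with pytest.raises(ValueError):
        GeometrySpec(branch_length=-1.0, diameter=1.0)
    with pytest.raises(ValueError):
        GeometrySpec(branch_length=1.0, diameter=1.0, branch_angle=120.0)


def test_printed_mesh_rows_reproduce_quad_counts():
    """The two published meshes follow from the physical quad footprint."""
    row1 = GeometrySpec(branch_length=8.84, diameter=2.55, branch_angle=30.0)
    row2 = GeometrySpec(branch_length=10.92, diameter=4.08,
                        branch_angle=30.0)
    assert 3 * row1.m * row1.n == 4080
    assert 3 * row2.m * row2.n == 8064


def test_cylinder_recovery_within_one_percent():
    spec = GeometrySpec(branch_length=2.6, diameter=2.55)
    mesh = build_tube(spec)
    nodes = mesh.segments[0].nodes
    radius = np.sqrt(nodes[..., 1] ** 2 + nodes[..., 2] ** 2)
    assert np.max(np.abs(radius - spec.diameter / 2)) < 0.01 * spec.diameter


def test_tiling_census(mini_tube):
    assert EC_PER_QUAD == 80 and SMC_PER_QUAD == 208
    assert CELLS_PER_QUAD == 288
    assert mini_tube.n_ec == mini_tube.n_quads * 80
    assert mini_tube.n_smc == mini_tube.n_quads * 208
    for q in range(mini_tube.n_quads):
        assert np.sum(mini_tube.ec.quad == q) == 80
        assert np.sum(mini_tube.smc.quad == q) == 208


def test_unit_area_bookkeeping():
    """5 ECs of 65 x 10 um cover the same area as 13 SMCs of 50 x 5 um."""
    ec_area = 65.0 * 10.0
    smc_area = 50.0 * 5.0
    assert 5 * ec_area == 13 * smc_area
    assert round(5 * ec_area / smc_area) == 13


def _edge_counter(mesh: BifurcationMesh) -> Counter:
    corners = mesh.quad_corner_ids()
    cnt = Counter()
    for q in corners:
        for a, b in zip(q, np.roll(q, 1)):
            cnt[frozenset((int(a), int(b)))] += 1
    return cnt


@pytest.fixture(scope="module")
def mini_bif():
    spec = GeometrySpec(branch_length=1.04, diameter=4 * 0.2 / math.pi,
                        quads_axial=4, quads_circ=8)
    return tile_cells(build_bifurcation(spec))


def test_bifurcation_watertight(mini_bif):
    """Every interior mesh edge is shared by exactly two quads."""
    cnt = _edge_counter(mini_bif)
    shares = Counter(cnt.values())
    n = mini_bif.spec.n
    assert set(shares) == {1, 2}
    assert shares[1] == 3 * n          # the three open rings
    boundary_share = shares[1]
    interior = sum(v for v in cnt.values() if v == 2) // 2
    assert interior + boundary_share == len(cnt)


def test_bifurcation_euler_characteristic(mini_bif):
    """V - E + F of the open surface equals -1 (pair of pants)."""
    nodes, _ = mini_bif.global_nodes()
    cnt = _edge_counter(mini_bif)
    chi = len(nodes) - len(cnt) + mini_bif.n_quads
    assert chi == -1


def test_bifurcation_axial_coordinates(mini_bif):
    """Parent cells upstream (negative), branch cells downstream."""
    parent = mini_bif.ec.seg == 0
    assert np.all(mini_bif.ec.axial[parent] < 0)
    assert np.all(mini_bif.ec.axial[~parent] > 0)


def test_domain_decomposition(mini_tube, mini_bif):
    dm = decompose_domains(mini_tube)
    assert dm.n_domains == mini_tube.n_quads
    # every quad domain touches its axial and circumferential neighbours
    # (n=4 ring: left and right neighbour coincide when wrapped)
    for d, nbrs in dm.neighbors.items():
        assert 2 <= len(nbrs) <= 4
    dmb = decompose_domains(mini_bif)
    sizes = [len(v) for v in dmb.neighbors.values()]
    assert min(sizes) >= 2


def test_untiled_mesh_rejected():
    spec = GeometrySpec(branch_length=0.52, diameter=0.26, quads_axial=2,
                        quads_circ=4)
    mesh = build_tube(spec)
    with pytest.raises(ValueError, match="tiled"):
        decompose_domains(mesh)
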