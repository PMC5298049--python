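"""Tube and Y-bifurcation quad surface meshes with EC/SMC tilings.

Surfaces are generated patchwise by solving the anisotropic biharmonic
equation ``(d^2/du^2 + a^2 d^2/dv^2)^2 phi = 0`` per coordinate on a
parameter rectangle, with Dirichlet positions and Neumann (inward
cross-derivative) data on the four edges.  A segment (parent or branch) is a
full tube assembled from two half-tube patches; a bifurcation is three
segments stitched along shared junction curves, giving the pair-of-pants
topology.

Every quadrilateral carries a fixed 4 x 4 grid of "fundamental units", each
unit holding 5 endothelial cells (65 x 10 um footprint, long axis axial) and
13 smooth muscle cells (50 x 5 um, long axis circumferential) of equal total
area, i.e. 80 EC + 208 SMC = 288 cells per quad.  A quad is therefore
260 um (axial) x 200 um (circumferential) of vessel wall.

Lengths are in mm; cell footprints quoted in um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

__all__ = [
    "QUAD_AXIAL_MM",
    "QUAD_CIRC_MM",
    "GeometrySpec",
    "PatchBoundary",
    "solve_biharmonic",
    "biharmonic_residual",
    "BifurcationMesh",
    "build_tube",
    "build_bifurcation",
    "tile_cells",
    "decompose_domains",
    "DomainMap",
]

# physical quad extents implied by the printed cell footprints
EC_LEN_UM, EC_WID_UM = 65.0, 10.0     # axial x circumferential
SMC_LEN_UM, SMC_WID_UM = 50.0, 5.0    # circumferential x axial
UNITS_PER_QUAD = 4                    # 4 x 4 fundamental units
EC_PER_UNIT, SMC_PER_UNIT = 5, 13
QUAD_AXIAL_MM = UNITS_PER_QUAD * EC_LEN_UM * 1e-3       # 0.26 mm
QUAD_CIRC_MM = UNITS_PER_QUAD * SMC_LEN_UM * 1e-3       # 0.20 mm

EC_AX, EC_CIRC = UNITS_PER_QUAD, UNITS_PER_QUAD * EC_PER_UNIT      # 4 x 20
SMC_AX, SMC_CIRC = UNITS_PER_QUAD * SMC_PER_UNIT, UNITS_PER_QUAD   # 52 x 4

EC_PER_QUAD = EC_AX * EC_CIRC          # 80
SMC_PER_QUAD = SMC_AX * SMC_CIRC       # 208
CELLS_PER_QUAD = EC_PER_QUAD + SMC_PER_QUAD

SEAM_TOL = 1e-9   # node merge tolerance, mm


@dataclass
class GeometrySpec:
    """Geometric parameters of a straight tube or symmetric Y-bifurcation.

    ``branch_length`` is the centreline length of each segment (mm),
    ``diameter`` the vessel diameter (mm) and ``branch_angle`` the angle of
    each daughter centreline to the parent axis (degrees).  ``quads_axial``
    and ``quads_circ`` override the per-segment quad resolution; by default
    they are derived from the physical quad size (0.26 x 0.20 mm), which is
    what ties the printed meshes to their cell census.
    """

    branch_length: float
    diameter: float
    branch_angle: float = 30.0
    quads_axial: int | None = None
    quads_circ: int | None = None
    anisotropy: float = 0.1

    def __post_init__(self) -> None:
        if self.branch_length <= 0 or self.diameter <= 0:
            raise ValueError("branch_length and diameter must be positive")
        if not (0.0 < self.branch_angle < 90.0):
            raise ValueError("branch_angle must lie in (0, 90) degrees")

    @property
    def m(self) -> int:
        if self.quads_axial is not None:
            return int(self.quads_axial)
        return max(3, round(self.branch_length / QUAD_AXIAL_MM))

    @property
    def n(self) -> int:
        if self.quads_circ is not None:
            return int(self.quads_circ)
        n = max(4, round(math.pi * self.diameter / QUAD_CIRC_MM))
        return n + (-n) % 4   # multiple of 4: two patches, four junction arcs

    @property
    def max_length(self) -> float:
        return 2.0 * self.branch_length


# ---------------------------------------------------------------------------
# biharmonic patch solver


@dataclass
class PatchBoundary:
    """Boundary data of one biharmonic patch on an (m+1) x (n+1) node grid.

    ``dirichlet`` holds the four edge polylines of 3D positions:
    ``u0``/``u1`` of shape (n+1, 3) and ``v0``/``v1`` of shape (m+1, 3); the
    corner points must agree between adjacent edges.  ``neumann`` holds the
    inward cross-derivative vectors (same shapes, units mm per unit
    parameter).  ``a`` is the anisotropy constant weighting the v (circum-
    ferential) derivatives.
    """

    m: int
    n: int
    dirichlet: dict[str, np.ndarray]
    neumann: dict[str, np.ndarray]
    a: float = 0.1

    def __post_init__(self) -> None:
        if self.m < 2 or self.n < 2:
            raise ValueError("patch resolution must be at least 2 x 2")
        for key, rows in (("u0", self.n), ("u1", self.n),
                          ("v0", self.m), ("v1", self.m)):
            for store, what in ((self.dirichlet, "dirichlet"),
                                (self.neumann, "neumann")):
                arr = np.asarray(store[key], dtype=float)
                if arr.shape != (rows + 1, 3):
                    raise ValueError(
                        f"{what}[{key!r}] must have shape {(rows + 1, 3)}")
                store[key] = arr


def _full_grid_with_boundary(b: PatchBoundary) -> np.ndarray:
    """(m+1, n+1, 3) array with boundary rows/cols filled, interior NaN."""
    g = np.full((b.m + 1, b.n + 1, 3), np.nan)
    g[0, :] = b.dirichlet["u0"]
    g[b.m, :] = b.dirichlet["u1"]
    g[:, 0] = b.dirichlet["v0"]
    g[:, b.n] = b.dirichlet["v1"]
    return g


def solve_biharmonic(boundary: PatchBoundary) -> np.ndarray:
    """Solve the patch PDE; returns the (m+1, n+1, 3) node grid.

    Discretisation: 13-point finite-difference stencil of
    ``(D_uu + a^2 D_vv)^2`` on the unit-spaced parameter grid; Dirichlet
    imposed exactly on edge nodes, Neumann through one ghost layer
    (``phi_ghost = phi_mirror - 2 * d``), sparse direct solve per
    coordinate.
    """
    m, n, a = boundary.m, boundary.n, boundary.a
    grid = _full_grid_with_boundary(boundary)
    a2, a4 = a * a, a ** 4

    # 13-point stencil offsets and coefficients for D4u + 2 a^2 D2uD2v + a^4 D4v
    stencil = {
        (-2, 0): 1.0, (2, 0): 1.0, (0, -2): a4, (0, 2): a4,
        (-1, 0): -4.0 - 4.0 * a2, (1, 0): -4.0 - 4.0 * a2,
        (0, -1): -4.0 * a4 - 4.0 * a2, (0, 1): -4.0 * a4 - 4.0 * a2,
        (-1, -1): 2.0 * a2, (-1, 1): 2.0 * a2,
        (1, -1): 2.0 * a2, (1, 1): 2.0 * a2,
        (0, 0): 6.0 + 6.0 * a4 + 8.0 * a2,
    }

    n_int = (m - 1) * (n - 1)
    if n_int <= 0:
        raise ValueError("no interior nodes to solve for")

    def idx(i: int, j: int) -> int:
        return (i - 1) * (n - 1) + (j - 1)

    # ghost values: phi[-1, j] = phi[1, j] - 2 * neumann_u0[j], etc.
    neu = boundary.neumann
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    rhs = np.zeros((n_int, 3))

    for i in range(1, m):
        for j in range(1, n):
            r = idx(i, j)
            for (di, dj), c in stencil.items():
                ii, jj = i + di, j + dj
                extra = np.zeros(3)
                if ii == -1:
                    ii, extra = 1, -2.0 * neu["u0"][jj]
                elif ii == m + 1:
                    ii, extra = m - 1, -2.0 * neu["u1"][jj]
                if jj == -1:
                    jj, extra = 1, -2.0 * neu["v0"][ii]
                elif jj == n + 1:
                    jj, extra = n - 1, -2.0 * neu["v1"][ii]
                rhs[r] -= c * extra
                if 1 <= ii <= m - 1 and 1 <= jj <= n - 1:
                    rows.append(r)
                    cols.append(idx(ii, jj))
                    vals.append(c)
                else:
                    rhs[r] -= c * grid[ii, jj]

    mat = sp.csr_matrix((vals, (rows, cols)), shape=(n_int, n_int))
    try:
        sol = spsolve(mat.tocsc(), rhs)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            "biharmonic system is singular; check boundary data") from exc
    if np.any(~np.isfinite(sol)):
        raise RuntimeError("biharmonic system is singular or boundary "
                           "data deficient (non-finite solution)")
    grid[1:m, 1:n] = sol.reshape(m - 1, n - 1, 3)
    return grid


def biharmonic_residual(grid: np.ndarray, a: float) -> float:
    """Max |stencil residual| over deep-interior nodes (diagnostic)."""
    m, n = grid.shape[0] - 1, grid.shape[1] - 1
    if m < 4 or n < 4:
        return 0.0
    a2, a4 = a * a, a ** 4
    g = grid
    c = g[2:m - 1, 2:n - 1]

    def sh(di, dj):
        return g[2 + di:m - 1 + di, 2 + dj:n - 1 + dj]

    res = (sh(-2, 0) + sh(2, 0) + a4 * (sh(0, -2) + sh(0, 2))
           + (-4 - 4 * a2) * (sh(-1, 0) + sh(1, 0))
           + (-4 * a4 - 4 * a2) * (sh(0, -1) + sh(0, 1))
           + 2 * a2 * (sh(-1, -1) + sh(-1, 1) + sh(1, -1) + sh(1, 1))
           + (6 + 6 * a4 + 8 * a2) * c)
    return float(np.max(np.abs(res)))


# ---------------------------------------------------------------------------
# segments and meshes


@dataclass
class Segment:
    """One tubular segment: (m+1) x n node grid, periodic in v.

    ``nodes[i, j]`` is the 3D position of node (axial i, circumferential j);
    column ``n`` wraps to column ``0``.  ``axial0`` is the centreline arc-
    length coordinate of node row 0, measured from the bifurcation point
    (negative upstream, positive downstream); rows advance by ``axial_step``.
    """

    name: str
    m: int
    n: int
    nodes: np.ndarray              # (m+1, n, 3)
    axial0: float
    axial_step: float

    def node_ring(self, i: int) -> np.ndarray:
        return self.nodes[i]

    def axial_of_row(self, i) -> np.ndarray:
        return self.axial0 + np.asarray(i, dtype=float) * self.axial_step


@dataclass
class CellField:
    """Per-layer cell bookkeeping produced by :func:`tile_cells`."""

    seg: np.ndarray        # (ncell,) segment index
    iu: np.ndarray         # axial grid row within segment
    jv: np.ndarray         # circumferential grid column within segment
    quad: np.ndarray       # (ncell,) global quad id
    axial: np.ndarray      # (ncell,) centreline coordinate, mm
    centroid: np.ndarray   # (ncell, 3) mm

    @property
    def count(self) -> int:
        return self.seg.size


class BifurcationMesh:
    """A stitched tube or Y-bifurcation surface with per-quad cell tilings."""

    def __init__(self, spec: GeometrySpec, segments: list[Segment]):
        self.spec = spec
        self.segments = segments
        self.n = spec.n
        # global quad enumeration: segment-major, axial-major, circumferential
        self.quads: list[tuple[int, int, int]] = []
        for si, seg in enumerate(segments):
            for iu in range(seg.m):
                for jv in range(seg.n):
                    self.quads.append((si, iu, jv))
        self._quad_id = {q: k for k, q in enumerate(self.quads)}
        self.ec: CellField | None = None
        self.smc: CellField | None = None

    # -- basic census ------------------------------------------------------

    @property
    def n_quads(self) -> int:
        return len(self.quads)

    @property
    def is_bifurcation(self) -> bool:
        return len(self.segments) == 3

    def quad_id(self, seg: int, iu: int, jv: int) -> int:
        return self._quad_id[(seg, iu, jv % self.segments[seg].n)]

    @property
    def n_ec(self) -> int:
        return self.n_quads * EC_PER_QUAD

    @property
    def n_smc(self) -> int:
        return self.n_quads * SMC_PER_QUAD

    @property
    def n_cells(self) -> int:
        return self.n_quads * CELLS_PER_QUAD

    @property
    def tiled(self) -> bool:
        return self.ec is not None

    # -- layer grid shapes -------------------------------------------------

    def layer_shape(self, seg: int, layer: str) -> tuple[int, int]:
        s = self.segments[seg]
        if layer == "ec":
            return s.m * EC_AX, s.n * EC_CIRC
        return s.m * SMC_AX, s.n * SMC_CIRC

    def layer_offsets(self, layer: str) -> list[int]:
        """Start index of each segment's cells in the global enumeration."""
        offs, tot = [], 0
        for si in range(len(self.segments)):
            offs.append(tot)
            rows, cols = self.layer_shape(si, layer)
            tot += rows * cols
        return offs

    def cell_index(self, layer: str, seg: int, iu, jv):
        """Global cell index from (segment, axial row, circ column)."""
        rows, cols = self.layer_shape(seg, layer)
        off = self.layer_offsets(layer)[seg]
        return off + np.asarray(iu) * cols + np.asarray(jv) % cols

    # -- geometry helpers --------------------------------------------------

    def interpolate(self, seg: int, fu, fv) -> np.ndarray:
        """Bilinear position at fractional grid coords (fu in [0,m], fv wraps)."""
        s = self.segments[seg]
        fu = np.clip(np.asarray(fu, dtype=float), 0.0, s.m)
        fv = np.asarray(fv, dtype=float) % s.n
        i0 = np.minimum(fu.astype(int), s.m - 1)
        j0 = fv.astype(int) % s.n
        tu = (fu - i0)[..., None]
        tv = (fv - j0)[..., None]
        j1 = (j0 + 1) % s.n
        p00 = s.nodes[i0, j0]
        p10 = s.nodes[i0 + 1, j0]
        p01 = s.nodes[i0, j1]
        p11 = s.nodes[i0 + 1, j1]
        return ((1 - tu) * (1 - tv) * p00 + tu * (1 - tv) * p10
                + (1 - tu) * tv * p01 + tu * tv * p11)

    def global_nodes(self) -> tuple[np.ndarray, list[np.ndarray]]:
        """Merged node table; returns (nodes, per-segment id grids).

        Nodes closer than the seam tolerance collapse to a single entry, so
        shared seam/junction samples become shared mesh nodes.
        """
        table: dict[tuple[int, int, int], int] = {}
        nodes: list[np.ndarray] = []
        id_grids = []
        for seg in self.segments:
            ids = np.empty((seg.m + 1, seg.n), dtype=int)
            for i in range(seg.m + 1):
                for j in range(seg.n):
                    p = seg.nodes[i, j]
                    key = tuple(int(round(x / SEAM_TOL / 1e3)) for x in p)
                    if key not in table:
                        table[key] = len(nodes)
                        nodes.append(p)
                    ids[i, j] = table[key]
            id_grids.append(ids)
        return np.array(nodes), id_grids

    def quad_corner_ids(self) -> np.ndarray:
        """(Q, 4) corner node ids (ccw) into the merged node table."""
        _, id_grids = self.global_nodes()
        out = np.empty((self.n_quads, 4), dtype=int)
        for k, (si, iu, jv) in enumerate(self.quads):
            ids = id_grids[si]
            nn = self.segments[si].n
            out[k] = (ids[iu, jv], ids[iu, (jv + 1) % nn],
                      ids[iu + 1, (jv + 1) % nn], ids[iu + 1, jv])
        return out


# -- boundary data factories -------------------------------------------------


def _half_tube_patch(spec: GeometrySpec, axis_origin: np.ndarray,
                     axis_dir: np.ndarray, e_z: np.ndarray, e_w: np.ndarray,
                     length: float, m: int, n_half: int,
                     theta0: float,
                     end_curve: np.ndarray | None = None) -> PatchBoundary:
    """Boundary data for one half-tube patch.

    The patch spans angles ``theta0 .. theta0 + pi`` around ``axis_dir``
    (radial direction ``cos(theta) e_z + sin(theta) e_w``) and axial
    parameter 0..length.  If ``end_curve`` is given (shape (n_half+1, 3)), it
    replaces the u1 edge (junction side); the u1 Neumann then points from
    the curve back along the axis.
    """
    r = spec.diameter / 2.0
    th = theta0 + np.linspace(0.0, math.pi, n_half + 1)
    ring = (np.cos(th)[:, None] * e_z + np.sin(th)[:, None] * e_w) * r
    du = (length / m) * axis_dir

    u0 = axis_origin + ring
    u1 = axis_origin + length * axis_dir + ring if end_curve is None \
        else np.asarray(end_curve, dtype=float)
    tu = np.linspace(0.0, 1.0, m + 1)[:, None]
    v0 = u0[0] * (1 - tu) + u1[0] * tu
    v1 = u0[-1] * (1 - tu) + u1[-1] * tu

    # inward cross-derivatives: axial at the u edges, circumferential at seams
    dth = math.pi / n_half
    tang0 = (-np.sin(th[0]) * e_z + np.cos(th[0]) * e_w) * r * dth
    tang1 = (-np.sin(th[-1]) * e_z + np.cos(th[-1]) * e_w) * r * dth
    neu = {
        "u0": np.tile(du, (n_half + 1, 1)),
        "u1": np.tile(-du, (n_half + 1, 1)),
        "v0": np.tile(tang0, (m + 1, 1)),
        "v1": np.tile(-tang1, (m + 1, 1)),
    }
    dir_ = {"u0": u0, "u1": u1, "v0": v0, "v1": v1}
    return PatchBoundary(m=m, n=n_half, dirichlet=dir_, neumann=neu,
                         a=spec.anisotropy)


def _segment_from_patches(name: str, spec: GeometrySpec, m: int,
                          patches: tuple[PatchBoundary, PatchBoundary],
                          axial0: float, axial_step: float) -> Segment:
    """Solve the two half patches and merge into one periodic node grid."""
    n = spec.n
    g0 = solve_biharmonic(patches[0])
    g1 = solve_biharmonic(patches[1])
    nodes = np.empty((m + 1, n, 3))
    half = n // 2
    # patch 0 covers columns 0..half (inclusive), patch 1 covers half..n (=0)
    nodes[:, :half] = g0[:, :half]
    nodes[:, half:] = g1[:, :half]
    # seams: average the two patch copies (they agree by construction)
    nodes[:, 0] = 0.5 * (g0[:, 0] + g1[:, half])
    nodes[:, half] = 0.5 * (g0[:, half] + g1[:, 0])
    return Segment(name=name, m=m, n=n, nodes=nodes,
                   axial0=axial0, axial_step=axial_step)


def build_tube(spec: GeometrySpec) -> BifurcationMesh:
    """Straight tube along +x, inlet at axial coordinate 0."""
    m, n = spec.m, spec.n
    ex = np.array([1.0, 0.0, 0.0])
    ez = np.array([0.0, 0.0, 1.0])
    ew = np.array([0.0, 1.0, 0.0])
    L = spec.branch_length
    p0 = _half_tube_patch(spec, np.zeros(3), ex, ez, ew, L, m, n // 2, 0.0)
    p1 = _half_tube_patch(spec, np.zeros(3), ex, ez, ew, L, m, n // 2,
                          math.pi)
    seg = _segment_from_patches("tube", spec, m, (p0, p1), 0.0, L / m)
    return BifurcationMesh(spec, [seg])


def _junction_curves(spec: GeometrySpec) -> dict[str, np.ndarray]:
    """Sampled seam curves of the junction, shared verbatim by the patches.

    ``pb1``/``pb2``: parent-to-branch seams (on the parent cylinder, bulging
    to the shoulder points at y = +/-r); ``carina``: branch-to-branch seam,
    the exact intersection ellipse of the two branch cylinders.  Each is
    sampled at n/2 + 1 points from the top pole P+ = (0, 0, r) to the bottom
    pole P- = (0, 0, -r).
    """
    r = spec.diameter / 2.0
    n = spec.n
    alpha = math.radians(spec.branch_angle)
    t = np.linspace(0.0, math.pi, n // 2 + 1)
    # shoulder x-offset: crossing of parent and branch outer wall lines
    x_sh = r * ((1 - math.cos(alpha)) * math.cos(alpha) / math.sin(alpha)
                - math.sin(alpha))
    pb1 = np.stack([x_sh * np.sin(t), r * np.sin(t), r * np.cos(t)], axis=1)
    pb2 = pb1 * np.array([1.0, -1.0, 1.0])
    carina = np.stack([(r / math.sin(alpha)) * np.sin(t),
                       np.zeros_like(t), r * np.cos(t)], axis=1)
    return {"pb1": pb1, "pb2": pb2, "carina": carina}


def build_bifurcation(spec: GeometrySpec) -> BifurcationMesh:
    """Symmetric planar Y-bifurcation: parent + two daughter segments.

    The parent runs along +x and ends on the junction curves; daughters
    leave at +/- branch_angle in the xy-plane.  Axial (centreline)
    coordinates are negative in the parent, zero at the junction and
    positive in the branches.
    """
    m, n = spec.m, spec.n
    half = n // 2
    r = spec.diameter / 2.0
    alpha = math.radians(spec.branch_angle)
    L = spec.branch_length
    ez = np.array([0.0, 0.0, 1.0])
    cur = _junction_curves(spec)

    # parent: axis +x from x = -L, angle theta measured from +z toward +y
    ex = np.array([1.0, 0.0, 0.0])
    ey = np.array([0.0, 1.0, 0.0])
    origin = np.array([-L, 0.0, 0.0])
    # patch A: theta 0..pi (y > 0 side), junction edge = pb1 from P+ to P-;
    # patch B: theta pi..2pi, junction edge = pb2 traversed P- to P+
    pA = _half_tube_patch(spec, origin, ex, ez, ey, L, m, half, 0.0,
                          end_curve=cur["pb1"])
    pB = _half_tube_patch(spec, origin, ex, ez, ey, L, m, half, math.pi,
                          end_curve=cur["pb2"][::-1])
    parent = _segment_from_patches("parent", spec, m, (pA, pB),
                                   -L, L / m)

    segs = [parent]
    for bi, sign in ((1, +1.0), (2, -1.0)):
        d = np.array([math.cos(alpha), sign * math.sin(alpha), 0.0])
        w = np.array([-math.sin(alpha), sign * math.cos(alpha), 0.0])
        outer_seam = cur["pb1"] if sign > 0 else cur["pb2"]
        # outer patch: theta 0..pi (radial cos t * ez + sin t * w), edge on
        # the parent seam; inner patch: theta pi..2pi, edge on the carina
        p_out = _branch_patch(spec, d, w, ez, L, m, half, outer_seam, 0.0)
        p_in = _branch_patch(spec, d, w, ez, L, m, half,
                             cur["carina"][::-1], math.pi)
        seg = _segment_from_patches(f"branch{bi}", spec, m, (p_out, p_in),
                                    0.0, L / m)
        segs.append(seg)
    return BifurcationMesh(spec, segs)


def _branch_patch(spec: GeometrySpec, axis_dir, e_w, e_z, length, m, n_half,
                  start_curve: np.ndarray, theta0: float) -> PatchBoundary:
    """Half-tube patch of a daughter branch, junction curve at u = 0."""
    r = spec.diameter / 2.0
    th = theta0 + np.linspace(0.0, math.pi, n_half + 1)
    ring = (np.cos(th)[:, None] * e_z + np.sin(th)[:, None] * e_w) * r
    end = length * np.asarray(axis_dir) + ring
    start = np.asarray(start_curve, dtype=float)
    du = (length / m) * np.asarray(axis_dir)
    tu = np.linspace(0.0, 1.0, m + 1)[:, None]
    v0 = start[0] * (1 - tu) + end[0] * tu
    v1 = start[-1] * (1 - tu) + end[-1] * tu
    dth = math.pi / n_half
    tang0 = (-np.sin(th[0]) * e_z + np.cos(th[0]) * np.asarray(e_w)) * r * dth
    tang1 = (-np.sin(th[-1]) * e_z + np.cos(th[-1]) * np.asarray(e_w)) * r * dth
    dir_ = {"u0": start, "u1": end, "v0": v0, "v1": v1}
    neu = {
        "u0": np.tile(du, (n_half + 1, 1)),
        "u1": np.tile(-du, (n_half + 1, 1)),
        "v0": np.tile(tang0, (m + 1, 1)),
        "v1": np.tile(-tang1, (m + 1, 1)),
    }
    return PatchBoundary(m=m, n=n_half, dirichlet=dir_, neumann=neu,
                         a=spec.anisotropy)


# ---------------------------------------------------------------------------
# cell tiling


def tile_cells(mesh: BifurcationMesh) -> BifurcationMesh:
    """Tile every quad with its 4 x 4 fundamental units (in place).

    Populates ``mesh.ec`` and ``mesh.smc`` with per-cell segment/grid
    indices, owning quad, centreline axial coordinate (mm) and 3D centroid.
    """
    for layer, (ax, circ) in (("ec", (EC_AX, EC_CIRC)),
                              ("smc", (SMC_AX, SMC_CIRC))):
        segs, ius, jvs, quads, axials, cents = [], [], [], [], [], []
        for si, seg in enumerate(mesh.segments):
            rows, cols = seg.m * ax, seg.n * circ
            iu, jv = np.meshgrid(np.arange(rows), np.arange(cols),
                                 indexing="ij")
            iu, jv = iu.ravel(), jv.ravel()
            qid = np.array([[mesh.quad_id(si, i, j) for j in range(seg.n)]
                            for i in range(seg.m)])
            quad = qid[iu // ax, jv // circ].ravel()
            fu = (iu + 0.5) / ax
            fv = (jv + 0.5) / circ
            cent = mesh.interpolate(si, fu, fv)
            axial = seg.axial_of_row(fu)
            segs.append(np.full(iu.size, si, dtype=np.int8))
            ius.append(iu.astype(np.int32))
            jvs.append(jv.astype(np.int32))
            quads.append(quad.astype(np.int32))
            axials.append(axial)
            cents.append(cent)
        field = CellField(
            seg=np.concatenate(segs), iu=np.concatenate(ius),
            jv=np.concatenate(jvs), quad=np.concatenate(quads),
            axial=np.concatenate(axials), centroid=np.vstack(cents))
        setattr(mesh, layer, field)
    return mesh


# ---------------------------------------------------------------------------
# domain decomposition


@dataclass
class DomainMap:
    """One quad = one computational domain.

    ``domain_of_quad`` is the identity map kept for clarity; ``ec_domain``
    and ``smc_domain`` give the owning domain of every cell; ``neighbors``
    maps a domain to the set of domains it shares cell edges with (through
    the in-segment grid, the circumferential wrap and the junction seams).
    """

    n_domains: int
    domain_of_quad: np.ndarray
    ec_domain: np.ndarray
    smc_domain: np.ndarray
    neighbors: dict[int, set[int]]


def decompose_domains(mesh: BifurcationMesh) -> DomainMap:
    if not mesh.tiled:
        raise ValueError("mesh must be tiled before domain decomposition")
    from .coupling import build_adjacency   # local import; cheap, cached edges

    adj = build_adjacency(mesh)
    nq = mesh.n_quads
    ecd = mesh.ec.quad
    smcd = mesh.smc.quad
    neighbors: dict[int, set[int]] = {d: set() for d in range(nq)}
    for pairs, dom in ((adj.ec_pairs, ecd), (adj.smc_pairs, smcd)):
        da, db = dom[pairs[:, 0]], dom[pairs[:, 1]]
        for x, y in zip(da[da != db], db[da != db]):
            neighbors[int(x)].add(int(y))
            neighbors[int(y)].add(int(x))
    return DomainMap(n_domains=nq, domain_of_quad=np.arange(nq),
                     ec_domain=ecd, smc_domain=smcd, neighbors=neighbors)
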