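"""Gap-junction coupling: cases, adjacency and the assembled tissue RHS.

Intercellular communication is linear gradient-driven exchange through gap
junctions: for a species x with rate g (1/s), a cell receives
``g * sum_k (x_k - x_self)`` from its neighbours.  Membrane potential uses
the pure diffusion form (the electro-diffusion drift term is neglected).
Homocellular coupling acts on the 4-neighbour grid of each layer
(circumferentially periodic, crossing quad and segment boundaries);
heterocellular coupling connects every EC to the 13 SMCs of its fundamental
unit with equal overlap weights.

The four coupling cases model healthy and pathological connexin expression:

=====  ====================  ==============  ===================
case   SMC homocellular      EC homocellular heterocellular
=====  ====================  ==============  ===================
1      V, Ca, IP3            V, Ca           V, IP3
2      V, Ca, IP3            V, Ca           V, IP3, Ca
3      V, Ca, IP3            V, Ca, IP3      V, IP3, Ca
4      V, Ca, IP3            IP3             IP3
=====  ====================  ==============  ===================

Case 4 mimics progressive atheroma in which Cx43 (IP3-permeable) dominates
after Cx37/Cx40 down-regulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp

from . import cell_models as cm
from .geometry import (BifurcationMesh, EC_CIRC, SMC_CIRC, EC_PER_UNIT,
                       SMC_PER_UNIT)

__all__ = [
    "CouplingConfig",
    "coupling_case",
    "gap_flux",
    "CellAdjacency",
    "build_adjacency",
    "StateLayout",
    "TissueModel",
    "tissue_rhs",
]


@dataclass(frozen=True)
class CouplingConfig:
    """Per-species gap-junction flags and rate coefficients (1/s)."""

    smc_homo_v: bool = True
    smc_homo_ca: bool = True
    smc_homo_ip3: bool = True
    ec_homo_v: bool = True
    ec_homo_ca: bool = True
    ec_homo_ip3: bool = False
    hetero_v: bool = True
    hetero_ca: bool = False
    hetero_ip3: bool = True
    g_v_homo: float = 1000.0
    g_chem_homo: float = 0.05
    g_v_hetero: float = 50.0
    g_ca_hetero: float = 0.05
    g_ip3_hetero: float = 0.0026

    def __post_init__(self) -> None:
        for name in ("g_v_homo", "g_chem_homo", "g_v_hetero",
                     "g_ca_hetero", "g_ip3_hetero"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def with_rates(self, **kw) -> "CouplingConfig":
        return replace(self, **kw)


_CASES = {
    1: dict(smc_homo_v=True, smc_homo_ca=True, smc_homo_ip3=True,
            ec_homo_v=True, ec_homo_ca=True, ec_homo_ip3=False,
            hetero_v=True, hetero_ca=False, hetero_ip3=True),
    2: dict(smc_homo_v=True, smc_homo_ca=True, smc_homo_ip3=True,
            ec_homo_v=True, ec_homo_ca=True, ec_homo_ip3=False,
            hetero_v=True, hetero_ca=True, hetero_ip3=True),
    3: dict(smc_homo_v=True, smc_homo_ca=True, smc_homo_ip3=True,
            ec_homo_v=True, ec_homo_ca=True, ec_homo_ip3=True,
            hetero_v=True, hetero_ca=True, hetero_ip3=True),
    4: dict(smc_homo_v=True, smc_homo_ca=True, smc_homo_ip3=True,
            ec_homo_v=False, ec_homo_ca=False, ec_homo_ip3=True,
            hetero_v=False, hetero_ca=False, hetero_ip3=True),
}


def coupling_case(case_id: int, **rate_overrides) -> CouplingConfig:
    """Coupling configuration for one of the four published cases."""
    try:
        flags = _CASES[case_id]
    except KeyError:
        raise ValueError(f"coupling case must be 1-4, got {case_id!r}") \
            from None
    return CouplingConfig(**flags, **rate_overrides)


def gap_flux(x_self, x_neighbors, rate: float):
    """Linear gap-junction flux ``rate * sum_k (x_k - x_self)``.

    Antisymmetric pairwise, so any closed collection of cells conserves the
    exchanged quantity.
    """
    if rate < 0:
        raise ValueError("coupling rate must be non-negative")
    x_neighbors = np.asarray(x_neighbors, dtype=float)
    return rate * np.sum(x_neighbors - x_self)


# ---------------------------------------------------------------------------
# adjacency


@dataclass
class CellAdjacency:
    """Cell-level neighbour structure of a tiled mesh.

    ``ec_pairs``/``smc_pairs`` list every undirected homocellular edge once
    (shape (E, 2) of global cell indices); ``het_pairs`` lists every EC-SMC
    pair (shape (P, 2), EC first).  ``het_w`` are the EC-side overlap
    weights (sum 1 over each EC's 13 partners) and ``het_w_smc`` the
    SMC-side weights (sum 1 over each SMC's 5 partners); the 13:5 weight
    ratio equals the EC:SMC footprint-area ratio, so equal-and-opposite
    molar fluxes through each junction yield these concentration rates.
    """

    n_ec: int
    n_smc: int
    ec_pairs: np.ndarray
    smc_pairs: np.ndarray
    het_pairs: np.ndarray
    het_w: np.ndarray
    het_w_smc: np.ndarray

    def neighbor_counts(self, layer: str) -> np.ndarray:
        pairs = self.ec_pairs if layer == "ec" else self.smc_pairs
        n = self.n_ec if layer == "ec" else self.n_smc
        return np.bincount(pairs.ravel(), minlength=n)

    def to_csv(self, path) -> None:
        """Edge list for inspection: kind, cell_a, cell_b, weight."""
        import pandas as pd

        frames = [
            pd.DataFrame({"kind": "ec_homo", "cell_a": self.ec_pairs[:, 0],
                          "cell_b": self.ec_pairs[:, 1], "weight": 1.0}),
            pd.DataFrame({"kind": "smc_homo", "cell_a": self.smc_pairs[:, 0],
                          "cell_b": self.smc_pairs[:, 1], "weight": 1.0}),
            pd.DataFrame({"kind": "hetero", "cell_a": self.het_pairs[:, 0],
                          "cell_b": self.het_pairs[:, 1],
                          "weight": self.het_w}),
        ]
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _grid_pairs(mesh: BifurcationMesh, layer: str) -> np.ndarray:
    """Homocellular 4-neighbour edges, periodic in v, junction-stitched."""
    pairs = []
    offs = mesh.layer_offsets(layer)
    shapes = [mesh.layer_shape(si, layer) for si in range(len(mesh.segments))]
    for si, (rows, cols) in enumerate(shapes):
        idx = offs[si] + np.arange(rows * cols).reshape(rows, cols)
        right = np.roll(idx, -1, axis=1)
        pairs.append(np.stack([idx.ravel(), right.ravel()], axis=1))
        pairs.append(np.stack([idx[:-1].ravel(), idx[1:].ravel()], axis=1))
    if mesh.is_bifurcation:
        (rows_p, cols), (rows_b, _), _ = shapes
        last_p = offs[0] + (rows_p - 1) * cols + np.arange(cols)
        first_b1 = offs[1] + np.arange(cols)
        first_b2 = offs[2] + np.arange(cols)
        half = cols // 2
        j = np.arange(half)
        pairs.append(np.stack([last_p[j], first_b1[j]], axis=1))
        j = np.arange(half, cols)
        pairs.append(np.stack([last_p[j], first_b2[cols - 1 - j]], axis=1))
        pairs.append(np.stack([first_b1[j], first_b2[j]], axis=1))
    return np.vstack(pairs)


def _hetero_pairs(mesh: BifurcationMesh) -> tuple[np.ndarray, np.ndarray]:
    """EC-SMC pairs of every fundamental unit with uniform overlap weights.

    In one unit the 5 EC footprints (65 x 10 um) and 13 SMC footprints
    (5 x 50 um) overlap pairwise in identical 5 x 10 um rectangles, so the
    area-proportional weights are uniform: 1/13 per pair for each EC.
    """
    ec_list, smc_list = [], []
    ec_offs = mesh.layer_offsets("ec")
    smc_offs = mesh.layer_offsets("smc")
    for si, seg in enumerate(mesh.segments):
        u_rows, u_cols = seg.m * 4, seg.n * 4     # fundamental units
        ur, uc = np.meshgrid(np.arange(u_rows), np.arange(u_cols),
                             indexing="ij")
        ur, uc = ur.ravel(), uc.ravel()
        ec_cols = seg.n * EC_CIRC
        smc_cols = seg.n * SMC_CIRC
        for ke in range(EC_PER_UNIT):
            ec_idx = ec_offs[si] + ur * ec_cols + uc * EC_PER_UNIT + ke
            for ks in range(SMC_PER_UNIT):
                smc_idx = (smc_offs[si] + (ur * SMC_PER_UNIT + ks) * smc_cols
                           + uc)
                ec_list.append(ec_idx)
                smc_list.append(smc_idx)
    het = np.stack([np.concatenate(ec_list), np.concatenate(smc_list)],
                   axis=1)
    w_ec = np.full(het.shape[0], 1.0 / SMC_PER_UNIT)
    w_smc = np.full(het.shape[0], 1.0 / EC_PER_UNIT)
    return het, w_ec, w_smc


def build_adjacency(mesh: BifurcationMesh) -> CellAdjacency:
    """Cell adjacency of a tiled mesh (homocellular + heterocellular)."""
    if not mesh.tiled:
        raise ValueError("mesh must be tiled (tile_cells) before adjacency")
    het, w_ec, w_smc = _hetero_pairs(mesh)
    return CellAdjacency(
        n_ec=mesh.n_ec, n_smc=mesh.n_smc,
        ec_pairs=_grid_pairs(mesh, "ec"),
        smc_pairs=_grid_pairs(mesh, "smc"),
        het_pairs=het, het_w=w_ec, het_w_smc=w_smc)


# ---------------------------------------------------------------------------
# assembled tissue RHS


@dataclass(frozen=True)
class StateLayout:
    """Flat state layout: EC variable blocks then SMC variable blocks.

    ``y = [ec_ca, ec_er, ec_v, ec_ip3, smc_ca, smc_sr, smc_v, smc_w,
    smc_ip3]`` with each block contiguous over cells, total length
    ``4 n_ec + 5 n_smc``.
    """

    n_ec: int
    n_smc: int

    @property
    def size(self) -> int:
        return 4 * self.n_ec + 5 * self.n_smc

    def ec_block(self, k: int) -> slice:
        return slice(k * self.n_ec, (k + 1) * self.n_ec)

    def smc_block(self, k: int) -> slice:
        off = 4 * self.n_ec
        return slice(off + k * self.n_smc, off + (k + 1) * self.n_smc)

    def split(self, y: np.ndarray):
        ec = [y[self.ec_block(k)] for k in range(4)]
        smc = [y[self.smc_block(k)] for k in range(5)]
        return ec, smc


def _exchange_operator(pairs: np.ndarray, n: int) -> sp.csr_matrix:
    """Sparse operator M with (M x)_i = sum_{j ~ i} (x_j - x_i)."""
    i = np.concatenate([pairs[:, 0], pairs[:, 1]])
    j = np.concatenate([pairs[:, 1], pairs[:, 0]])
    data = np.ones(i.size)
    adj = sp.csr_matrix((data, (i, j)), shape=(n, n))
    deg = np.asarray(adj.sum(axis=1)).ravel()
    return (adj - sp.diags(deg)).tocsr()


class TissueModel:
    """Vectorised RHS of a whole coupled tissue.

    Wraps a tiled mesh, a :class:`CouplingConfig`, an agonist map (per-EC
    ``j_plc``, uM/s) and a :class:`~cawave.cell_models.ModelParameters` set
    into a callable ``rhs(t, y)`` suitable for scipy integrators, plus the
    Jacobian sparsity pattern for implicit methods.
    """

    def __init__(self, mesh: BifurcationMesh, config: CouplingConfig,
                 agonist, params: cm.ModelParameters | None = None,
                 adjacency: CellAdjacency | None = None):
        self.mesh = mesh
        self.config = config
        self.params = params or cm.ModelParameters()
        self.adjacency = adjacency or build_adjacency(mesh)
        j = np.asarray(getattr(agonist, "values", agonist), dtype=float)
        if j.shape != (mesh.n_ec,):
            raise ValueError(
                f"agonist map length {j.shape} does not match nEC={mesh.n_ec}")
        self.j_plc = j
        self.layout = StateLayout(mesh.n_ec, mesh.n_smc)

        adj = self.adjacency
        self._M_ec = _exchange_operator(adj.ec_pairs, adj.n_ec)
        self._M_smc = _exchange_operator(adj.smc_pairs, adj.n_smc)
        # heterocellular weight matrices, normalised per receiving cell:
        # each EC averages its 13 SMC partners, each SMC its 5 EC partners.
        # Per-junction molar flux is then conserved because the EC/SMC cell
        # area (hence lumped volume) ratio is 650/250 = 13/5 exactly.
        self._W = sp.csr_matrix(
            (adj.het_w, (adj.het_pairs[:, 0], adj.het_pairs[:, 1])),
            shape=(adj.n_ec, adj.n_smc))
        self._U = sp.csr_matrix(
            (adj.het_w_smc, (adj.het_pairs[:, 1], adj.het_pairs[:, 0])),
            shape=(adj.n_smc, adj.n_ec))

    # -- flux assembly -----------------------------------------------------

    def _homo(self, M, x, enabled: bool, rate: float):
        return rate * (M @ x) if (enabled and rate > 0.0) else 0.0

    def _hetero(self, x_ec, x_smc, enabled: bool, rate: float):
        if not (enabled and rate > 0.0):
            return 0.0, 0.0
        into_ec = rate * (self._W @ x_smc - x_ec)
        into_smc = rate * (self._U @ x_ec - x_smc)
        return into_ec, into_smc

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        c = self.config
        (e_ca, e_er, e_v, e_ip3), (s_ca, s_sr, s_v, s_w, s_ip3) = \
            self.layout.split(y)

        h_ca_e, h_ca_s = self._hetero(e_ca, s_ca, c.hetero_ca, c.g_ca_hetero)
        h_ip_e, h_ip_s = self._hetero(e_ip3, s_ip3, c.hetero_ip3,
                                      c.g_ip3_hetero)
        h_v_e, h_v_s = self._hetero(e_v, s_v, c.hetero_v, c.g_v_hetero)

        j_ca_e = self._homo(self._M_ec, e_ca, c.ec_homo_ca, c.g_chem_homo)
        j_ip_e = self._homo(self._M_ec, e_ip3, c.ec_homo_ip3, c.g_chem_homo)
        j_v_e = self._homo(self._M_ec, e_v, c.ec_homo_v, c.g_v_homo)
        j_ca_s = self._homo(self._M_smc, s_ca, c.smc_homo_ca, c.g_chem_homo)
        j_ip_s = self._homo(self._M_smc, s_ip3, c.smc_homo_ip3,
                            c.g_chem_homo)
        j_v_s = self._homo(self._M_smc, s_v, c.smc_homo_v, c.g_v_homo)

        d_ec = cm.ec_derivatives(e_ca, e_er, e_v, e_ip3, self.params,
                                 j_plc=self.j_plc,
                                 j_ca=j_ca_e + h_ca_e,
                                 j_ip3=j_ip_e + h_ip_e,
                                 j_v=j_v_e + h_v_e)
        d_smc = cm.smc_derivatives(s_ca, s_sr, s_v, s_w, s_ip3, self.params,
                                   j_ca=j_ca_s + h_ca_s,
                                   j_ip3=j_ip_s + h_ip_s,
                                   j_v=j_v_s + h_v_s)
        return np.concatenate(list(d_ec) + list(d_smc))

    __call__ = rhs

    # -- initial state -----------------------------------------------------

    def initial_state(self, seed: int | None = None,
                      ca_noise: float = 0.0) -> np.ndarray:
        """Uniform rest state (isolated cells at j_plc = 0), optionally with
        small seeded Ca2+ perturbations to break mesh symmetry."""
        ec0, smc0 = cm.rest_state(self.params)
        lay = self.layout
        y = np.empty(lay.size)
        for k, val in enumerate(ec0.to_array()):
            y[lay.ec_block(k)] = val
        for k, val in enumerate(smc0.to_array()):
            y[lay.smc_block(k)] = val
        if ca_noise > 0.0:
            rng = np.random.default_rng(seed)
            y[lay.ec_block(0)] *= 1.0 + ca_noise * rng.standard_normal(lay.n_ec)
            y[lay.smc_block(0)] *= 1.0 + ca_noise * rng.standard_normal(lay.n_smc)
        return y

    # -- Jacobian sparsity for implicit integrators ------------------------

    def jac_sparsity(self) -> sp.csr_matrix:
        lay = self.layout
        rows, cols = [], []

        def block(ri, ci, i_idx, j_idx):
            rows.append(ri.start + np.asarray(i_idx))
            cols.append(ci.start + np.asarray(j_idx))

        e_all = np.arange(lay.n_ec)
        s_all = np.arange(lay.n_smc)
        # dense intra-cell blocks
        for ki in range(4):
            for kj in range(4):
                block(lay.ec_block(ki), lay.ec_block(kj), e_all, e_all)
        for ki in range(5):
            for kj in range(5):
                block(lay.smc_block(ki), lay.smc_block(kj), s_all, s_all)

        c = self.config
        homo = [(lay.ec_block, self.adjacency.ec_pairs,
                 [(0, c.ec_homo_ca), (2, c.ec_homo_v), (3, c.ec_homo_ip3)]),
                (lay.smc_block, self.adjacency.smc_pairs,
                 [(0, c.smc_homo_ca), (2, c.smc_homo_v),
                  (4, c.smc_homo_ip3)])]
        for blk, pairs, specs in homo:
            for k, on in specs:
                if not on:
                    continue
                i, j = pairs[:, 0], pairs[:, 1]
                block(blk(k), blk(k), i, j)
                block(blk(k), blk(k), j, i)
        het = self.adjacency.het_pairs
        for on, ke, ks in ((c.hetero_ca, 0, 0), (c.hetero_v, 2, 2),
                           (c.hetero_ip3, 3, 4)):
            if not on:
                continue
            block(lay.ec_block(ke), lay.smc_block(ks), het[:, 0], het[:, 1])
            block(lay.smc_block(ks), lay.ec_block(ke), het[:, 1], het[:, 0])
        r = np.concatenate(rows)
        s = np.concatenate(cols)
        return sp.csr_matrix((np.ones(r.size, dtype=np.int8), (r, s)),
                             shape=(lay.size, lay.size))


def tissue_rhs(state: np.ndarray, adjacency: CellAdjacency,
               config: CouplingConfig, agonist, params=None,
               mesh: BifurcationMesh | None = None) -> np.ndarray:
    """Functional form of the tissue RHS (see :class:`TissueModel`).

    ``state`` must have length ``4 nEC + 5 nSMC`` in the
    :class:`StateLayout` ordering.
    """
    if mesh is None:
        raise ValueError("tissue_rhs requires the mesh for layout metadata")
    model = TissueModel(mesh, config, agonist, params, adjacency=adjacency)
    state = np.asarray(state, dtype=float)
    if state.size != model.layout.size:
        raise ValueError(
            f"state length {state.size} != 4*nEC + 5*nSMC = "
            f"{model.layout.size}")
    return model.rhs(0.0, state)
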