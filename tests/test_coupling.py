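"""Coupling cases, gap fluxes, adjacency and the assembled tissue RHS."""

import numpy as np
import pytest

from cawave import cell_models as cm
from cawave.coupling import (CouplingConfig, TissueModel, build_adjacency,
                             coupling_case, gap_flux, tissue_rhs)


# ---------------------------------------------------------------------------
# coupling cases (healthy vs pathological connexin patterns)


def test_case1_has_no_heterocellular_ca():
    cfg = coupling_case(1)
    assert cfg.hetero_v and cfg.hetero_ip3 and not cfg.hetero_ca
    assert cfg.ec_homo_v and cfg.ec_homo_ca and not cfg.ec_homo_ip3


def test_case4_removes_ec_and_heterocellular_electrical_coupling():
    cfg = coupling_case(4)
    assert not cfg.ec_homo_v and not cfg.ec_homo_ca and cfg.ec_homo_ip3
    assert not cfg.hetero_v and not cfg.hetero_ca and cfg.hetero_ip3
    assert cfg.smc_homo_v and cfg.smc_homo_ca and cfg.smc_homo_ip3


def test_cases_2_and_3_differ_only_in_ec_homocellular_ip3():
    c2, c3 = coupling_case(2), coupling_case(3)
    d2, d3 = c2.__dict__, c3.__dict__
    diff = {k for k in d2 if d2[k] != d3[k]}
    assert diff == {"ec_homo_ip3"}


@pytest.mark.parametrize("bad", [0, 5, -1, "one"])
def test_invalid_case_rejected(bad):
    with pytest.raises(ValueError):
        coupling_case(bad)


def test_negative_rate_rejected():
    with pytest.raises(ValueError):
        CouplingConfig(g_v_homo=-1.0)


# ---------------------------------------------------------------------------
# gap flux primitive


def test_gap_flux_examples():
    assert gap_flux(2.0, [2.0, 2.0, 2.0], 5.0) == 0.0
    a, b, rate = 1.0, 3.0, 0.7
    assert gap_flux(a, [b], rate) == pytest.approx(rate * (b - a))
    assert gap_flux(a, [b], rate) == -gap_flux(b, [a], rate)
    # 4 neighbours symmetric about self: exact cancellation
    assert gap_flux(2.5, [1.0, 2.0, 3.0, 4.0], 0.05) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        gap_flux(0.0, [1.0], -0.1)


# ---------------------------------------------------------------------------
# adjacency invariants


def test_homocellular_adjacency_structure(mini_tube, mini_adjacency):
    adj = mini_adjacency
    for layer in ("ec", "smc"):
        counts = adj.neighbor_counts(layer)
        rows, cols = mini_tube.layer_shape(0, layer)
        grid = counts.reshape(rows, cols)
        # interior rows: exactly 4 neighbours; open tube ends: 3
        assert np.all(grid[1:-1] == 4)
        assert np.all(grid[[0, -1]] == 3)


def test_circumferential_periodicity(mini_tube, mini_adjacency):
    """First and last columns of a ring are gap-junction neighbours."""
    rows, cols = mini_tube.layer_shape(0, "smc")
    a = mini_tube.cell_index("smc", 0, 5, 0)
    b = mini_tube.cell_index("smc", 0, 5, cols - 1)
    pairs = {frozenset(p) for p in mini_adjacency.smc_pairs.tolist()}
    assert frozenset((int(a), int(b))) in pairs


def test_heterocellular_pairs_per_unit(mini_tube, mini_adjacency):
    adj = mini_adjacency
    # 65 pairs per fundamental unit, uniform overlap weights
    n_units = mini_tube.n_quads * 16
    assert adj.het_pairs.shape == (65 * n_units, 2)
    assert np.allclose(adj.het_w, 1.0 / 13.0)
    per_ec = np.zeros(adj.n_ec)
    np.add.at(per_ec, adj.het_pairs[:, 0], adj.het_w)
    assert np.allclose(per_ec, 1.0, atol=1e-12)
    per_ec_count = np.bincount(adj.het_pairs[:, 0], minlength=adj.n_ec)
    assert np.all(per_ec_count == 13)
    per_smc_count = np.bincount(adj.het_pairs[:, 1], minlength=adj.n_smc)
    assert np.all(per_smc_count == 5)


def test_adjacency_requires_tiling():
    from cawave.geometry import GeometrySpec, build_tube
    mesh = build_tube(GeometrySpec(branch_length=0.52, diameter=0.26,
                                   quads_axial=2, quads_circ=4))
    with pytest.raises(ValueError, match="tiled"):
        build_adjacency(mesh)


# ---------------------------------------------------------------------------
# assembled RHS


def _naive_rhs(mesh, adj, cfg, jplc, params, y, layout):
    """Cell-by-cell loop oracle for the vectorised tissue RHS."""
    ec_vars, smc_vars = layout.split(y)
    ec = np.stack(ec_vars, 1)
    smc = np.stack(smc_vars, 1)
    ecnb = [[] for _ in range(adj.n_ec)]
    smcnb = [[] for _ in range(adj.n_smc)]
    for a, b in adj.ec_pairs:
        ecnb[a].append(b)
        ecnb[b].append(a)
    for a, b in adj.smc_pairs:
        smcnb[a].append(b)
        smcnb[b].append(a)
    het_ec = [[] for _ in range(adj.n_ec)]
    het_smc = [[] for _ in range(adj.n_smc)]
    for (e, s), w_e, w_s in zip(adj.het_pairs, adj.het_w, adj.het_w_smc):
        het_ec[e].append((s, w_e))
        het_smc[s].append((e, w_s))
    out_ec = np.zeros_like(ec)
    out_smc = np.zeros_like(smc)
    for i in range(adj.n_ec):
        jca = (cfg.g_chem_homo * sum(ec[j, 0] - ec[i, 0] for j in ecnb[i])
               if cfg.ec_homo_ca else 0.0)
        jv = (cfg.g_v_homo * sum(ec[j, 2] - ec[i, 2] for j in ecnb[i])
              if cfg.ec_homo_v else 0.0)
        jip = (cfg.g_chem_homo * sum(ec[j, 3] - ec[i, 3] for j in ecnb[i])
               if cfg.ec_homo_ip3 else 0.0)
        if cfg.hetero_ca:
            jca += cfg.g_ca_hetero * sum(w * (smc[s, 0] - ec[i, 0])
                                         for s, w in het_ec[i])
        if cfg.hetero_v:
            jv += cfg.g_v_hetero * sum(w * (smc[s, 2] - ec[i, 2])
                                       for s, w in het_ec[i])
        if cfg.hetero_ip3:
            jip += cfg.g_ip3_hetero * sum(w * (smc[s, 4] - ec[i, 3])
                                          for s, w in het_ec[i])
        out_ec[i] = cm.ec_derivatives(*ec[i], params, j_plc=jplc[i],
                                      j_ca=jca, j_ip3=jip, j_v=jv)
    for i in range(adj.n_smc):
        jca = (cfg.g_chem_homo * sum(smc[j, 0] - smc[i, 0] for j in smcnb[i])
               if cfg.smc_homo_ca else 0.0)
        jv = (cfg.g_v_homo * sum(smc[j, 2] - smc[i, 2] for j in smcnb[i])
              if cfg.smc_homo_v else 0.0)
        jip = (cfg.g_chem_homo * sum(smc[j, 4] - smc[i, 4] for j in smcnb[i])
               if cfg.smc_homo_ip3 else 0.0)
        if cfg.hetero_ca:
            jca += cfg.g_ca_hetero * sum(w * (ec[e, 0] - smc[i, 0])
                                         for e, w in het_smc[i])
        if cfg.hetero_v:
            jv += cfg.g_v_hetero * sum(w * (ec[e, 2] - smc[i, 2])
                                       for e, w in het_smc[i])
        if cfg.hetero_ip3:
            jip += cfg.g_ip3_hetero * sum(w * (ec[e, 3] - smc[i, 4])
                                          for e, w in het_smc[i])
        out_smc[i] = cm.smc_derivatives(*smc[i], params,
                                        j_ca=jca, j_ip3=jip, j_v=jv)
    return np.concatenate([out_ec.T.ravel(), out_smc.T.ravel()])


def test_vectorised_rhs_matches_naive_loop(mini_tube, mini_adjacency,
                                           mini_agonist, params):
    model = TissueModel(mini_tube, coupling_case(2), mini_agonist, params,
                        adjacency=mini_adjacency)
    rng = np.random.default_rng(7)
    y = model.initial_state() * (1 + 0.1 * rng.standard_normal(
        model.layout.size))
    got = model.rhs(0.0, y)
    want = _naive_rhs(mini_tube, mini_adjacency, coupling_case(2),
                      mini_agonist.values, params, y, model.layout)
    scale = np.maximum(np.abs(want), 1.0)
    assert np.max(np.abs(got - want) / scale) < 1e-12


def test_state_length_mismatch_rejected(mini_tube, mini_adjacency,
                                        mini_agonist):
    with pytest.raises(ValueError, match="length"):
        tissue_rhs(np.zeros(10), mini_adjacency, coupling_case(1),
                   mini_agonist, mesh=mini_tube)


def test_agonist_length_mismatch_rejected(mini_tube):
    with pytest.raises(ValueError, match="nEC"):
        TissueModel(mini_tube, coupling_case(1),
                    np.zeros(mini_tube.n_ec - 1))


def test_decoupled_rhs_is_per_cell(mini_tube, params):
    """All coupling off + uniform agonist: every EC has the same RHS."""
    cfg = CouplingConfig(smc_homo_v=False, smc_homo_ca=False,
                         smc_homo_ip3=False, ec_homo_v=False,
                         ec_homo_ca=False, ec_homo_ip3=False,
                         hetero_v=False, hetero_ca=False, hetero_ip3=False)
    model = TissueModel(mini_tube, cfg, np.full(mini_tube.n_ec, 2.0), params)
    y = model.initial_state()
    dy = model.rhs(0.0, y)
    lay = model.layout
    for k in range(4):
        blk = dy[lay.ec_block(k)]
        assert np.allclose(blk, blk[0], rtol=0, atol=1e-12)


def test_homocellular_fluxes_conserve_over_closed_surface(
        mini_tube, mini_adjacency, mini_agonist, params):
    """Per species, homocellular fluxes sum to zero over the closed tissue."""
    cfg = coupling_case(2).with_rates(g_v_hetero=0.0, g_ca_hetero=0.0,
                                      g_ip3_hetero=0.0)
    off = cfg.with_rates(g_v_homo=0.0, g_chem_homo=0.0)
    m_on = TissueModel(mini_tube, cfg, mini_agonist, params,
                       adjacency=mini_adjacency)
    m_off = TissueModel(mini_tube, off, mini_agonist, params,
                        adjacency=mini_adjacency)
    rng = np.random.default_rng(3)
    y = m_on.initial_state() * (1 + 0.2 * rng.standard_normal(
        m_on.layout.size))
    delta = m_on.rhs(0.0, y) - m_off.rhs(0.0, y)
    lay = m_on.layout
    n = mini_tube.n_cells
    for blocks, scale in ((
            (lay.ec_block(0), lay.smc_block(0)), 1.0),
            ((lay.ec_block(3), lay.smc_block(4)), 1.0),
            ((lay.ec_block(2), lay.smc_block(2)), 1e5)):
        total = sum(float(np.sum(delta[b])) for b in blocks)
        assert abs(total) < 1e-9 * n * scale


def test_heterocellular_fluxes_conserve_molar_content(
        mini_tube, mini_adjacency, mini_agonist, params):
    """Hetero exchange conserves moles: EC and SMC sides balance 13:5.

    Concentration rates weighted by the lumped cell volumes (areas
    650 vs 250 um^2) must cancel for every coupled species.
    """
    cfg = coupling_case(2).with_rates(g_v_homo=0.0, g_chem_homo=0.0)
    off = cfg.with_rates(g_v_hetero=0.0, g_ca_hetero=0.0, g_ip3_hetero=0.0)
    m_on = TissueModel(mini_tube, cfg, mini_agonist, params,
                       adjacency=mini_adjacency)
    m_off = TissueModel(mini_tube, off, mini_agonist, params,
                        adjacency=mini_adjacency)
    rng = np.random.default_rng(5)
    y = m_on.initial_state() * (1 + 0.2 * rng.standard_normal(
        m_on.layout.size))
    delta = m_on.rhs(0.0, y) - m_off.rhs(0.0, y)
    lay = m_on.layout
    v_ec, v_smc = 13.0, 5.0
    for eb, sb in ((lay.ec_block(0), lay.smc_block(0)),
                   (lay.ec_block(3), lay.smc_block(4))):
        total = v_ec * float(np.sum(delta[eb])) \
            + v_smc * float(np.sum(delta[sb]))
        assert abs(total) < 1e-9 * mini_tube.n_cells


def test_rotational_equivariance_of_rhs(mini_tube, params):
    """Rotating the state by one fundamental unit rotates the RHS likewise.

    One unit spans 5 EC columns and 1 SMC column (both 50 um of
    circumference), the smallest rotation mapping the tissue onto itself.
    """
    model = TissueModel(mini_tube, coupling_case(2),
                        np.full(mini_tube.n_ec, 3.0), params)
    lay = model.layout
    rng = np.random.default_rng(11)
    y = model.initial_state() * (1 + 0.1 * rng.standard_normal(lay.size))

    def rotate(y):
        out = np.empty_like(y)
        for layer, shift, blocks in (
                ("ec", 5, [lay.ec_block(k) for k in range(4)]),
                ("smc", 1, [lay.smc_block(k) for k in range(5)])):
            rows, cols = mini_tube.layer_shape(0, layer)
            for b in blocks:
                out[b] = np.roll(y[b].reshape(rows, cols), shift,
                                 axis=1).ravel()
        return out

    lhs = model.rhs(0.0, rotate(y))
    rhs = rotate(model.rhs(0.0, y))
    assert np.max(np.abs(lhs - rhs)) < 1e-9


def test_adjacency_edge_list_export(tmp_path, mini_adjacency):
    import pandas as pd
    path = tmp_path / "edges.csv"
    mini_adjacency.to_csv(path)
    df = pd.read_csv(path)
    assert set(df["kind"]) == {"ec_homo", "smc_homo", "hetero"}
    assert (df["kind"] == "hetero").sum() == len(mini_adjacency.het_pairs)
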