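"""Post-processing: bifurcation diagrams, space-time maps and wave metrics.

The bifurcation diagram characterises the agonist-dependent dynamics of one
heterocellularly coupled EC/SMC unit: for each ``j_plc`` the unit is
integrated past its transient and the envelope (max/min) of the SMC
cytosolic Ca2+ is recorded.  Between a lower and an upper Hopf-type
threshold the Ca2+ is oscillatory; outside, it is steady.  Thresholds are
located empirically by bisection on the oscillation classifier.

Space-time (kymograph) extraction samples the SMC Ca2+ along an axial line
on the vessel wall over all snapshots; wave metrics (amplitude, period,
front position, propagation direction) are then computed per position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from . import cell_models as cm
from .coupling import CouplingConfig, coupling_case
from .engine import StateArchive
from .geometry import BifurcationMesh

__all__ = ["BifurcationDiagram", "bifurcation_sweep", "classify_unit",
           "SpaceTimeMap", "extract_line", "wave_metrics"]

#: oscillation tolerance: peak-to-peak > 1% of the window mean
OSC_REL_TOL = 0.01


@dataclass
class BifurcationDiagram:
    """SMC Ca2+ envelope vs the EC agonist flux for one coupling case."""

    j_plc: np.ndarray
    ca_max: np.ndarray
    ca_min: np.ndarray
    lower_threshold: float | None
    upper_threshold: float | None
    case_id: int | None = None

    @property
    def oscillatory(self) -> np.ndarray:
        mean = 0.5 * (self.ca_max + self.ca_min)
        return (self.ca_max - self.ca_min) > OSC_REL_TOL * mean


def _unit_rhs_flat(t, y, params, cfg: CouplingConfig, j_plc: float):
    ec = cm.EcState.from_array(y[:4])
    smc = cm.SmcState.from_array(y[4:])
    return cm.unit_rhs(ec, smc, params, cfg, j_plc=j_plc)


def classify_unit(j_plc: float, cfg: CouplingConfig,
                  params: cm.ModelParameters, y0: np.ndarray,
                  settle: float = 200.0, measure: float = 300.0,
                  rtol: float = 1e-8) -> tuple[bool, float, float]:
    """Integrate one coupled unit and classify its long-run behaviour.

    Returns ``(oscillatory, ca_max, ca_min)`` where the envelope is taken
    over the measurement window after the settle window.  A slowly decaying
    transient is not counted as oscillation: the peak-to-peak amplitude of
    the second half of the window must exceed both the relative tolerance
    and half the first-half amplitude.
    """
    t_eval = np.linspace(settle, settle + measure, 1500)
    sol = solve_ivp(_unit_rhs_flat, (0.0, settle + measure), y0,
                    args=(params, cfg, j_plc), method="LSODA",
                    rtol=rtol, atol=rtol * 1e-2, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(
            f"unit integration failed at j_plc={j_plc}: {sol.message}")
    ca = sol.y[4]
    half = ca.size // 2
    a1 = float(np.ptp(ca[:half]))
    a2 = float(np.ptp(ca[half:]))
    osc = (a2 > OSC_REL_TOL * max(float(np.mean(ca)), 1e-12)
           and a2 > 0.5 * a1)
    return osc, float(ca.max()), float(ca.min())


def bifurcation_sweep(case_id: int | CouplingConfig,
                      j_plc_range: tuple[float, float] = (0.0, 8.0),
                      params: cm.ModelParameters | None = None,
                      coarse_step: float = 0.5,
                      resolution: float = 0.01,
                      settle: float = 200.0, measure: float = 300.0
                      ) -> BifurcationDiagram:
    """Single-unit bifurcation diagram with threshold bisection.

    The unit carries only the heterocellular coupling of the chosen case
    (homocellular coupling is meaningless for one EC/SMC pair).  The sweep
    scans ``j_plc_range`` at ``coarse_step``, then bisects each
    oscillatory/steady boundary down to ``resolution``.
    """
    params = params or cm.ModelParameters()
    cfg = coupling_case(case_id) if isinstance(case_id, int) else case_id
    ec0, smc0 = cm.rest_state(params)
    y0 = np.concatenate([ec0.to_array(), smc0.to_array()])

    lo, hi = j_plc_range
    grid = np.round(np.arange(lo, hi + 0.5 * coarse_step, coarse_step), 9)
    flags, cmaxs, cmins = [], [], []
    for j in grid:
        osc, cma, cmi = classify_unit(j, cfg, params, y0, settle, measure)
        flags.append(osc)
        cmaxs.append(cma)
        cmins.append(cmi)
    flags = np.array(flags)

    def bisect(j_steady: float, j_osc: float) -> float:
        while abs(j_osc - j_steady) > resolution:
            mid = 0.5 * (j_steady + j_osc)
            osc, _, _ = classify_unit(mid, cfg, params, y0, settle, measure)
            if osc:
                j_osc = mid
            else:
                j_steady = mid
        return 0.5 * (j_steady + j_osc)

    lower = upper = None
    osc_idx = np.flatnonzero(flags)
    if osc_idx.size:
        first, last = osc_idx[0], osc_idx[-1]
        if first > 0:
            lower = bisect(grid[first - 1], grid[first])
        if last < grid.size - 1:
            upper = bisect(grid[last + 1], grid[last])
    return BifurcationDiagram(
        j_plc=grid, ca_max=np.array(cmaxs), ca_min=np.array(cmins),
        lower_threshold=lower, upper_threshold=upper,
        case_id=case_id if isinstance(case_id, int) else None)


# ---------------------------------------------------------------------------
# space-time extraction


@dataclass
class SpaceTimeMap:
    """SMC Ca2+ along an axial line: values[p, t] at positions/times."""

    positions: np.ndarray      # (P,) axial coordinates, mm, ascending
    times: np.ndarray          # (T,) s
    values: np.ndarray         # (P, T) uM
    smc_indices: np.ndarray | None = None
    agonist_at: np.ndarray | None = None   # per-position J_PLC, if known

    def __post_init__(self) -> None:
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be ordered along the line")
        if self.values.shape != (self.positions.size, self.times.size):
            raise ValueError("values shape inconsistent with axes")


def extract_line(archive: StateArchive, mesh: BifurcationMesh,
                 circ_index: int | None = None,
                 segments: tuple[int, ...] | None = None) -> SpaceTimeMap:
    """SMC Ca2+ along an outer-wall axial line from inlet to outlet.

    One SMC per axial ring is taken at a fixed circumferential column
    (default: the outer bend, a quarter turn from the top pole).  On a
    bifurcation the line runs through the parent and continues into the
    first daughter branch.
    """
    if not mesh.tiled:
        raise ValueError("mesh must be tiled")
    if archive.layout.n_smc != mesh.n_smc:
        raise ValueError("archive does not belong to this mesh")
    if segments is None:
        segments = (0, 1) if mesh.is_bifurcation else (0,)
    ca = archive.smc_var("ca")                       # (T, nSMC)
    pos_list, idx_list = [], []
    for si in segments:
        rows, cols = mesh.layer_shape(si, "smc")
        jv = cols // 8 if circ_index is None else circ_index
        if not (0 <= jv < cols):
            raise ValueError(f"circumferential index {jv} outside 0..{cols-1}")
        iu = np.arange(rows)
        idx = mesh.cell_index("smc", si, iu, jv)
        pos_list.append(mesh.smc.axial[idx])
        idx_list.append(idx)
    pos = np.concatenate(pos_list)
    idx = np.concatenate(idx_list)
    order = np.argsort(pos, kind="stable")
    if idx.size == 0:
        raise ValueError("extraction line intersects no cells")
    return SpaceTimeMap(positions=pos[order], times=archive.times.copy(),
                        values=ca[:, idx[order]].T.copy(),
                        smc_indices=idx[order])


# ---------------------------------------------------------------------------
# wave metrics


def wave_metrics(stmap: SpaceTimeMap,
                 lower_threshold_position: float | None = None,
                 rel_tol: float = OSC_REL_TOL,
                 front_window: float | None = None) -> dict:
    """Amplitude, period, front trajectory and propagation direction.

    Per position: amplitude = peak-to-peak over the whole record, period =
    mean peak spacing.  The wave front at time t is the most upstream
    (smallest axial coordinate) position whose amplitude inside a sliding
    window around t exceeds the tolerance; the direction is the sign of the
    front displacement (``"upstream"`` towards decreasing axial coordinate,
    i.e. decreasing agonist for the canonical maps).  Returns a dict with
    ``present=False`` when nothing oscillates.
    """
    v = stmap.values
    t = stmap.times
    mean = v.mean(axis=1)
    amplitude = v.max(axis=1) - v.min(axis=1)
    osc_mask = amplitude > rel_tol * np.maximum(mean, 1e-12)
    if not np.any(osc_mask):
        return {"present": False, "amplitude": amplitude,
                "period": np.full(v.shape[0], np.nan)}

    period = np.full(v.shape[0], np.nan)
    for p in np.flatnonzero(osc_mask):
        prom = 0.25 * amplitude[p]
        peaks, _ = find_peaks(v[p], prominence=prom)
        if peaks.size >= 2:
            period[p] = float(np.mean(np.diff(t[peaks])))

    if front_window is None:
        valid = period[np.isfinite(period)]
        front_window = 2.0 * float(np.median(valid)) if valid.size else \
            0.2 * (t[-1] - t[0])
    half_w = max(front_window / 2.0, (t[1] - t[0]) if t.size > 1 else 1.0)

    front_t, front_x = [], []
    for ti, tc in enumerate(t):
        sel = (t >= tc - half_w) & (t <= tc + half_w)
        if sel.sum() < 3:
            continue
        local_amp = v[:, sel].max(axis=1) - v[:, sel].min(axis=1)
        act = np.flatnonzero(local_amp > rel_tol * np.maximum(mean, 1e-12))
        if act.size:
            front_t.append(tc)
            front_x.append(stmap.positions[act[0]])
    front_t = np.array(front_t)
    front_x = np.array(front_x)

    direction = None
    crossed = None
    if front_x.size >= 2:
        slope = np.polyfit(front_t, front_x, 1)[0]
        direction = "upstream" if slope < 0 else "downstream"
    if lower_threshold_position is not None and front_x.size:
        crossed = bool(np.min(front_x) < lower_threshold_position)
    return {"present": True, "amplitude": amplitude, "period": period,
            "front_times": front_t, "front_positions": front_x,
            "direction": direction,
            "phase_direction": phase_direction(stmap, rel_tol=rel_tol),
            "crossed_lower_threshold": crossed}


def phase_direction(stmap: SpaceTimeMap, rel_tol: float = OSC_REL_TOL,
                    min_separation: float = 0.05) -> str | None:
    """Direction of crest propagation inside the oscillatory band.

    Estimated from the lag of the peak cross-correlation between pairs of
    oscillatory positions at least ``min_separation`` (mm) apart, using the
    second half of the record (past the start-up transient).  A negative
    median lag per unit distance means crests arrive later at smaller axial
    coordinates, i.e. waves travel ``"upstream"`` toward decreasing agonist.
    """
    v = stmap.values
    t = stmap.times
    half = v.shape[1] // 2
    w = v[:, half:]
    mean = w.mean(axis=1)
    amp = w.max(axis=1) - w.min(axis=1)
    band = np.flatnonzero(amp > rel_tol * np.maximum(mean, 1e-12))
    if band.size < 3:
        return None
    dt = t[1] - t[0] if t.size > 1 else 1.0
    lags = []
    prev = band[0]
    for idx in band[1:]:
        if stmap.positions[idx] - stmap.positions[prev] < min_separation:
            continue
        a = w[prev] - w[prev].mean()
        b = w[idx] - w[idx].mean()
        cc = np.correlate(b, a, mode="full")
        lag = (np.argmax(cc) - (a.size - 1)) * dt
        lags.append(lag / (stmap.positions[idx] - stmap.positions[prev]))
        prev = idx
    if not lags:
        return None
    med = float(np.median(lags))
    if med == 0.0:
        return None
    # downstream cells lead (negative lag upstream-to-downstream) when the
    # wave source is downstream and crests move upstream
    return "upstream" if med < 0 else "downstream"
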