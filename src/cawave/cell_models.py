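"""Single-cell pathway models for arterial smooth muscle and endothelial cells.

The smooth muscle cell (SMC) is described by five state variables: cytosolic
Ca2+ ``ca_i`` (uM), sarcoplasmic-reticulum store Ca2+ ``ca_sr`` (uM), membrane
potential ``v_m`` (mV), the open fraction ``w_k`` of Ca2+-activated K+
channels, and cytosolic IP3 ``ip3`` (uM).  The endothelial cell (EC) carries
four: cytosolic Ca2+ ``ca_j``, endoplasmic-reticulum store Ca2+ ``ca_er``,
membrane potential ``v_m`` and ``ip3``.  The oscillation engine is
IP3-sensitised, calcium-induced calcium release (CICR) from the internal
store, fed in the SMC by voltage-operated Ca2+ channels (VOCC) and drained by
extrusion pumps; the agonist input is ``j_plc``, the IP3 production flux at
the EC membrane (uM/s) driven by ATP binding to P2Y receptors.

Units are uM, mV and s throughout.  All right-hand sides are pure functions
and accept scalars or numpy arrays for every state component, so the same
code evaluates one cell or a whole tissue layer.
"""

from __future__ import annotations


from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

__all__ = [
    "ConfigurationError",
    "ModelParameters",
    "SmcState",
    "EcState",
    "CouplingInflux",
    "smc_rhs",
    "ec_rhs",
    "unit_rhs",
    "smc_derivatives",
    "ec_derivatives",
    "rest_state",
]

SMC_VARS = ("ca_i", "ca_sr", "v_m", "w_k", "ip3")
EC_VARS = ("ca_j", "ca_er", "v_m", "ip3")

#: floor used inside log10() terms to keep the RHS finite for ca -> 0+
_LOG_FLOOR = 1e-12


class ConfigurationError(KeyError):
    """Raised when a required model parameter is missing or malformed."""


def _read_defaults() -> dict[str, float]:
    text = (
        resources.files("cawave.params")
        .joinpath("default_parameters.txt")
        .read_text()
    )
    values: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        values[parts[0]] = float(parts[1])
    return values


class ModelParameters:
    """Symbol-keyed parameter set for the coupled EC/SMC model.

    Defaults are loaded from the versioned flat file
    ``cawave/params/default_parameters.txt``; individual symbols can be
    overridden through the constructor or :meth:`replace`.  Access by
    attribute (``params.G_Ca``) or :meth:`get`; a missing symbol raises
    :class:`ConfigurationError` naming it.
    """

    def __init__(self, overrides: Mapping[str, float] | None = None, **kw: float):
        self._values = _read_defaults()
        merged = dict(overrides or {})
        merged.update(kw)
        for key, val in merged.items():
            if key not in self._values:
                raise ConfigurationError(f"unknown model parameter {key!r}")
            self._values[key] = float(val)

    def get(self, symbol: str) -> float:
        try:
            return self._values[symbol]
        except KeyError:
            raise ConfigurationError(
                f"missing model parameter {symbol!r}"
            ) from None

    def __getattr__(self, symbol: str) -> float:
        if symbol.startswith("_"):
            raise AttributeError(symbol)
        return self.get(symbol)

    def replace(self, **kw: float) -> "ModelParameters":
        merged = dict(self._values)
        merged.update(kw)
        out = ModelParameters()
        out._values = {k: float(v) for k, v in merged.items()}
        return out

    def as_dict(self) -> dict[str, float]:
        return dict(self._values)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ModelParameters({len(self._values)} symbols)"


@dataclass
class SmcState:
    """State of one smooth muscle cell (uM, mV, s units)."""

    ca_i: float
    ca_sr: float
    v_m: float
    w_k: float
    ip3: float

    def to_array(self) -> np.ndarray:
        return np.array([self.ca_i, self.ca_sr, self.v_m, self.w_k, self.ip3])

    @classmethod
    def from_array(cls, arr) -> "SmcState":
        return cls(*(float(x) for x in arr))


@dataclass
class EcState:
    """State of one endothelial cell (uM, mV, s units)."""

    ca_j: float
    ca_er: float
    v_m: float
    ip3: float

    def to_array(self) -> np.ndarray:
        return np.array([self.ca_j, self.ca_er, self.v_m, self.ip3])

    @classmethod
    def from_array(cls, arr) -> "EcState":
        return cls(*(float(x) for x in arr))


@dataclass
class CouplingInflux:
    """Additive gap-junction flux terms entering one cell's RHS.

    ``ca`` and ``ip3`` are concentration fluxes (uM/s); ``v`` is a membrane
    potential rate (mV/s).  All default to zero (uncoupled cell).
    """

    ca: float = 0.0
    ip3: float = 0.0
    v: float = 0.0


# ---------------------------------------------------------------------------
# vectorised flux kernels


def smc_derivatives(ca, sr, v, w, ip3, p: ModelParameters,
                    j_ca=0.0, j_ip3=0.0, j_v=0.0):
    """Time derivatives of the five SMC variables (array-friendly).

    ``j_ca``/``j_ip3``/``j_v`` are additive coupling fluxes.  Returns a tuple
    ``(dca, dsr, dv, dw, dip3)``.
    """
    j_ip3r = p.F_smc * ip3 ** 2 / (p.Kr_smc ** 2 + ip3 ** 2)
    j_serca = p.B_smc * ca ** 2 / (ca ** 2 + p.cb_smc ** 2)
    j_cicr = (p.C_smc * sr ** 2 / (p.sc_smc ** 2 + sr ** 2)
              * ca ** 4 / (p.cc_smc ** 4 + ca ** 4))
    j_extr = p.D_smc * ca * (1.0 + (v - p.vd_smc) / p.Rd_smc)
    j_leak = p.L_smc * sr
    j_vocc = p.G_Ca * (v - p.v_Ca1) / (1.0 + np.exp(-(v - p.v_Ca2) / p.R_Ca))
    j_naca = p.G_NaCa * ca / (ca + p.c_NaCa) * (v - p.v_NaCa)
    j_cl = p.G_Cl * (v - p.v_Cl)
    j_k = p.G_K * w * (v - p.v_K)
    k_act = ((ca + p.c_w) ** 2
             / ((ca + p.c_w) ** 2 + p.beta_w * np.exp(-(v - p.v_Ca3) / p.R_K)))

    dca = (j_ip3r - j_serca + j_cicr - j_extr + j_leak
           - j_vocc + j_naca + j_ca)
    dsr = j_serca - j_cicr - j_leak
    dv = p.gamma_smc * (-p.F_NaK - j_cl - 2.0 * j_vocc - j_naca - j_k) + j_v
    dw = p.lambda_w * (k_act - w)
    dip3 = -p.k_ip3_smc * ip3 + j_ip3
    return dca, dsr, dv, dw, dip3


def ec_derivatives(ca, er, v, ip3, p: ModelParameters, j_plc=0.0,
                   j_ca=0.0, j_ip3=0.0, j_v=0.0):
    """Time derivatives of the four EC variables (array-friendly).

    ``j_plc`` is the agonist-driven IP3 production flux (uM/s); it enters
    only the IP3 equation.  Returns ``(dca, der, dv, dip3)``.
    """
    log_ca = np.log10(np.maximum(ca, _LOG_FLOOR))
    j_ip3r = p.F_ec * ip3 ** 2 / (p.Kr_ec ** 2 + ip3 ** 2)
    j_serca = p.B_ec * ca ** 2 / (ca ** 2 + p.cb_ec ** 2)
    j_cicr = (p.C_ec * er ** 2 / (p.sc_ec ** 2 + er ** 2)
              * ca ** 4 / (p.cc_ec ** 4 + ca ** 4))
    j_extr = p.D_ec * ca
    j_leak = p.L_ec * er
    j_cat = (p.G_cat * (p.E_Ca - v) * 0.5
             * (1.0 + np.tanh((log_ca - p.m3_cat) / p.m4_cat)))

    # K+ channel open probability: BKCa part (max 0.4) jointly gated by v and
    # cytosolic Ca, plus SKCa part (max 0.6) gated by Ca alone (the EDH route)
    num = (log_ca - p.c_bk) * (v - p.b_bk) - p.a1_bk
    den = p.m3_bk * (v + p.a2_bk * (log_ca - p.c_bk) - p.b_bk) ** 2 + p.m4_bk
    p_bk = 0.2 * (1.0 + np.tanh(num / den))
    p_sk = 0.3 * (1.0 + np.tanh((log_ca - p.m3_sk) / p.m4_sk))
    i_k = p.G_tot_ec * (p_bk + p_sk) * (v - p.v_K_ec)   # pS*mV
    i_r = p.G_R_ec * (v - p.v_rest_ec)
    dv = -(i_k + i_r) / p.C_m_ec + j_v              # pS*mV/pF = mV/s

    dca = (j_ip3r - j_serca + j_cicr - j_extr + j_leak
           + j_cat + p.J0_ec + j_ca)
    der = j_serca - j_cicr - j_leak
    dip3 = j_plc - p.k_ip3_ec * ip3 + j_ip3
    return dca, der, dv, dip3


# ---------------------------------------------------------------------------
# state-object wrappers


def smc_rhs(state: SmcState, params: ModelParameters,
            influx: CouplingInflux | None = None) -> np.ndarray:
    """RHS of one SMC; returns the five derivatives as an array."""
    influx = influx or CouplingInflux()
    return np.array(smc_derivatives(
        state.ca_i, state.ca_sr, state.v_m, state.w_k, state.ip3,
        params, j_ca=influx.ca, j_ip3=influx.ip3, j_v=influx.v))


def ec_rhs(state: EcState, params: ModelParameters,
           influx: CouplingInflux | None = None,
           j_plc: float = 0.0) -> np.ndarray:
    """RHS of one EC; returns the four derivatives as an array."""
    influx = influx or CouplingInflux()
    return np.array(ec_derivatives(
        state.ca_j, state.ca_er, state.v_m, state.ip3,
        params, j_plc=j_plc, j_ca=influx.ca, j_ip3=influx.ip3, j_v=influx.v))


def unit_rhs(ec: EcState, smc: SmcState, params: ModelParameters,
             coupling, j_plc: float = 0.0) -> np.ndarray:
    """RHS of a single heterocellularly coupled EC/SMC unit (9 derivatives).

    ``coupling`` is any object exposing the flag/rate attributes of
    :class:`cawave.coupling.CouplingConfig`; only its heterocellular entries
    are used here.  Each coupled species exchanges flux
    ``g * (x_ec - x_smc)`` into the SMC and the exact opposite into the EC,
    so heterocellular fluxes are conserved pairwise.

    Returns the concatenated ``(ec 4, smc 5)`` derivative vector.
    """
    f_v = coupling.g_v_hetero * (ec.v_m - smc.v_m) if coupling.hetero_v else 0.0
    f_ca = (coupling.g_ca_hetero * (ec.ca_j - smc.ca_i)
            if coupling.hetero_ca else 0.0)
    f_ip3 = (coupling.g_ip3_hetero * (ec.ip3 - smc.ip3)
             if coupling.hetero_ip3 else 0.0)
    dec = ec_rhs(ec, params, CouplingInflux(ca=-f_ca, ip3=-f_ip3, v=-f_v),
                 j_plc=j_plc)
    dsmc = smc_rhs(smc, params, CouplingInflux(ca=f_ca, ip3=f_ip3, v=f_v))
    return np.concatenate([dec, dsmc])


# ---------------------------------------------------------------------------
# rest state


def _isolated_rhs(y: np.ndarray, params: ModelParameters,
                  j_plc: float) -> np.ndarray:
    dec = ec_derivatives(*y[:4], params, j_plc=j_plc)
    dsmc = smc_derivatives(*y[4:], params)
    return np.concatenate([np.asarray(dec), np.asarray(dsmc)])


def rest_state(params: ModelParameters | None = None, j_plc: float = 0.0,
               relax_time: float = 500.0) -> tuple[EcState, SmcState]:
    """Rest state of the two isolated cells at a given agonist flux.

    Found by relaxation integration for ``relax_time`` seconds from a generic
    physiological guess, followed by root polishing of the uncoupled RHS.
    This is the initial-condition convention of the package: parameter
    derived, hence reproducible without any stated initial values.
    """
    params = params or ModelParameters()
    # layout: ec(ca, er, v, ip3) then smc(ca, sr, v, w, ip3)
    y0 = np.array([0.1, 1.0, -60.0, max(j_plc, 1e-3) / 0.1,
                   0.1, 1.0, -45.0, 0.1, 0.0])
    sol = solve_ivp(lambda t, y: _isolated_rhs(y, params, j_plc),
                    (0.0, relax_time), y0, method="LSODA",
                    rtol=1e-8, atol=1e-10)
    y_rel = sol.y[:, -1]
    y_fix = fsolve(lambda y: _isolated_rhs(y, params, j_plc), y_rel,
                   xtol=1e-13)
    resid = _isolated_rhs(y_fix, params, j_plc)
    if np.max(np.abs(resid)) > 1e-9:
        # near a Hopf point relaxation may keep orbiting; report the issue
        raise RuntimeError(
            f"rest-state search did not converge (max |rhs| = "
            f"{np.max(np.abs(resid)):.2e}); the cell may be oscillatory "
            f"at j_plc={j_plc}")
    return EcState.from_array(y_fix[:4]), SmcState.from_array(y_fix[4:])
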