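"""Single-cell ChI Ca²⁺/IP₃ dynamics and gap-junction IP₃ flux.

The ChI model describes one astrocyte by three variables: cytosolic Ca²⁺
concentration ``C`` (μM), the fraction ``h`` of IP₃ receptor channels not yet
inactivated by Ca²⁺, and cytosolic IP₃ concentration ``I`` (μM).  Calcium
follows the Li-Rinzel description of IP₃-receptor mediated Ca²⁺-induced
Ca²⁺ release from the ER, with SERCA re-uptake and a passive leak; IP₃ is
produced by Ca²⁺-activated PLCδ and degraded by IP₃-3K and IP-5P.  On a
network, cells additionally exchange IP₃ through gap-junction channels.

This module provides the closed-form right-hand side used both by the
vectorised integration kernel and by the tests; it is the single source of
truth for the flux forms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import optimize

from .params import ChIParams, GJParams

if TYPE_CHECKING:  # pragma: no cover
    from .topology import CouplingNetwork


@dataclass
class CellState:
    """State of one astrocyte: Ca²⁺ ``C`` (μM), gating ``h`` ∈ [0,1], IP₃ ``I`` (μM)."""

    C: float
    h: float
    I: float

    def __post_init__(self) -> None:
        if self.C < 0 or self.I < 0 or not 0 <= self.h <= 1:
            raise ValueError(f"invalid cell state C={self.C}, h={self.h}, I={self.I}")


def calcium_fluxes(state: CellState, params: ChIParams) -> tuple[float, float, float]:
    """ER↔cytosol Ca²⁺ fluxes ``(J_C, J_L, J_P)`` in μM s⁻¹.

    ``J_C`` is the IP₃R-gated CICR efflux, ``J_L`` the passive leak (both
    proportional to the ER-cytosol free Ca²⁺ gradient ``C_T − (1+ρ_A)·C``)
    and ``J_P`` the Hill-2 SERCA uptake.
    """
    p = params
    free = p.C_T - (1.0 + p.rho_A) * state.C
    m_inf = state.I / (state.I + p.d1)
    n_inf = state.C / (state.C + p.d5)
    J_C = p.Omega_C * (m_inf * n_inf * state.h) ** 3 * free
    J_L = p.Omega_L * free
    J_P = p.O_P * state.C**2 / (state.C**2 + p.K_P**2)
    return J_C, J_L, J_P


def h_kinetics(state: CellState, params: ChIParams) -> tuple[float, float]:
    """IP₃R inactivation gate: equilibrium ``h_inf`` and relaxation rate ``Omega_h`` (s⁻¹)."""
    p = params
    Q2 = p.d2 * (state.I + p.d1) / (state.I + p.d3)
    h_inf = Q2 / (Q2 + state.C)
    Omega_h = p.O2 * (Q2 + state.C)
    return h_inf, Omega_h


def ip3_fluxes(state: CellState, params: ChIParams) -> tuple[float, float, float]:
    """IP₃ production and degradation ``(J_delta, J_3K, J_5P)`` in μM s⁻¹."""
    p = params
    C, I = state.C, state.I
    J_delta = p.O_delta * (p.kappa_delta / (p.kappa_delta + I)) * C**2 / (C**2 + p.K_delta**2)
    J_3K = p.O_3K * (C**4 / (C**4 + p.K_D**4)) * (I / (I + p.K_3K))
    J_5P = p.Omega_5P * I
    return J_delta, J_3K, J_5P


def gj_flux(delta_I, params: GJParams):
    """Gap-junction IP₃ flux into cell *i* for gradient ``delta_I = I_i − I_j`` (μM s⁻¹).

    Nonlinear mode gates transport on the gradient magnitude: the flux is
    ``−(F/2)·(1 + tanh((|ΔI| − I_θ)/ω_I))·sign(ΔI)``, saturating at ``F`` and
    effectively off below the threshold gradient ``I_θ``.  Linear mode is
    Fickian, ``−F·ΔI``.  Both are odd in ``delta_I`` with ``flux(0) = 0``
    (the 0/0 of the nonlinear form is resolved by the odd extension).
    Accepts scalars or arrays.
    """
    delta_I = np.asarray(delta_I, dtype=float)
    if params.mode == "linear":
        out = -params.F * delta_I
    else:
        mag = np.abs(delta_I)
        out = np.where(
            delta_I == 0.0,
            0.0,
            -(params.F / 2.0)
            * (1.0 + np.tanh((mag - params.I_theta) / params.omega_I))
            * np.sign(delta_I),
        )
    return out if out.ndim else float(out)


def single_cell_rhs(C, h, I, params: ChIParams):
    """Vectorised isolated-cell derivatives ``(dC, dh, dI)``; accepts arrays."""
    p = params
    C = np.asarray(C, dtype=float)
    h = np.asarray(h, dtype=float)
    I = np.asarray(I, dtype=float)
    free = p.C_T - (1.0 + p.rho_A) * C
    m_inf = I / (I + p.d1)
    n_inf = C / (C + p.d5)
    J_C = p.Omega_C * (m_inf * n_inf * h) ** 3 * free
    J_L = p.Omega_L * free
    J_P = p.O_P * C**2 / (C**2 + p.K_P**2)
    Q2 = p.d2 * (I + p.d1) / (I + p.d3)
    dh = p.O2 * (Q2 - (Q2 + C) * h)
    J_delta = p.O_delta * (p.kappa_delta / (p.kappa_delta + I)) * C**2 / (C**2 + p.K_delta**2)
    J_3K = p.O_3K * (C**4 / (C**4 + p.K_D**4)) * (I / (I + p.K_3K))
    J_5P = p.Omega_5P * I
    return J_C + J_L - J_P, dh, J_delta - J_3K - J_5P


def network_rhs(
    states: np.ndarray,
    network: "CouplingNetwork",
    chi: ChIParams,
    gj: GJParams,
    stim=None,
    t: float = 0.0,
) -> np.ndarray:
    """Right-hand side of the coupled network ODE system.

    Parameters
    ----------
    states : ndarray, shape (3, N)
        Rows are ``C``, ``h``, ``I`` for the N cells, in network node order.
    network : CouplingNetwork
        Undirected coupling graph; per-edge strengths, when present,
        override ``gj.F`` edge by edge (symmetrically).
    stim : StimulusProtocol, optional
        When given and active at time ``t``, the stimulated cell's IP₃
        derivative is overridden (clamp mode) or augmented (additive mode).

    Returns the (3, N) array of time derivatives.  Pairwise IP₃ exchange is
    conservative: each edge contributes equal and opposite fluxes to its two
    endpoints, so the coupling terms sum to zero over the network.
    """
    states = np.asarray(states, dtype=float)
    if states.shape != (3, network.n_nodes):
        raise ValueError(
            f"state shape {states.shape} does not match network with {network.n_nodes} nodes"
        )
    C, h, I = states
    dC, dh, dI = single_cell_rhs(C, h, I, chi)
    ei, ej = network.edge_i, network.edge_j
    if len(ei):
        delta = I[ei] - I[ej]
        if network.strengths is not None:
            F_e = network.strengths
        else:
            F_e = np.full(len(ei), gj.F)
        if gj.mode == "linear":
            flux = -F_e * delta
        else:
            mag = np.abs(delta)
            flux = np.where(
                delta == 0.0,
                0.0,
                -(F_e / 2.0) * (1.0 + np.tanh((mag - gj.I_theta) / gj.omega_I)) * np.sign(delta),
            )
        np.add.at(dI, ei, flux)
        np.subtract.at(dI, ej, flux)
    if stim is not None and stim.t_on <= t < stim.t_off:
        if stim.mode == "clamp":
            dI[stim.target_cell] = 0.0
        else:
            dI[stim.target_cell] += stim.I_bias
    return np.stack([dC, dh, dI])


def up_state(chi: ChIParams) -> CellState:
    """Elevated stable fixed point ("Up" state) of the isolated cell.

    With the reference biochemistry the isolated ChI cell is bistable: next
    to the low resting point there is a second attractor with much larger
    Ca²⁺ and IP₃.  A cell sitting there produces IP₃ at the rate it loses
    it, so in a network it acts as a sustained donor until drainage through
    its couplings pulls it back below the separatrix.

    Raises
    ------
    RuntimeError
        If no elevated fixed point distinct from rest is found (monostable
        parameter set).
    """
    def f(y):
        return np.array(single_cell_rhs(y[0], y[1], y[2], chi))

    rest = resting_state(chi)
    # relax toward the attractor first (robust), then polish with a root find
    y = np.array([rest.C, rest.h, 1.2])
    dt = 0.01
    for _ in range(20000):
        k1 = np.array(f(y))
        k2 = np.array(f(y + 0.5 * dt * k1))
        k3 = np.array(f(y + 0.5 * dt * k2))
        k4 = np.array(f(y + dt * k3))
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    sol = optimize.root(f, x0=y, tol=1e-14)
    x = sol.x if np.abs(f(sol.x)).max() <= np.abs(f(y)).max() else y
    if np.abs(f(x)).max() > 1e-10:
        raise RuntimeError("no elevated fixed point found")
    C, h, I = x
    if abs(I - rest.I) < 0.1:
        raise RuntimeError("parameter set is not bistable: only the rest state exists")
    return CellState(C=C, h=h, I=I)


def resting_state(chi: ChIParams, C_theta: float = 0.7) -> CellState:
    """Resting fixed point of an isolated, unstimulated astrocyte.

    Solves ``single_cell_rhs = 0`` numerically and verifies that the rest
    Ca²⁺ lies below the activation threshold ``C_theta`` (i.e. the parameter
    set is excitable-from-rest rather than spontaneously active).

    Raises
    ------
    RuntimeError
        If no root is found or the root is not subthreshold.
    """
    def f(y):
        return np.array(single_cell_rhs(y[0], y[1], y[2], chi))

    sol = optimize.root(f, x0=[0.05, 0.9, 0.05], tol=1e-14)
    if not sol.success or np.abs(f(sol.x)).max() > 1e-10:
        raise RuntimeError("no resting fixed point found: parameter set may be oscillatory")
    C, h, I = sol.x
    if not (0 <= C < C_theta and 0 <= h <= 1 and I >= 0):
        raise RuntimeError(
            f"fixed point C={C:.3g}, h={h:.3g}, I={I:.3g} is not a subthreshold rest state"
        )
    return CellState(C=C, h=h, I=I)
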