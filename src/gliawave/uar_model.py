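"""Stochastic three-state (Unactivated/Activated/Refractory) wave model.

The UAR automaton abstracts the ChI dynamics into a single signaling state
per astrocyte.  What distinguishes it from classical
susceptible-excited-refractory models is the dilution-aware activation rule:
an activated cell's capacity to recruit a neighbour is its *propagation
efficiency* β = 1/N^u, the reciprocal of its number of unactivated
neighbours, so the same IP₃ output spread over more recipients helps each of
them less.  A U cell fires (at rate 1/τ_U) only while the summed efficiency
of its activated neighbours exceeds a degree-dependent threshold
ϑ_i = a·k_i + b — a two-hop neighbourhood rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .topology import CouplingNetwork

U, A, R = 0, 1, 2

#: Default parameters calibrated from the ChI model with the reference
#: biochemistry (outputs of ``calibrate_uar``): τ_U from the mid-wave
#: shell-to-shell transmission delay, τ_A from the donor (supra-threshold
#: IP₃) residence time on a small lattice wave, τ_R from
#: τ_A + τ_R = T_min with T_min the minimum single-cell oscillation
#: period, (a, b) from the per-degree minimal-donor-efficiency thresholds.
DEFAULT_TAU_U = 6.29
DEFAULT_TAU_A = 14.3
DEFAULT_TAU_R = 2.93
DEFAULT_A = 0.0404
DEFAULT_B = 0.0624


@dataclass
class UARParams:
    """Threshold coefficients ``(a, b)`` and transition time constants (s)."""

    a: float = DEFAULT_A
    b: float = DEFAULT_B
    tau_U: float = DEFAULT_TAU_U
    tau_A: float = DEFAULT_TAU_A
    tau_R: float = DEFAULT_TAU_R
    dt: float = 0.1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.tau_U, self.tau_A, self.tau_R) <= 0 or self.dt <= 0:
            raise ValueError("time constants and dt must be > 0")
        if self.a < 0:
            raise ValueError("threshold slope a must be >= 0")


@dataclass
class UARState:
    states: np.ndarray  # int, one of U/A/R per cell
    time: float = 0.0


def propagation_efficiency(state: UARState, net: CouplingNetwork, i: int) -> float:
    """β_i = 1/N_i^u for an activated cell, 0 otherwise.

    ``N_i^u`` counts neighbours of ``i`` not currently activated.  An
    activated cell whose neighbours are all activated has no recipient and
    its efficiency is defined as 0.
    """
    if not 0 <= i < net.n_nodes:
        raise ValueError(f"node {i} not in network")
    if state.states[i] != A:
        return 0.0
    nbrs = np.concatenate([net.edge_j[net.edge_i == i], net.edge_i[net.edge_j == i]])
    n_u = int(np.sum(state.states[nbrs] != A))
    return 1.0 / n_u if n_u >= 1 else 0.0


def _all_efficiencies(states: np.ndarray, net: CouplingNetwork) -> np.ndarray:
    n_u = np.zeros(net.n_nodes, dtype=np.int64)
    not_a_i = (states[net.edge_i] != A).astype(np.int64)
    not_a_j = (states[net.edge_j] != A).astype(np.int64)
    np.add.at(n_u, net.edge_i, not_a_j)
    np.add.at(n_u, net.edge_j, not_a_i)
    beta = np.zeros(net.n_nodes)
    act = (states == A) & (n_u >= 1)
    beta[act] = 1.0 / n_u[act]
    return beta


def uar_step(
    state: UARState,
    net: CouplingNetwork,
    params: UARParams,
    rng: np.random.Generator,
    thresholds: Optional[np.ndarray] = None,
    source: Optional[int] = None,
    source_efficiency: float = 1.0,
) -> UARState:
    """One synchronous update of all cells.

    Each U cell whose summed neighbour efficiency exceeds its threshold
    ϑ_i = a·k_i + b fires with probability 1 − exp(−dt/τ_U); A cells decay
    to R and R cells back to U with the analogous exponential-rate
    probabilities.  All draws are independent.

    When ``source`` is given and in state A, its efficiency is overridden
    with ``source_efficiency``: an externally stimulated cell's IP₃ output
    is continuously replenished, so — unlike a relay cell — it delivers an
    activating dose to each neighbour instead of dividing a fixed pool.
    """
    s = state.states
    if thresholds is None:
        thresholds = params.a * net.degrees() + params.b
    beta = _all_efficiencies(s, net)
    if source is not None and s[source] == A:
        beta[source] = source_efficiency
    drive = np.zeros(net.n_nodes)
    np.add.at(drive, net.edge_i, beta[net.edge_j])
    np.add.at(drive, net.edge_j, beta[net.edge_i])
    u = rng.random(net.n_nodes)
    p_fire = 1.0 - np.exp(-params.dt / params.tau_U)
    p_rest = 1.0 - np.exp(-params.dt / params.tau_A)
    p_back = 1.0 - np.exp(-params.dt / params.tau_R)
    new = s.copy()
    new[(s == U) & (drive > thresholds) & (u < p_fire)] = A
    new[(s == A) & (u < p_rest)] = R
    new[(s == R) & (u < p_back)] = U
    return UARState(states=new, time=state.time + params.dt)


def simulate_uar(
    net: CouplingNetwork,
    params: UARParams,
    source: int,
    T: float,
    t_stim: Optional[float] = None,
    source_efficiency: float = 1.0,
):
    """Run the UAR automaton for ``T`` seconds with a persistently activated source.

    The source starts in A and is re-seeded to A whenever it decays, for the
    whole stimulation duration ``t_stim`` (default: the full run, matching
    the ChI protocol where the source receives its IP₃ bias throughout),
    and propagates at full efficiency ``source_efficiency`` while
    stimulated.  Returns an object with ``activated`` flags,
    first-activation times and ``n_act``.
    """
    from .icw_engine import ActivationRecord

    if not 0 <= source < net.n_nodes:
        raise ValueError(f"source {source} not in network")
    if t_stim is None:
        t_stim = T
    rng = np.random.default_rng(params.seed)
    s = np.full(net.n_nodes, U, dtype=np.int64)
    s[source] = A
    state = UARState(states=s)
    thresholds = params.a * net.degrees() + params.b
    activated = np.zeros(net.n_nodes, dtype=bool)
    activated[source] = True
    t_first = np.full(net.n_nodes, np.nan)
    t_first[source] = 0.0
    n_steps = int(round(T / params.dt))
    for _ in range(n_steps):
        stim_on = state.time < t_stim
        state = uar_step(state, net, params, rng, thresholds,
                         source=source if stim_on else None,
                         source_efficiency=source_efficiency)
        if state.time <= t_stim and state.states[source] != A:
            state.states[source] = A
        newly = (state.states == A) & ~activated
        activated |= newly
        t_first[newly] = state.time
    return ActivationRecord(
        activated=activated, t_first=t_first,
        tail_mean_C=np.zeros(net.n_nodes), tail_mean_I=np.zeros(net.n_nodes),
    )


# ---------------------------------------------------------------------------
# calibration from the ChI model


def minimum_oscillation_period(
    chi,
    I_grid=None,
    T: float = 400.0,
    dt: float = 0.01,
    C_theta: float = 0.7,
) -> tuple[float, float]:
    """Minimum Ca²⁺ oscillation period over clamped IP₃ levels.

    Integrates a single cell with IP₃ held at each grid value, measures the
    steady inter-peak interval after discarding the first half of the run,
    and returns ``(T_min, I_at_min)``.  Raises if no clamp level produces
    sustained supra-threshold oscillations.
    """
    from scipy.signal import find_peaks

    from .icw_engine import SimulationSettings, StimulusProtocol, integrate
    from .topology import CouplingNetwork
    from .params import GJParams

    if I_grid is None:
        I_grid = np.arange(0.4, 1.3001, 0.02)
    net1 = CouplingNetwork(1, np.array([], dtype=np.int64), np.array([], dtype=np.int64))
    gj0 = GJParams(F=0.0)
    best = (np.inf, np.nan)
    settings = SimulationSettings(T=T, dt=dt, record=True, record_stride=1)
    for I_clamp in I_grid:
        stim = StimulusProtocol(target_cell=0, t_on=0.0, t_off=T, I_bias=float(I_clamp),
                                mode="clamp")
        rec = integrate(net1, chi, gj0, stim, settings)
        trace = rec.traj_C[:, 0]
        half = len(trace) // 2
        peaks, _ = find_peaks(trace[half:], height=C_theta, prominence=0.2)
        if len(peaks) >= 3:
            period = float(np.diff(peaks).mean() * dt)
            if period < best[0]:
                best = (period, float(I_clamp))
    if not np.isfinite(best[0]):
        raise RuntimeError("no oscillatory clamp level found: calibration failure")
    return best


def two_cell_delay(chi, gj, t_stim: float = 1.0, T: float = 60.0, dt: float = 0.01,
                   C_theta: float = 0.7) -> float:
    """Source-to-neighbour transmission delay in the two-cell ChI experiment.

    Cell 1 is stimulated briefly; the returned delay separates the Ca²⁺
    threshold crossings of cell 1 and cell 2.  Note that a directly
    stimulated donor is far stronger than a relay cell, so this delay is a
    lower bound on the mid-wave hop time (see :func:`relay_delay`).
    """
    from .experiments import make_fixture
    from .icw_engine import SimulationSettings, StimulusProtocol, integrate

    _, net = make_fixture("two_cell")
    stim = StimulusProtocol(target_cell=0, t_on=0.0, t_off=t_stim)
    settings = SimulationSettings(T=T, dt=dt, C_theta=C_theta)
    rec = integrate(net, chi, gj, stim, settings)
    if not rec.activated.all():
        raise RuntimeError("two-cell transmission failed: cannot calibrate tau_U")
    return float(rec.t_first[1] - rec.t_first[0])


def _lattice_wave(chi, gj, T: float, dt: float):
    from .experiments import make_fixture
    from .icw_engine import SimulationSettings, StimulusProtocol, central_cell, integrate
    from .shell_analysis import shell_decomposition

    pos, net = make_fixture("lattice_5")
    src = central_cell(pos.coords)
    stim = StimulusProtocol(target_cell=src, t_off=T)
    settings = SimulationSettings(T=T, dt=dt, record=True, record_stride=10)
    rec = integrate(net, chi, gj, stim, settings)
    shells = shell_decomposition(net, src)
    return rec, shells, src, dt * settings.record_stride


def relay_delay(chi, gj, T: float = 120.0, dt: float = 0.01) -> float:
    """Mid-wave cell-to-cell transmission delay τ_U.

    Measured as the median shell-to-shell difference of first-activation
    times of a 5³ lattice wave — the delay between the Ca²⁺ increases of a
    relay cell and the cells it recruits, in a propagating-front context.
    """
    rec, shells, _, _ = _lattice_wave(chi, gj, T, dt)
    med = np.array([np.nanmedian(rec.t_first[m]) for m in shells.members])
    diffs = np.diff(med[np.isfinite(med)])
    diffs = diffs[diffs > 0]
    if len(diffs) == 0:
        raise RuntimeError("lattice wave did not advance; cannot calibrate tau_U")
    return float(np.median(diffs))


def active_period(chi, gj, T: float = 120.0, dt: float = 0.01) -> float:
    """Activated-state residence time τ_A measured on a small lattice wave.

    A relay cell counts as an active donor while its IP₃ exceeds the level
    that can drive gap-junction transport into a resting neighbour,
    ``I_rest + I_theta`` (the gradient threshold measured against the
    resting baseline).  Because an isolated elevated cell is a stable Up
    state, the residence time is only finite in a coupled context where
    neighbours drain the cell; a 5³ lattice wave provides that context, and
    τ_A is the median supra-threshold duration over its non-source cells.
    """
    from .chi_dynamics import resting_state

    rec, shells, src, frame_dt = _lattice_wave(chi, gj, T, dt)
    rest = resting_state(chi)
    ref = rest.I + gj.I_theta
    durations = []
    for c in np.flatnonzero(rec.activated):
        if c == src:
            continue
        above = rec.traj_I[:, c] >= ref
        if above.any():
            durations.append(above.sum() * frame_dt)
    if not durations:
        raise RuntimeError("no relay cell exceeded the donor threshold; cannot calibrate tau_A")
    return float(np.median(durations))


def _single_donor_fires(chi, gj, k: int, u: int, window: float, dt: float = 0.01) -> bool:
    """Does one just-activated donor with ``u`` private sinks fire a degree-k hub?"""
    from . import _kernel
    from .chi_dynamics import resting_state, up_state

    rest = resting_state(chi)
    up = up_state(chi)
    ei = [0] * k
    ej = list(range(1, k + 1))
    nxt = k + 1
    for _ in range(u):
        ei.append(1)
        ej.append(nxt)
        nxt += 1
    net = CouplingNetwork(nxt, np.array(ei, dtype=np.int64), np.array(ej, dtype=np.int64))
    n = net.n_nodes
    C = np.full(n, rest.C)
    h = np.full(n, rest.h)
    I = np.full(n, rest.I)
    C[1], h[1], I[1] = up.C, up.h, up.I
    e0 = np.empty(0, dtype=np.int64)
    rec0 = np.empty((0, 0))
    act, _, _, _, ok = _kernel.rk4_run(
        C, h, I, _kernel.pack_params(chi),
        np.ascontiguousarray(net.edge_i), np.ascontiguousarray(net.edge_j),
        np.full(net.n_edges, gj.F),
        gj.mode == "linear", gj.I_theta, gj.omega_I,
        e0, 0.0, -1.0, 0.0, False, False,
        dt, int(round(window / dt)), 0.7, 1_000_000,
        rec0, rec0, rec0,
    )
    return bool(ok and act[0])


def donor_efficiency_thresholds(
    chi, gj, degrees=range(2, 16), window: float = 14.0, dt: float = 0.01
) -> dict[int, float]:
    """Minimal donor efficiency β that activates a degree-k cell.

    One neighbour of a degree-k hub starts in the just-activated (Up) state
    with ``u`` additional private resting sinks, so its output efficiency
    toward the hub is 1/(u+1).  Scanning ``u`` upward until the hub stops
    firing within ``window`` seconds (the donor's active period) brackets
    the hub's activation threshold; the returned ϑ(k) is the midpoint value
    1/(u*+1.5) with ``u*`` the largest firing sink count.
    """
    out = {}
    for k in degrees:
        u = 0
        while u <= 40 and _single_donor_fires(chi, gj, k, u, window, dt):
            u += 1
        if u == 0:  # not even a full-efficiency donor fires the hub
            out[k] = float("inf")
        else:
            out[k] = 1.0 / ((u - 1) + 1.5)
    return out


def calibrate_uar(chi, gj, degrees=range(2, 16)) -> UARParams:
    """Estimate UAR parameters from ChI-model experiments.

    - τ_U: mid-wave transmission delay (median shell-to-shell activation
      delay on a 5³ lattice wave);
    - τ_A: donor residence time (median duration of supra-threshold IP₃ on
      the same wave);
    - τ_R: from τ_A + τ_R = T_min, with T_min the minimum single-cell Ca²⁺
      oscillation period over clamped IP₃ levels;
    - (a, b): least-squares line through the per-degree activation
      thresholds ϑ(k) measured as the minimal donor efficiency that fires a
      degree-k cell within the donor's active period.
    """
    tau_U = relay_delay(chi, gj)
    T_min, _ = minimum_oscillation_period(chi)
    tau_A = active_period(chi, gj)
    tau_R = T_min - tau_A
    if tau_R <= 0:
        raise RuntimeError("tau_A exceeds the minimum oscillation period; calibration failed")
    theta = donor_efficiency_thresholds(chi, gj, degrees=degrees, window=tau_A)
    ks = np.array([k for k in sorted(theta) if np.isfinite(theta[k])], dtype=float)
    if len(ks) < 2:
        raise RuntimeError("too few usable donor thresholds; calibration failed")
    th = np.array([theta[int(k)] for k in ks])
    a, b = np.polyfit(ks, th, 1)
    return UARParams(a=float(max(a, 0.0)), b=float(b), tau_U=tau_U, tau_A=tau_A, tau_R=tau_R)
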