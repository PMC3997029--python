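"""Network integration, stimulation protocol and ICW extent measurement.

An intercellular calcium wave (ICW) is triggered by clamping the IP₃
concentration of one central astrocyte at ``I_bias`` for the stimulation
window and integrating the coupled ChI system with a fixed-step fourth-order
Runge-Kutta scheme.  A cell counts as *activated* the first time its
cytosolic Ca²⁺ crosses the threshold ``C_theta``; the wave extent is the
number of cells activated at least once, ``N_act`` (the stimulated cell
included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernel
from .chi_dynamics import resting_state
from .params import ChIParams, GJParams
from .topology import CouplingNetwork, mean_degree


@dataclass
class StimulusProtocol:
    """Stimulation of a single cell over ``[t_on, t_off)``.

    The default ``additive`` mode adds ``I_bias`` (μM s⁻¹) to the cell's IP₃
    production, so the injected IP₃ is a finite resource divided among the
    cell's neighbours — the premise of the dilution mechanism that limits
    wave range.  ``clamp`` mode instead holds the cell's IP₃ at ``I_bias``
    (μM), overriding its IP₃ derivative inside every integrator stage; a
    clamped source can sustain an output that grows with its degree, which
    qualitatively changes the propagation regimes.
    """

    target_cell: int = 0
    t_on: float = 0.0
    t_off: float = 200.0
    I_bias: float = 2.0
    mode: str = "additive"

    def __post_init__(self) -> None:
        if not 0 <= self.t_on < self.t_off:
            raise ValueError("need 0 <= t_on < t_off")
        if self.mode not in ("clamp", "additive"):
            raise ValueError(f"unknown stimulation mode {self.mode!r}")


@dataclass
class SimulationSettings:
    T: float = 200.0
    dt: float = 0.01
    C_theta: float = 0.7
    record_stride: int = 10
    record: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.T < self.dt:
            raise ValueError("need dt > 0 and T >= dt")


@dataclass
class ActivationRecord:
    """Per-cell activation outcome of one simulation run."""

    activated: np.ndarray  # bool, (N,)
    t_first: np.ndarray  # s; NaN where never activated
    tail_mean_C: np.ndarray  # time-averaged Ca²⁺ over the final 10% of the run
    tail_mean_I: np.ndarray
    times: Optional[np.ndarray] = None  # recorded frame times (s)
    traj_C: Optional[np.ndarray] = None  # (n_frames, N) when recording enabled
    traj_h: Optional[np.ndarray] = None
    traj_I: Optional[np.ndarray] = None
    settings: Optional[SimulationSettings] = None
    stimulus: Optional[StimulusProtocol] = None

    @property
    def n_act(self) -> int:
        return int(self.activated.sum())


def count_activated(rec: ActivationRecord) -> int:
    """Number of cells activated at least once (N_act), stimulated cell included."""
    return rec.n_act


def central_cell(coords: np.ndarray) -> int:
    """Cell nearest the centroid of the positions; ties broken by lowest id."""
    centroid = coords.mean(axis=0)
    return int(np.argmin(np.linalg.norm(coords - centroid, axis=1)))


def integrate(
    net: CouplingNetwork,
    chi: ChIParams,
    gj: GJParams,
    stim: Optional[StimulusProtocol] = None,
    settings: Optional[SimulationSettings] = None,
    initial: Optional[np.ndarray] = None,
) -> ActivationRecord:
    """Fixed-step RK4 integration of the coupled network over ``[0, T]``.

    All cells start at the resting fixed point of the isolated ChI model
    unless ``initial`` (a (3, N) state array) is given.  The stimulated
    cell's IP₃ override is applied inside every RK4 stage.

    Raises
    ------
    FloatingPointError
        If the state diverges (non-finite values).
    """
    settings = settings or SimulationSettings()
    n = net.n_nodes
    if stim is not None and not 0 <= stim.target_cell < n:
        raise ValueError(f"stimulated cell {stim.target_cell} outside network of {n} nodes")
    if initial is None:
        rest = resting_state(chi, C_theta=settings.C_theta)
        C = np.full(n, rest.C)
        h = np.full(n, rest.h)
        I = np.full(n, rest.I)
    else:
        initial = np.asarray(initial, dtype=float)
        if initial.shape != (3, n):
            raise ValueError(f"initial state shape {initial.shape} != (3, {n})")
        C, h, I = (initial[k].copy() for k in range(3))
    n_steps = int(round(settings.T / settings.dt))
    if settings.record:
        n_frames = (n_steps + settings.record_stride - 1) // settings.record_stride
        rec_C = np.empty((n_frames, n))
        rec_h = np.empty((n_frames, n))
        rec_I = np.empty((n_frames, n))
        times = np.arange(n_frames) * settings.record_stride * settings.dt
    else:
        rec_C = rec_h = rec_I = np.empty((0, 0))
        times = None
    if net.strengths is not None:
        Fe = np.ascontiguousarray(net.strengths, dtype=np.float64)
    else:
        Fe = np.full(net.n_edges, gj.F, dtype=np.float64)
    if stim is None:
        targets = np.empty(0, dtype=np.int64)
        t_on, t_off, I_bias = 0.0, -1.0, 0.0
        clamp = additive = False
    else:
        targets = np.array([stim.target_cell], dtype=np.int64)
        t_on, t_off, I_bias = stim.t_on, stim.t_off, stim.I_bias
        clamp = stim.mode == "clamp"
        additive = stim.mode == "additive"
    activated, t_first, tail_C, tail_I, ok = _kernel.rk4_run(
        C, h, I, _kernel.pack_params(chi),
        np.ascontiguousarray(net.edge_i), np.ascontiguousarray(net.edge_j), Fe,
        gj.mode == "linear", gj.I_theta, gj.omega_I,
        targets, t_on, t_off, I_bias, clamp, additive,
        settings.dt, n_steps, settings.C_theta, settings.record_stride,
        rec_C, rec_h, rec_I,
    )
    if not ok:
        raise FloatingPointError(
            "network state diverged (non-finite values); check parameters and dt"
        )
    return ActivationRecord(
        activated=activated, t_first=t_first,
        tail_mean_C=tail_C, tail_mean_I=tail_I,
        times=times,
        traj_C=rec_C if settings.record else None,
        traj_h=rec_h if settings.record else None,
        traj_I=rec_I if settings.record else None,
        settings=settings, stimulus=stim,
    )


def heterogeneous_strengths(
    net: CouplingNetwork, F: float, sigma_F: float, seed: Optional[int] = None
) -> CouplingNetwork:
    """Draw per-edge coupling strengths from a truncated normal law.

    Each edge gets an independent N(F, σ_F²) draw, rejection-resampled until
    it falls in [0, 2F]; the symmetric truncation preserves the mean F.
    Rejection (rather than clipping) keeps the distribution smooth at the
    bounds.
    """
    if F < 0 or sigma_F < 0:
        raise ValueError("F and sigma_F must be >= 0")
    rng = np.random.default_rng(seed)
    if sigma_F == 0:
        vals = np.full(net.n_edges, F)
    else:
        vals = np.empty(net.n_edges)
        todo = np.arange(net.n_edges)
        while len(todo):
            draw = rng.normal(F, sigma_F, size=len(todo))
            good = (draw >= 0) & (draw <= 2 * F)
            vals[todo[good]] = draw[good]
            todo = todo[~good]
    out = net.with_strengths(vals)
    out.provenance.update({"F": F, "sigma_F": sigma_F, "strength_seed": seed})
    return out


def mean_total_strength(net: CouplingNetwork, F: Optional[float] = None) -> float:
    """Mean total gap-junction strength per cell, ⟨ΣF⟩ (μM s⁻¹).

    Equals ⟨k⟩·F for homogeneous strengths; with per-edge strengths it is the
    average over cells of the summed incident strengths.
    """
    if net.strengths is None:
        if F is None:
            raise ValueError("F required when the network carries no per-edge strengths")
        return mean_degree(net) * F
    total = np.zeros(net.n_nodes)
    np.add.at(total, net.edge_i, net.strengths)
    np.add.at(total, net.edge_j, net.strengths)
    return float(total.mean())


def detect_up_state(
    rec: ActivationRecord, chi: ChIParams, factor: float = 2.0
) -> np.ndarray:
    """Flag cells left in the elevated "Up" state at the end of a run.

    A cell is flagged when its time-averaged Ca²⁺ *and* IP₃ over the final
    10% of the run both exceed ``factor`` × their resting values — the
    signature of the stationary high-Ca²⁺/high-IP₃ state that accompanies
    regenerative propagation at intermediate coupling strengths.
    """
    if rec.tail_mean_C is None or rec.tail_mean_I is None:
        raise ValueError("run record carries no terminal-state statistics")
    rest = resting_state(chi)
    return (rec.tail_mean_C > factor * rest.C) & (rec.tail_mean_I > factor * rest.I)
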