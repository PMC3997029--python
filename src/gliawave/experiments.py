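"""Scripted parameter sweeps with replicate management, plus test fixtures.

A sweep runs one ICW simulation per (parameter point, replicate), each on a
freshly sampled network, and records the realised topology quantifiers
alongside the wave extent.  Seeds are derived deterministically from the
base seed and the (point, replicate) indices, so re-running a sweep
reproduces every row bit-identically; completed rows found in an existing
output file are skipped.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .icw_engine import (
    SimulationSettings,
    StimulusProtocol,
    central_cell,
    integrate,
    mean_total_strength,
)
from .params import ChIParams, GJParams
from .topology import (
    AstrocytePositions,
    CouplingNetwork,
    build_erdos_renyi,
    build_link_radius,
    build_regular_degree,
    build_shortcut,
    build_spatial_scale_free,
    lattice_indices,
    mean_degree,
    mean_shortest_path,
    place_astrocytes,
)

#: standard placement: 11³ cells, a = 70 μm, jitter width 55 μm
STANDARD_N_SIDE = 11
STANDARD_A = 70.0
STANDARD_SIGMA = 55.0


def derive_seed(base_seed: int, *indices: int) -> int:
    """Deterministic per-run seed from a base seed and run coordinates (< 2³¹)."""
    ss = np.random.SeedSequence([int(base_seed), *map(int, indices)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _build(topology: str, pos: AstrocytePositions, params: dict, seed: int) -> CouplingNetwork:
    if topology == "regular_degree":
        return build_regular_degree(pos, k=int(params["k"]), seed=seed)
    if topology == "link_radius":
        return build_link_radius(pos, d=float(params["d"]))
    if topology == "shortcut":
        return build_shortcut(pos, m_latt=int(params.get("m_latt", 1)),
                              p_s=float(params.get("p_s", 0.0)), seed=seed)
    if topology == "spatial_scale_free":
        return build_spatial_scale_free(pos, m_sf=int(params.get("m_sf", 3)),
                                        r_c=float(params["r_c"]), seed=seed)
    if topology == "erdos_renyi":
        return build_erdos_renyi(pos.n, p=float(params["p"]), seed=seed)
    raise ValueError(f"unknown topology family {topology!r}")


@dataclass
class SweepSpec:
    """One topology family swept over a parameter grid with replicates."""

    topology: str
    grid: list  # list of parameter dicts, one per sweep point
    replicates: int = 20
    engine: str = "chi"  # or "uar"
    base_seed: int = 0
    n_side: int = STANDARD_N_SIDE
    a: float = STANDARD_A
    sigma: float = STANDARD_SIGMA
    chi: ChIParams = field(default_factory=ChIParams)
    gj: GJParams = field(default_factory=GJParams)
    settings: SimulationSettings = field(default_factory=SimulationSettings)
    uar_params: Optional[object] = None  # UARParams for engine="uar"
    F_override: Optional[float] = None  # homogeneous strength; None → gj.F
    sigma_F: float = 0.0  # heterogeneous strength spread (μM s⁻¹)
    compute_L: bool = False  # mean shortest path is O(N·E); opt-in
    out_csv: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.grid:
            raise ValueError("sweep grid must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.engine not in ("chi", "uar"):
            raise ValueError(f"unknown engine {self.engine!r}")


def run_one(spec: SweepSpec, point_idx: int, rep: int) -> dict:
    """Execute a single (point, replicate) run and return its summary row."""
    from .icw_engine import heterogeneous_strengths
    from .uar_model import UARParams, simulate_uar

    params = spec.grid[point_idx]
    seed = derive_seed(spec.base_seed, point_idx, rep)
    t0 = time.perf_counter()
    pos = place_astrocytes(spec.n_side, spec.a, spec.sigma, seed=seed)
    net = _build(spec.topology, pos, params, seed=derive_seed(seed, 1))
    F = spec.F_override if spec.F_override is not None else spec.gj.F
    if spec.sigma_F > 0:
        net = heterogeneous_strengths(net, F=F, sigma_F=spec.sigma_F,
                                      seed=derive_seed(seed, 2))
        sum_F = mean_total_strength(net)
    else:
        sum_F = mean_total_strength(net, F=F)
    src = central_cell(pos.coords)
    row = {
        "point": point_idx, "replicate": rep, "seed": seed,
        **{k: v for k, v in params.items()},
        "mean_degree": mean_degree(net),
        "sum_F": sum_F,
    }
    if spec.compute_L:
        L, frac_disc = mean_shortest_path(net)
        row["L"] = L
        row["frac_disconnected"] = frac_disc
    if spec.engine == "chi":
        gj = spec.gj if spec.F_override is None else GJParams(
            mode=spec.gj.mode, F=F, I_theta=spec.gj.I_theta, omega_I=spec.gj.omega_I)
        stim = StimulusProtocol(target_cell=src, t_off=spec.settings.T)
        rec = integrate(net, spec.chi, gj, stim, spec.settings)
    else:
        up = spec.uar_params or UARParams()
        up = UARParams(a=up.a, b=up.b, tau_U=up.tau_U, tau_A=up.tau_A,
                       tau_R=up.tau_R, dt=up.dt, seed=derive_seed(seed, 3))
        rec = simulate_uar(net, up, source=src, T=spec.settings.T)
    row["n_act"] = rec.n_act
    row["runtime_s"] = time.perf_counter() - t0
    return row


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run all (point, replicate) pairs of the sweep; resumable via ``out_csv``.

    Individual run failures are logged as rows with ``error`` set and the
    sweep continues.
    """
    done: dict[tuple[int, int], dict] = {}
    out_path = Path(spec.out_csv) if spec.out_csv else None
    if out_path is not None and out_path.exists():
        prev = pd.read_csv(out_path)
        for _, r in prev.iterrows():
            done[(int(r["point"]), int(r["replicate"]))] = r.to_dict()
    rows = []
    for point_idx in range(len(spec.grid)):
        for rep in range(spec.replicates):
            key = (point_idx, rep)
            if key in done:
                rows.append(done[key])
                continue
            try:
                row = run_one(spec, point_idx, rep)
            except Exception as err:  # noqa: BLE001 — sweep must survive bad runs
                row = {"point": point_idx, "replicate": rep, "error": str(err)}
            rows.append(row)
            if out_path is not None:
                pd.DataFrame(rows).to_csv(out_path, index=False)
    return pd.DataFrame(rows)


def summarize(result: pd.DataFrame, by: str = "point") -> pd.DataFrame:
    """Mean ± sample SD of N_act (and quantifiers) per sweep point."""
    if len(result) == 0:
        raise ValueError("empty sweep result")
    ok = result[result["error"].isna()] if "error" in result.columns else result
    cols = [c for c in ("n_act", "mean_degree", "sum_F", "L") if c in ok.columns]
    agg = ok.groupby(by)[cols].agg(["mean", "std"])  # sample SD (ddof=1)
    agg.columns = [f"{c}_{stat}" for c, stat in agg.columns]
    sd_cols = [c for c in agg.columns if c.endswith("_std")]
    agg[sd_cols] = agg[sd_cols].fillna(0.0)  # single replicate → SD 0
    return agg.reset_index()


# ---------------------------------------------------------------------------
# fixtures


def make_fixture(name: str, k: int = 5, seed: int = 0):
    """Deterministic small networks used in tests and calibration.

    - ``two_cell``: two astrocytes 50 μm apart, one coupling.
    - ``star_k``: a hub at the origin with ``k`` leaves 50 μm away.
    - ``lattice_5``: unjittered 5³ cubic lattice, nearest-neighbour couplings.
    - ``standard_positions``: the full 11³ jittered placement (positions
      only; the returned network is empty).
    """
    if name == "two_cell":
        coords = np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]])
        pos = AstrocytePositions(coords=coords, a=50.0, sigma=0.0)
        net = CouplingNetwork(2, np.array([0]), np.array([1]))
        net.provenance = {"type": "fixture:two_cell"}
        return pos, net
    if name == "star_k":
        angles = np.linspace(0, 2 * np.pi, k, endpoint=False)
        leaves = 50.0 * np.stack([np.cos(angles), np.sin(angles), np.zeros(k)], axis=1)
        coords = np.vstack([[0.0, 0.0, 0.0], leaves])
        pos = AstrocytePositions(coords=coords, a=50.0, sigma=0.0)
        net = CouplingNetwork(k + 1, np.zeros(k, dtype=np.int64),
                              np.arange(1, k + 1, dtype=np.int64))
        net.provenance = {"type": "fixture:star", "k": k}
        return pos, net
    if name == "lattice_5":
        pos = place_astrocytes(5, STANDARD_A, 0.0, seed=seed)
        net = build_shortcut(pos, m_latt=1, p_s=0.0, seed=seed)
        net.provenance["type"] = "fixture:lattice_5"
        return pos, net
    if name == "standard_positions":
        pos = place_astrocytes(STANDARD_N_SIDE, STANDARD_A, STANDARD_SIGMA, seed=seed)
        net = CouplingNetwork(pos.n, np.array([], dtype=np.int64), np.array([], dtype=np.int64))
        return pos, net
    raise ValueError(f"unknown fixture {name!r}")
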