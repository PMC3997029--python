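"""Biochemical and coupling parameters of the astrocyte network model.

All concentrations are in μM and all rates in s⁻¹ or μM s⁻¹.  The defaults
reproduce the calibrated parameter set of the ChI astrocyte model (Li-Rinzel
calcium-induced calcium release extended with PLCδ IP₃ production and
degradation by IP₃-3K and IP-5P) used for the network simulations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal


@dataclass
class ChIParams:
    """Single-astrocyte ChI model constants.

    Attributes
    ----------
    d1, d2, d3, d5 : float
        IP₃R binding affinities (μM): IP₃ (d1), inactivating Ca²⁺ (d2),
        IP₃ with Ca²⁺ inactivation (d3), activating Ca²⁺ (d5).
    O2 : float
        Inactivating Ca²⁺ binding rate (μM⁻¹ s⁻¹).
    C_T : float
        Total free ER Ca²⁺ content, cytosolic-volume equivalent (μM).
    rho_A : float
        ER-to-cytoplasm volume ratio (dimensionless).
    Omega_C, Omega_L : float
        Maximal IP₃R release rate / passive ER leak rate (s⁻¹).
    O_P, K_P : float
        Maximal SERCA uptake rate (μM s⁻¹) and its Ca²⁺ affinity (μM).
    O_delta, K_delta, kappa_delta : float
        PLCδ maximal IP₃ production rate (μM s⁻¹), Ca²⁺ affinity (μM) and
        IP₃ inhibition affinity (μM).
    Omega_5P : float
        IP-5P degradation rate (s⁻¹).
    O_3K, K_D, K_3K : float
        IP₃-3K maximal degradation rate (μM s⁻¹), Ca²⁺ affinity (μM) and
        IP₃ affinity (μM).
    """

    d1: float = 0.13
    O2: float = 0.2
    d2: float = 1.049
    d3: float = 0.9434
    d5: float = 0.08234
    C_T: float = 2.0
    rho_A: float = 0.185
    Omega_C: float = 6.0
    Omega_L: float = 0.11
    O_P: float = 0.9
    K_P: float = 0.05
    O_delta: float = 0.7
    K_delta: float = 0.1
    kappa_delta: float = 1.5
    Omega_5P: float = 0.21
    O_3K: float = 4.5
    K_D: float = 1.0
    K_3K: float = 0.7

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"ChIParams.{f.name} must be strictly positive, got {v!r}")


@dataclass
class GJParams:
    """Gap-junction IP₃ transport parameters.

    ``mode='nonlinear'`` uses the sigmoidal threshold flux with maximal flux
    ``F`` (μM s⁻¹), gradient threshold ``I_theta`` (μM) and slope ``omega_I``
    (μM); ``mode='linear'`` uses Fickian diffusion with permeability ``F``
    (s⁻¹).
    """

    mode: Literal["nonlinear", "linear"] = "nonlinear"
    F: float = 2.0
    I_theta: float = 0.3
    omega_I: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in ("nonlinear", "linear"):
            raise ValueError(f"unknown coupling mode {self.mode!r}")
        if self.F < 0:
            raise ValueError("F must be >= 0")
        if self.I_theta < 0:
            raise ValueError("I_theta must be >= 0")
        if not self.omega_I > 0:
            raise ValueError("omega_I must be > 0")


#: Keys accepted in flat parameter files, named after the model symbols.
_CHI_KEYS = {f.name for f in dataclasses.fields(ChIParams)}
_GJ_KEYS = {"mode", "F", "I_theta", "omega_I"}
_EXTRA_KEYS = {"I_bias", "T", "t_s", "C_theta", "dt"}


def load_params(path: str | Path) -> dict:
    """Read a flat key→value parameter file (JSON or YAML).

    Keys must be model symbols (``Omega_C``, ``rho_A``, ``kappa_delta``, …);
    unknown keys are rejected.  Returns a dict with ``chi`` (:class:`ChIParams`),
    ``gj`` (:class:`GJParams`) and ``extra`` (remaining scalar settings such
    as ``I_bias`` or ``T``).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat mapping of parameters")
    unknown = set(raw) - _CHI_KEYS - _GJ_KEYS - _EXTRA_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown parameter keys {sorted(unknown)}")
    chi = ChIParams(**{k: v for k, v in raw.items() if k in _CHI_KEYS})
    gj = GJParams(**{k: v for k, v in raw.items() if k in _GJ_KEYS})
    extra = {k: v for k, v in raw.items() if k in _EXTRA_KEYS}
    return {"chi": chi, "gj": gj, "extra": extra}


def dump_params(chi: ChIParams, gj: GJParams, path: str | Path, **extra) -> None:
    """Write parameters as a flat JSON mapping (symbol → value)."""
    out = dataclasses.asdict(chi)
    out.update(dataclasses.asdict(gj))
    out.update(extra)
    Path(path).write_text(json.dumps(out, indent=1))
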