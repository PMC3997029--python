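# gliawave

Simulation of intercellular Ca²⁺ waves (ICWs) in three-dimensional
astrocyte networks coupled by gap-junction channels (GJCs).

Astrocytes respond to stimulation with cytosolic Ca²⁺ elevations that can
propagate from cell to cell as a wave, carried by IP₃ diffusing through
gap junctions.  Experimentally, the reach of such waves varies enormously —
from a handful of cells to hundreds — even at fixed stimulation.  This
package implements a biophysical model to test one explanation: that the
*topology* of the gap-junction coupling network alone controls the
propagation range.  It is intended for computational neuroscientists and
network-physiology researchers who want to reproduce, probe or extend that
analysis from Python.

## The model

Each of N = 11³ point astrocytes carries the three-variable ChI dynamics —
cytosolic Ca²⁺ C, IP₃-receptor gating h, and IP₃ concentration I:

    dC/dt = J_C(C,h,I) + J_L(C) − J_P(C)
    dh/dt = Ω_h(C,I) · (h∞(C,I) − h)
    dI/dt = J_δ(C,I) − J_3K(C,I) − J_5P(I) + Σ_j J_ij

combining Li–Rinzel Ca²⁺-induced Ca²⁺ release from ER stores with PLCδ
IP₃ production and degradation by IP₃-3K and IP-5P.  Cells exchange IP₃
through a threshold-gated, saturating gap-junction flux

    J_ij = −(F/2)(1 + tanh((|I_i − I_j| − I_θ)/ω_I)) · sign(I_i − I_j).

Cells are placed on a jittered cubic lattice calibrated to hippocampal
cell-distance statistics and wired under five coupling organizations
(regular degree, link radius, rewired-lattice "shortcut", spatial
scale-free, Erdős–Rényi), plus the Voronoi/Delaunay adjacency of
domain-tiling astrocytes.  One central cell receives an IP₃ bias for
200 s; the wave extent N_act counts cells whose Ca²⁺ ever exceeds
C_θ = 0.7 μM.  A shell decomposition quantifies why intra-shell couplings
dilute the wave, and a calibrated stochastic three-state
(Unactivated/Activated/Refractory) automaton reproduces the propagation
rules without the biophysics.

## Worked example

The elementary relay step — one stimulated astrocyte driving its
neighbour through a gap junction (`examples/two_cell_wave.py`):

```python
import gliawave as gw
from gliawave.experiments import make_fixture

chi, gj = gw.ChIParams(), gw.GJParams()
_, net = make_fixture("two_cell")
stim = gw.StimulusProtocol(target_cell=0, t_off=60.0)
rec = gw.integrate(net, chi, gj, stim, gw.SimulationSettings(T=60.0))
print(rec.t_first)        # [1.  1.3]
print(rec.n_act)          # 2
```

Cell 1 crosses the 0.7-μM Ca²⁺ threshold at 1.00 s, its neighbour at
1.30 s: both cells are activated and the 0.30-s gap is the cell-to-cell
transmission delay of the wave.  At network scale
(`examples/icw_extent.py`), a regular-degree network with k = 6 couplings
per cell confines the wave to `N_act = 221` of 1331 cells (seed 0): each
activated cell splits a fixed IP₃ output six ways, and a few shells out
the per-cell dose no longer triggers Ca²⁺ release.  The same positions
wired as a cubic lattice (no intra-shell couplings) carry the wave to all
1331 cells.

Other examples: `build_topologies.py` (the five generators and their
⟨k⟩/L quantifiers), `single_cell_oscillations.py` (clamped-IP₃ periods),
`shell_structure.py` (shell tables and the dilution formula),
`uar_propagation.py` (the simplified stochastic model).

A thin CLI mirrors the library for shell use:
`gliawave generate|simulate|shells|uar|calibrate|sweep|summarize`
(see `gliawave --help`).

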