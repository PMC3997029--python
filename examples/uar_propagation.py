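"""Wave propagation under the simplified three-state (UAR) model.

Each astrocyte is Unactivated, Activated or Refractory.  An activated
cell's power to recruit a neighbour is its efficiency beta = 1/N_u (one
IP3 pool divided among its unactivated neighbours); a cell fires when the
summed efficiency of its activated neighbours exceeds a degree-dependent
threshold.  Parameters are calibrated from the biophysical ChI model.
"""

import numpy as np

import gliawave as gw
from gliawave.uar_model import UARParams, simulate_uar

p = UARParams(seed=0)
print(f"calibrated parameters: a={p.a}, b={p.b}, "
      f"tau_U={p.tau_U} s, tau_A={p.tau_A} s, tau_R={p.tau_R} s\n")

pos = gw.place_astrocytes(11, 70.0, 55.0, seed=0)
src = gw.central_cell(pos.coords)
for name, net in (
    ("regular k=3", gw.build_regular_degree(pos, 3, seed=0)),
    ("regular k=6", gw.build_regular_degree(pos, 6, seed=0)),
    ("regular k=15", gw.build_regular_degree(pos, 15, seed=0)),
):
    counts = [simulate_uar(net, UARParams(seed=s), source=src, T=200.0).n_act
              for s in range(3)]
    print(f"{name:14s} <k>={gw.mean_degree(net):5.2f}  "
          f"N_act median {np.median(counts):6.0f}  (runs: {counts})")
print("\nDense coupling dilutes each cell's output (beta = 1/N_u falls while")
print("the threshold a*k + b rises), collapsing propagation at high degree.")
print("At intermediate degree the automaton is more permissive than the")
print("biophysical engine (see docs/methods.md, Fidelity).")
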