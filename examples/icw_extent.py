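"""Extent of one intercellular calcium wave in a 1331-cell network.

Builds a regular-degree network (k=6) on standard positions, stimulates the
central astrocyte with an IP3 bias for 200 s and counts how many cells the
wave activates (cytosolic Ca2+ above 0.7 uM at least once).
"""

import numpy as np

import gliawave as gw

chi, gj = gw.ChIParams(), gw.GJParams()
pos = gw.place_astrocytes(11, 70.0, 55.0, seed=0)
net = gw.build_regular_degree(pos, 6, seed=0)
src = gw.central_cell(pos.coords)

stim = gw.StimulusProtocol(target_cell=src, t_off=200.0)
rec = gw.integrate(net, chi, gj, stim, gw.SimulationSettings(T=200.0))

tf = rec.t_first[np.isfinite(rec.t_first)]
print(f"network: <k> = {gw.mean_degree(net):.2f}, N = {net.n_nodes}")
print(f"stimulated cell: {src}")
print(f"N_act = {rec.n_act} cells activated at least once")
print(f"last activation at t = {tf.max():.0f} s")
print("At k=6 the wave stays regional: IP3 leaving each activated cell is")
print("split among its neighbours, and past a few shells the per-cell dose")
print("no longer reaches the calcium-release threshold.")
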