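"""Clamped-IP3 oscillations of a single astrocyte.

Holds the IP3 concentration of an isolated ChI cell at a series of levels
and measures the steady Ca2+ oscillation period at each.  The oscillatory
range and the minimum period set the timescales of wave relay: a cell can
fire again no sooner than the minimum period.
"""

import numpy as np

import gliawave as gw

chi = gw.ChIParams()
rest = gw.resting_state(chi)
print(f"resting state: C = {rest.C:.4f} uM, h = {rest.h:.3f}, I = {rest.I:.4f} uM")

T_min, I_at_min = gw.minimum_oscillation_period(chi, I_grid=np.arange(0.5, 1.2, 0.05))
print(f"minimum Ca2+ oscillation period: {T_min:.1f} s at clamped IP3 = {I_at_min:.2f} uM")
print("Cells relay a wave as brief Ca2+ pulses; the minimum period bounds how")
print("often a cell can fire and sets the activated+refractory timescale.")
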