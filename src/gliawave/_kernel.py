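"""Compiled fixed-step RK4 integration kernel for the coupled ChI system.

The kernel is deliberately flat: parameters arrive as a packed float64
vector and the coupling graph as undirected edge arrays, so that a single
scalar loop handles networks from 2 to >10³ cells.  Edge fluxes are applied
with equal magnitude and opposite sign to the two endpoints, making the
gap-junction exchange exactly conservative at every stage.  Stimulation
clamps (IP₃ held at a bias level in one or more cells) are imposed on the
state and on the derivative inside every RK4 stage, not as a post-step
projection, so stage gradients never see a spurious relaxation.
"""

import numpy as np
from numba import njit

# packed ChIParams order used by the kernel
PARAM_ORDER = (
    "d1", "O2", "d2", "d3", "d5", "C_T", "rho_A", "Omega_C", "Omega_L",
    "O_P", "K_P", "O_delta", "K_delta", "kappa_delta", "Omega_5P",
    "O_3K", "K_D", "K_3K",
)


def pack_params(chi) -> np.ndarray:
    return np.array([getattr(chi, k) for k in PARAM_ORDER], dtype=np.float64)


@njit(cache=True)
def _rhs(C, h, I, p, ei, ej, Fe, linear, I_theta, omega_I,
         dC, dh, dI, clamp_active, targets):
    n = C.shape[0]
    d1 = p[0]; O2 = p[1]; d2 = p[2]; d3 = p[3]; d5 = p[4]
    C_T = p[5]; rho_A = p[6]; Omega_C = p[7]; Omega_L = p[8]
    O_P = p[9]; K_P = p[10]; O_delta = p[11]; K_delta = p[12]
    kappa_delta = p[13]; Omega_5P = p[14]; O_3K = p[15]; K_D = p[16]; K_3K = p[17]
    KD4 = K_D * K_D * K_D * K_D
    for i in range(n):
        c = C[i]; hh = h[i]; ii = I[i]
        free = C_T - (1.0 + rho_A) * c
        m = ii / (ii + d1)
        g = c / (c + d5)
        x = m * g * hh
        c2 = c * c
        dC[i] = Omega_C * x * x * x * free + Omega_L * free \
            - O_P * c2 / (c2 + K_P * K_P)
        Q2 = d2 * (ii + d1) / (ii + d3)
        dh[i] = O2 * (Q2 - (Q2 + c) * hh)
        c4 = c2 * c2
        dI[i] = (O_delta * (kappa_delta / (kappa_delta + ii)) * c2 / (c2 + K_delta * K_delta)
                 - O_3K * (c4 / (c4 + KD4)) * (ii / (ii + K_3K))
                 - Omega_5P * ii)
    for e in range(ei.shape[0]):
        a = ei[e]; b = ej[e]
        d = I[a] - I[b]
        if d != 0.0:
            if linear:
                f = -Fe[e] * d
            else:
                ad = d if d > 0.0 else -d
                s = 1.0 if d > 0.0 else -1.0
                f = -(0.5 * Fe[e]) * (1.0 + np.tanh((ad - I_theta) / omega_I)) * s
            dI[a] += f
            dI[b] -= f
    if clamp_active:
        for k in range(targets.shape[0]):
            dI[targets[k]] = 0.0


@njit(cache=True)
def rk4_run(C, h, I, p, ei, ej, Fe, linear, I_theta, omega_I,
            targets, t_on, t_off, I_bias, clamp, additive,
            dt, n_steps, C_theta, stride,
            rec_C, rec_h, rec_I):
    """Integrate the network in place; returns activation and tail statistics.

    ``rec_*`` are preallocated ``(n_frames, N)`` arrays (possibly 0×0) filled
    with the state every ``stride`` steps starting at t = 0.  The returned
    tuple is ``(activated, t_first, tail_C, tail_I, ok)`` where ``tail_C`` /
    ``tail_I`` are time averages over the final 10% of the run and ``ok`` is
    False when the state left the finite range (divergence).
    """
    n = C.shape[0]
    k1C = np.empty(n); k1h = np.empty(n); k1I = np.empty(n)
    k2C = np.empty(n); k2h = np.empty(n); k2I = np.empty(n)
    k3C = np.empty(n); k3h = np.empty(n); k3I = np.empty(n)
    k4C = np.empty(n); k4h = np.empty(n); k4I = np.empty(n)
    tC = np.empty(n); th = np.empty(n); tI = np.empty(n)
    activated = np.zeros(n, np.bool_)
    t_first = np.full(n, np.nan)
    tail_C = np.zeros(n)
    tail_I = np.zeros(n)
    tail_from = (9 * n_steps) // 10
    tail_n = 0
    record = rec_C.shape[0] > 0
    frame = 0
    ok = True
    half = 0.5 * dt
    nt = targets.shape[0]
    for step in range(n_steps):
        t = step * dt
        stim = t_on <= t < t_off
        clamp_now = stim and clamp
        if clamp_now:
            for k in range(nt):
                I[targets[k]] = I_bias
        if record and step % stride == 0 and frame < rec_C.shape[0]:
            for i in range(n):
                rec_C[frame, i] = C[i]
                rec_h[frame, i] = h[i]
                rec_I[frame, i] = I[i]
            frame += 1
        _rhs(C, h, I, p, ei, ej, Fe, linear, I_theta, omega_I,
             k1C, k1h, k1I, clamp_now, targets)
        if stim and additive:
            for k in range(nt):
                k1I[targets[k]] += I_bias
        for i in range(n):
            tC[i] = C[i] + half * k1C[i]
            th[i] = h[i] + half * k1h[i]
            tI[i] = I[i] + half * k1I[i]
        if clamp_now:
            for k in range(nt):
                tI[targets[k]] = I_bias
        _rhs(tC, th, tI, p, ei, ej, Fe, linear, I_theta, omega_I,
             k2C, k2h, k2I, clamp_now, targets)
        if stim and additive:
            for k in range(nt):
                k2I[targets[k]] += I_bias
        for i in range(n):
            tC[i] = C[i] + half * k2C[i]
            th[i] = h[i] + half * k2h[i]
            tI[i] = I[i] + half * k2I[i]
        if clamp_now:
            for k in range(nt):
                tI[targets[k]] = I_bias
        _rhs(tC, th, tI, p, ei, ej, Fe, linear, I_theta, omega_I,
             k3C, k3h, k3I, clamp_now, targets)
        if stim and additive:
            for k in range(nt):
                k3I[targets[k]] += I_bias
        for i in range(n):
            tC[i] = C[i] + dt * k3C[i]
            th[i] = h[i] + dt * k3h[i]
            tI[i] = I[i] + dt * k3I[i]
        if clamp_now:
            for k in range(nt):
                tI[targets[k]] = I_bias
        _rhs(tC, th, tI, p, ei, ej, Fe, linear, I_theta, omega_I,
             k4C, k4h, k4I, clamp_now, targets)
        if stim and additive:
            for k in range(nt):
                k4I[targets[k]] += I_bias
        sixth = dt / 6.0
        for i in range(n):
            C[i] += sixth * (k1C[i] + 2.0 * k2C[i] + 2.0 * k3C[i] + k4C[i])
            h[i] += sixth * (k1h[i] + 2.0 * k2h[i] + 2.0 * k3h[i] + k4h[i])
            I[i] += sixth * (k1I[i] + 2.0 * k2I[i] + 2.0 * k3I[i] + k4I[i])
        if clamp_now:
            for k in range(nt):
                I[targets[k]] = I_bias
        tnext = (step + 1) * dt
        for i in range(n):
            if not activated[i] and C[i] >= C_theta:
                activated[i] = True
                t_first[i] = tnext
        if step >= tail_from:
            tail_n += 1
            for i in range(n):
                tail_C[i] += C[i]
                tail_I[i] += I[i]
        if step % 200 == 199:
            for i in range(n):
                if not np.isfinite(C[i]) or not np.isfinite(I[i]):
                    ok = False
            if not ok:
                break
    if tail_n > 0:
        for i in range(n):
            tail_C[i] /= tail_n
            tail_I[i] /= tail_n
    return activated, t_first, tail_C, tail_I, ok
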