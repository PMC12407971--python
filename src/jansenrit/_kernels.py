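"""Numba inner loop for the Euler-Maruyama network integration.

The kernel advances the full 18-variable-per-region system with explicit
Euler drift and additive diffusion noise in the pyramidal-input velocity
equations.  It records, at every integration step, the combined pyramidal
PSP (the EEG-like output), the combined pyramidal firing rate, the
combined excitatory-feedback potential x0 (the bifurcation variable), and
the two C4 gains at a coarser stride.  State layout matches
``NodeState._FIELDS``: rows 0-5 alpha (x0,y0,x1,y1,x2,y2), 6-11 gamma,
12-13 the C4 gains, 14-17 the slow rate estimates (zp_a, zi_a, zp_g,
zi_g) that drive the plasticity rule.
"""

import numpy as np
from numba import njit

STATE_DIM = 18


@njit(cache=True, fastmath=False)
def _sig(v, zmax, r, vth):
    return zmax / (1.0 + np.exp(r * (vth - v)))


@njit(cache=True, fastmath=False)
def integrate_network(
    n_steps, dt, M, K,
    Aa, aa, Ba, ba,
    Ag, ag, Bg, bg,
    zmax, r, vth,
    C1, C2, C3, Cloc, r_alpha,
    isp_on, rho, tau, beta, c4_min, t_avg,
    p_mean, p_sd, sampled_noise,
    seed, state, c4_stride,
):
    """Integrate in place; returns (eeg, rate, x0, c4, status).

    ``status`` is -1 on success, else the step index at which the state
    became non-finite (checked every 1000 steps).
    """
    n = M.shape[0]
    eeg = np.empty((n_steps, n))
    rate = np.empty((n_steps, n))
    x0out = np.empty((n_steps, n))
    nc4 = (n_steps + c4_stride - 1) // c4_stride
    c4out = np.empty((nc4, n, 2))

    np.random.seed(seed)
    sqdt = np.sqrt(dt)
    scomb = np.empty(n)
    drive = np.empty(n)
    diffusion = (not sampled_noise) and p_sd > 0.0
    status = -1

    for t in range(n_steps):
        # record current state, then evaluate sigmoid outputs for coupling
        for i in range(n):
            va = state[2, i] - state[4, i]
            vg = state[8, i] - state[10, i]
            comb = r_alpha * va + (1.0 - r_alpha) * vg
            eeg[t, i] = comb
            rate[t, i] = r_alpha * _sig(va, zmax, r, vth) + (1.0 - r_alpha) * _sig(vg, zmax, r, vth)
            x0out[t, i] = r_alpha * state[0, i] + (1.0 - r_alpha) * state[6, i]
            scomb[i] = _sig(comb, zmax, r, vth)
        if t % c4_stride == 0:
            k = t // c4_stride
            for i in range(n):
                c4out[k, i, 0] = state[12, i]
                c4out[k, i, 1] = state[13, i]

        # network drive from pre-step states (pyramidal outputs only)
        if K != 0.0:
            for i in range(n):
                acc = 0.0
                for j in range(n):
                    acc += M[i, j] * scomb[j]
                drive[i] = K * Cloc * acc
        else:
            for i in range(n):
                drive[i] = 0.0

        for i in range(n):
            p = p_mean
            if sampled_noise and p_sd > 0.0:
                p = p_mean + p_sd * np.random.standard_normal()

            # alpha subpopulation
            x0 = state[0, i]; y0 = state[1, i]
            x1 = state[2, i]; y1 = state[3, i]
            x2 = state[4, i]; y2 = state[5, i]
            c4 = state[12, i]
            zp = state[14, i]; zi = state[15, i]
            spyr = _sig(x1 - x2, zmax, r, vth)
            sexc = _sig(C1 * x0, zmax, r, vth)
            sinh = _sig(C3 * x0, zmax, r, vth)
            dy0 = Aa * aa * spyr - 2.0 * aa * y0 - aa * aa * x0
            dy1 = Aa * aa * (p + C2 * sexc + drive[i]) - 2.0 * aa * y1 - aa * aa * x1
            dy2 = Ba * ba * c4 * sinh - 2.0 * ba * y2 - ba * ba * x2
            state[0, i] = x0 + dt * y0
            state[1, i] = y0 + dt * dy0
            state[2, i] = x1 + dt * y1
            state[3, i] = y1 + dt * dy1
            state[4, i] = x2 + dt * y2
            state[5, i] = y2 + dt * dy2
            if diffusion:
                state[3, i] += Aa * aa * p_sd * sqdt * np.random.standard_normal()
            state[14, i] = zp + dt * (spyr - zp) / t_avg
            state[15, i] = zi + dt * (sinh - zi) / t_avg
            if isp_on:
                gap = c4 - c4_min
                if gap < 0.0:
                    gap = 0.0
                dc4 = (1.0 / tau) * zi * (zp - rho) * (gap / Cloc) ** beta
                c4new = c4 + dt * dc4
                if c4new < c4_min:
                    c4new = c4_min
                state[12, i] = c4new

            # gamma subpopulation (identical equations, gamma constants)
            x0 = state[6, i]; y0 = state[7, i]
            x1 = state[8, i]; y1 = state[9, i]
            x2 = state[10, i]; y2 = state[11, i]
            c4 = state[13, i]
            zp = state[16, i]; zi = state[17, i]
            spyr = _sig(x1 - x2, zmax, r, vth)
            sexc = _sig(C1 * x0, zmax, r, vth)
            sinh = _sig(C3 * x0, zmax, r, vth)
            dy0 = Ag * ag * spyr - 2.0 * ag * y0 - ag * ag * x0
            dy1 = Ag * ag * (p + C2 * sexc + drive[i]) - 2.0 * ag * y1 - ag * ag * x1
            dy2 = Bg * bg * c4 * sinh - 2.0 * bg * y2 - bg * bg * x2
            state[6, i] = x0 + dt * y0
            state[7, i] = y0 + dt * dy0
            state[8, i] = x1 + dt * y1
            state[9, i] = y1 + dt * dy1
            state[10, i] = x2 + dt * y2
            state[11, i] = y2 + dt * dy2
            if diffusion:
                state[9, i] += Ag * ag * p_sd * sqdt * np.random.standard_normal()
            state[16, i] = zp + dt * (spyr - zp) / t_avg
            state[17, i] = zi + dt * (sinh - zi) / t_avg
            if isp_on:
                gap = c4 - c4_min
                if gap < 0.0:
                    gap = 0.0
                dc4 = (1.0 / tau) * zi * (zp - rho) * (gap / Cloc) ** beta
                c4new = c4 + dt * dc4
                if c4new < c4_min:
                    c4new = c4_min
                state[13, i] = c4new

        if t % 1000 == 0:
            s = 0.0
            for i in range(n):
                s += state[2, i] + state[8, i]
            if not np.isfinite(s):
                status = t
                break

    return eeg, rate, x0out, c4out, status
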