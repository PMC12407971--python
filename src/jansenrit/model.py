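"""Multi-frequency Jansen-Rit node and network simulation.

Each region holds two Jansen-Rit subpopulations (alpha ~10 Hz, gamma
~45 Hz) whose pyramidal PSPs are mixed with weight ``r_alpha`` to form
the region's EEG-like output.  Regions are coupled through the sigmoid
of that combined PSP, scaled by the structural connectivity matrix M,
the local gain C and the global coupling K.  Homeostatic inhibitory
synaptic plasticity (ISP) makes each subpopulation's
inhibitory-to-pyramidal gain C4 a dynamic variable that clamps
pyramidal firing to a target rate rho.

The stochastic system is integrated with Euler-Maruyama at 1 ms.  The
python-level functions here (``node_derivatives``, ``em_step``) are the
reference implementation of one step; ``simulate`` runs the compiled
kernel in :mod:`jansenrit._kernels`, which reproduces repeated
reference steps exactly in the noise-free case.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from ._kernels import integrate_network
from .config import ModelConfig
from .params import (
    NodeState,
    PlasticityParams,
    SigmoidParams,
    SimulationProtocol,
)

__all__ = [
    "SimulationError",
    "SimulationResult",
    "sigmoid",
    "psp_impulse_response",
    "combined_output",
    "combined_pyramidal_rate",
    "node_derivatives",
    "isp_derivative",
    "coupling_drive",
    "em_step",
    "simulate",
    "attractor_scan",
]


class SimulationError(RuntimeError):
    """Raised when the integration produces a non-finite state (blow-up)."""


def sigmoid(v, sp: SigmoidParams = SigmoidParams()):
    """Population firing rate (Hz) from the mean PSP v (mV).

    S(v) = zeta_max / (1 + exp(r (v_th - v))); strictly increasing,
    bounded in (0, zeta_max), S(v_th) = zeta_max / 2.
    """
    return sp.zeta_max / (1.0 + np.exp(sp.r * (sp.v_th - v)))


def psp_impulse_response(A: float, a: float, t):
    """Alpha-function PSP kernel h(t) = A a t e^{-a t} for t >= 0, else 0.

    Peaks at t = 1/a with value A/e.
    """
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0.0, A * a * t * np.exp(-a * np.clip(t, 0.0, None)), 0.0)
    return out if out.ndim else float(out)


def combined_output(state: NodeState, r_alpha: float) -> np.ndarray:
    """EEG-like output: r_alpha-weighted sum of the two pyramidal PSPs (mV)."""
    return r_alpha * (state.x1_a - state.x2_a) + (1.0 - r_alpha) * (state.x1_g - state.x2_g)


def combined_pyramidal_rate(state: NodeState, r_alpha: float, sp: SigmoidParams) -> np.ndarray:
    """Combined pyramidal firing rate (Hz): mixture of the subpopulation rates."""
    return r_alpha * sigmoid(state.x1_a - state.x2_a, sp) + (1.0 - r_alpha) * sigmoid(
        state.x1_g - state.x2_g, sp
    )


def isp_derivative(c4, zeta_inh, zeta_pyr, pp: PlasticityParams, C: float):
    """Rate of change of the inhibitory-to-pyramidal gain C4.

    dC4/dt = (1/tau) zeta_inh (zeta_pyr - rho) ((C4 - C4_min)/C)**beta.
    Zero at the homeostatic fixed point zeta_pyr = rho and at the soft
    bound C4 = C4_min.  In the full model the rates passed in are the
    slow (t_avg-filtered) population-rate estimates, so the rule clamps
    the time-averaged pyramidal rate.
    """
    gap = np.clip(np.asarray(c4, dtype=float) - pp.C4_min, 0.0, None)
    return (1.0 / pp.tau) * zeta_inh * (zeta_pyr - pp.rho) * (gap / C) ** pp.beta


def coupling_drive(state: NodeState, M: np.ndarray, K: float, C: float,
                   r_alpha: float, sp: SigmoidParams) -> np.ndarray:
    """Per-region network input (Hz): K C sum_j M_ij S(combined PSP of j).

    Long-range projections originate from pyramidal cells only, so the
    source signal is the region's r_alpha-combined pyramidal PSP.
    """
    if M.shape[0] != state.n or M.shape[0] != M.shape[1]:
        raise ValueError("connectivity matrix does not match the number of regions")
    return K * C * (M @ sigmoid(combined_output(state, r_alpha), sp))


def node_derivatives(state: NodeState, p_drive, net_drive, cfg: ModelConfig) -> NodeState:
    """Time derivative of the full state (drift only; returned as a NodeState).

    Per subpopulation s:
        dx0 = y0;  dy0 = A_s a_s S(x1-x2) - 2 a_s y0 - a_s^2 x0
        dx1 = y1;  dy1 = A_s a_s (p + C2 S(C1 x0) + net) - 2 a_s y1 - a_s^2 x1
        dx2 = y2;  dy2 = B_s b_s C4_s S(C3 x0) - 2 b_s y2 - b_s^2 x2
    plus the first-order rate-estimator dynamics dz = (S - z)/t_avg and,
    when plasticity is enabled, the ISP equation for each C4_s driven by
    the slow estimates (state.zp_s, state.zi_s).
    """
    sp, cc, pp = cfg.sigmoid, cfg.circuit, cfg.plasticity
    p_drive = np.broadcast_to(np.asarray(p_drive, dtype=float), (state.n,))
    net_drive = np.broadcast_to(np.asarray(net_drive, dtype=float), (state.n,))
    out = {}
    for tag, sub in (("a", cfg.alpha), ("g", cfg.gamma)):
        x0, y0 = getattr(state, f"x0_{tag}"), getattr(state, f"y0_{tag}")
        x1, y1 = getattr(state, f"x1_{tag}"), getattr(state, f"y1_{tag}")
        x2, y2 = getattr(state, f"x2_{tag}"), getattr(state, f"y2_{tag}")
        c4 = getattr(state, f"c4_{tag}")
        s_pyr = sigmoid(x1 - x2, sp)
        s_exc = sigmoid(cc.C1 * x0, sp)
        s_inh = sigmoid(cc.C3 * x0, sp)
        out[f"x0_{tag}"] = y0
        out[f"y0_{tag}"] = sub.A * sub.a * s_pyr - 2 * sub.a * y0 - sub.a**2 * x0
        out[f"x1_{tag}"] = y1
        out[f"y1_{tag}"] = (
            sub.A * sub.a * (p_drive + cc.C2 * s_exc + net_drive)
            - 2 * sub.a * y1 - sub.a**2 * x1
        )
        out[f"x2_{tag}"] = y2
        out[f"y2_{tag}"] = sub.B * sub.b * c4 * s_inh - 2 * sub.b * y2 - sub.b**2 * x2
        zp = getattr(state, f"zp_{tag}")
        zi = getattr(state, f"zi_{tag}")
        out[f"zp_{tag}"] = (s_pyr - zp) / pp.t_avg
        out[f"zi_{tag}"] = (s_inh - zi) / pp.t_avg
        if pp.enabled:
            out[f"c4_{tag}"] = isp_derivative(c4, zi, zp, pp, cc.C)
        else:
            out[f"c4_{tag}"] = np.zeros(state.n)
    return NodeState(**out)


def em_step(state: NodeState, cfg: ModelConfig, M: np.ndarray, dt: float,
            rng: np.random.Generator | None = None) -> NodeState:
    """One Euler-Maruyama step of the coupled network (reference implementation).

    Drift is explicit Euler on :func:`node_derivatives`; with
    ``noise_mode='diffusion'`` an additive A_s a_s sigma_p sqrt(dt) N(0,1)
    increment enters each dy1 update (independent per region and
    subpopulation); with ``noise_mode='sampled'`` the background input p
    itself is drawn N(p_mean, p_sd) per region and step.  With sigma_p = 0
    this reduces to explicit Euler.
    """
    dr = cfg.drive
    n = state.n
    if rng is None:
        rng = np.random.default_rng()
    if dr.noise_mode == "sampled" and dr.p_sd > 0:
        p = dr.p_mean + dr.p_sd * rng.standard_normal(n)
    else:
        p = np.full(n, dr.p_mean)
    net = coupling_drive(state, M, cfg.K, cfg.circuit.C, cfg.circuit.r_alpha, cfg.sigmoid)
    deriv = node_derivatives(state, p, net, cfg)
    new = NodeState(**{
        f: getattr(state, f) + dt * getattr(deriv, f) for f in NodeState._FIELDS
    })
    if dr.noise_mode == "diffusion" and dr.p_sd > 0:
        sq = np.sqrt(dt)
        new.y1_a = new.y1_a + cfg.alpha.A * cfg.alpha.a * dr.p_sd * sq * rng.standard_normal(n)
        new.y1_g = new.y1_g + cfg.gamma.A * cfg.gamma.a * dr.p_sd * sq * rng.standard_normal(n)
    if cfg.plasticity.enabled:
        cmin = cfg.plasticity.C4_min
        new.c4_a = np.clip(new.c4_a, cmin, None)
        new.c4_g = np.clip(new.c4_g, cmin, None)
    return new


@dataclass
class SimulationResult:
    """Decimated, transient-free output of one network simulation.

    ``eeg``: combined pyramidal PSP (mV), shape (n_samples, n_regions);
    ``rate_pyr``: combined pyramidal firing rate (Hz, bin-averaged during
    decimation so it stays within [0, zeta_max]); ``x0``: combined
    excitatory-feedback potential (the bifurcation variable, mV); ``c4``:
    the two ISP gains, shape (n_samples, n_regions, 2) with the alpha
    gain at index 0; ``fs``: output sampling rate (Hz).
    """

    eeg: np.ndarray
    rate_pyr: np.ndarray
    x0: np.ndarray
    c4: np.ndarray
    fs: float
    seed: int
    protocol: SimulationProtocol
    config: ModelConfig

    @property
    def n_regions(self) -> int:
        return self.eeg.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.protocol.t_discard + np.arange(self.eeg.shape[0]) / self.fs

    def save(self, directory) -> None:
        """Write eeg/rate/c4 as delimited text, one file per observable."""
        import os

        os.makedirs(directory, exist_ok=True)
        header = self.config.summary_line() + f" seed={self.seed} fs={self.fs}"
        for name, arr in (("eeg", self.eeg), ("rate_pyr", self.rate_pyr),
                          ("x0", self.x0),
                          ("c4_alpha", self.c4[:, :, 0]), ("c4_gamma", self.c4[:, :, 1])):
            np.savetxt(os.path.join(directory, f"{name}.csv"), arr,
                       delimiter=",", header=header)


def _bin_mean(x: np.ndarray, q: int) -> np.ndarray:
    """Decimate by averaging consecutive length-q bins (boxcar anti-aliasing)."""
    m = (x.shape[0] // q) * q
    return x[:m].reshape(-1, q, *x.shape[1:]).mean(axis=1)


def simulate(cfg: ModelConfig, protocol: SimulationProtocol,
             M: np.ndarray | None = None, seed: int | None = None) -> SimulationResult:
    """Integrate the network and return decimated, transient-free outputs.

    Parameters
    ----------
    cfg : ModelConfig
        Full model configuration (subpopulations, circuit, ISP, drive, K).
    protocol : SimulationProtocol
        Step size, duration, discard window, output rate and seed.
    M : ndarray, optional
        Structural connectivity (square, symmetric, zero diagonal,
        weights in [0, 1]).  ``None`` simulates one isolated region.
    seed : int, optional
        Overrides ``protocol.seed``.

    The EEG-like PSP and x0 are decimated with a zero-phase polyphase
    FIR anti-aliasing filter; the firing rate and C4 gains by bin
    averaging (which preserves the [0, zeta_max] rate bounds).  The
    first ``t_discard`` seconds are then dropped.
    """
    if M is None:
        M = np.zeros((1, 1))
    M = np.ascontiguousarray(np.asarray(M, dtype=float))
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("M must be a square matrix")
    if seed is None:
        seed = protocol.seed
    n = M.shape[0]
    cc, pp, dr = cfg.circuit, cfg.plasticity, cfg.drive
    state = NodeState.initial(n, cc.C4_init,
                              zeta0=float(sigmoid(0.0, cfg.sigmoid))).as_array()
    q = protocol.decimation
    eeg, rate, x0, c4, status = integrate_network(
        protocol.n_steps, protocol.dt, M, float(cfg.K),
        cfg.alpha.A, cfg.alpha.a, cfg.alpha.B, cfg.alpha.b,
        cfg.gamma.A, cfg.gamma.a, cfg.gamma.B, cfg.gamma.b,
        cfg.sigmoid.zeta_max, cfg.sigmoid.r, cfg.sigmoid.v_th,
        cc.C1, cc.C2, cc.C3, cc.C, cc.r_alpha,
        pp.enabled, pp.rho, pp.tau, pp.beta, pp.C4_min, pp.t_avg,
        dr.p_mean, dr.p_sd, dr.noise_mode == "sampled",
        int(seed) % (2**32), state, q,
    )
    if status >= 0:
        raise SimulationError(
            f"state became non-finite at t={status * protocol.dt:.3f} s "
            f"(K={cfg.K}, r_alpha={cc.r_alpha}, isp={pp.enabled}); "
            "reduce K or enable ISP"
        )
    if q > 1:
        # polyphase FIR decimation; line padding avoids end-of-array edge
        # artifacts that a plain filtfilt decimator leaves on signals with
        # a large DC offset
        eeg = signal.resample_poly(eeg, 1, q, axis=0, padtype="line")
        x0 = signal.resample_poly(x0, 1, q, axis=0, padtype="line")
        rate = _bin_mean(rate, q)
        m = min(eeg.shape[0], rate.shape[0], c4.shape[0])
        eeg, x0, rate, c4 = eeg[:m], x0[:m], rate[:m], c4[:m]
    k = int(round(protocol.t_discard * protocol.out_fs))
    return SimulationResult(
        eeg=eeg[k:], rate_pyr=rate[k:], x0=x0[k:], c4=c4[k:],
        fs=protocol.out_fs, seed=int(seed), protocol=protocol, config=cfg,
    )


def attractor_scan(p_values, cfg: ModelConfig, protocol: SimulationProtocol | None = None,
                   amplitude_threshold: float = 0.1) -> pd.DataFrame:
    """Numerical attractor scan over the background input p (noise-free).

    For each p, a deterministic simulation is classified as oscillatory
    when the retained EEG-like PSP has peak-to-peak amplitude above
    ``amplitude_threshold`` (mV); limit cycles and fixed points differ by
    orders of magnitude on this scale.  Returns a table with columns
    ``p``, ``x0_min``, ``x0_max``, ``freq`` (Welch peak, Hz) and
    ``oscillating``.
    """
    from .observables import dominant_frequency, welch_psd

    p_values = np.asarray(p_values, dtype=float)
    if np.any(np.diff(p_values) < 0):
        raise ValueError("p_values must be sorted ascending")
    if protocol is None:
        protocol = SimulationProtocol(t_sim=60.0, t_discard=30.0, out_fs=200.0)
    rows = []
    for p in p_values:
        c = replace(cfg, drive=replace(cfg.drive, p_mean=float(p), p_sd=0.0))
        res = simulate(c, protocol)
        x = res.eeg[:, 0]
        ptp = float(np.ptp(x))
        f, pxx = welch_psd(x, res.fs)
        rows.append({
            "p": float(p),
            "x0_min": float(res.x0[:, 0].min()),
            "x0_max": float(res.x0[:, 0].max()),
            "amplitude": ptp,
            "freq": dominant_frequency((f, pxx)) if ptp > 0 else 0.0,
            "oscillating": ptp > amplitude_threshold,
        })
    return pd.DataFrame(rows)
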