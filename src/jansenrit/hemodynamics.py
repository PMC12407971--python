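"""Balloon-Windkessel hemodynamic forward model (Stephan-style generalized form).

Pyramidal firing drives a vasodilatory signal s, which drives blood
inflow f, venous volume v and deoxyhemoglobin content q (all normalized
to rest):

    ds/dt = z - s/tau_s - (f - 1)/tau_f
    df/dt = s
    dv/dt = (f - v**(1/kappa)) / tau_v
    dq/dt = (f (1 - (1-E0)**(1/f)) / E0 - q v**(1/kappa) / v) / tau_q

and the BOLD readout is V0 (k1 (1-q) + k2 (1 - q/v) + k3 (1 - v)).
(0, 1, 1, 1) is the resting fixed point under zero input, where the
readout is exactly 0.  Integration is explicit Euler at 10 ms; the
neural input is bin-averaged onto that grid and the output strided to
the scanner TR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HemodynamicParams", "HemodynamicState", "hemo_derivatives",
           "bold_readout", "simulate_bold"]


@dataclass
class HemodynamicParams:
    tau_s: float = 0.65   # vasodilatory signal decay (s)
    tau_f: float = 0.41   # blood-inflow feedback (s)
    tau_v: float = 0.98   # venous volume (s)
    tau_q: float = 0.98   # deoxyhemoglobin clearance (s)
    kappa: float = 0.32   # vein stiffness (Grubb exponent)
    E0: float = 0.4       # resting oxygen extraction fraction
    V0: float = 0.04      # resting venous blood volume fraction
    k1: float = 2.77
    k2: float = 0.2
    k3: float = 0.5

    def __post_init__(self) -> None:
        for name in ("tau_s", "tau_f", "tau_v", "tau_q"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.E0 < 1.0:
            raise ValueError("E0 must lie in (0, 1)")
        if self.V0 <= 0:
            raise ValueError("V0 must be > 0")


@dataclass
class HemodynamicState:
    """Per-region (or scalar) state: vasodilatory signal s, inflow f, volume v, deoxyHb q."""

    s: np.ndarray
    f: np.ndarray
    v: np.ndarray
    q: np.ndarray

    @classmethod
    def resting(cls, n: int) -> "HemodynamicState":
        return cls(np.zeros(n), np.ones(n), np.ones(n), np.ones(n))


def hemo_derivatives(state: HemodynamicState, z, hp: HemodynamicParams) -> HemodynamicState:
    """Right-hand side of the hemodynamic ODEs for neural input z (per region)."""
    f = np.asarray(state.f, dtype=float)
    v = np.asarray(state.v, dtype=float)
    q = np.asarray(state.q, dtype=float)
    if np.any(f <= 0) or np.any(v <= 0):
        raise ValueError("blood inflow f and volume v must stay positive (fractional powers)")
    ds = np.asarray(z, dtype=float) - state.s / hp.tau_s - (f - 1.0) / hp.tau_f
    df = np.asarray(state.s, dtype=float)
    outflow = v ** (1.0 / hp.kappa)
    dv = (f - outflow) / hp.tau_v
    extraction = (1.0 - (1.0 - hp.E0) ** (1.0 / f)) / hp.E0
    dq = (f * extraction - q * outflow / v) / hp.tau_q
    return HemodynamicState(ds, df, dv, dq)


def bold_readout(state: HemodynamicState, hp: HemodynamicParams):
    """Nonlinear BOLD observation: V0 (k1 (1-q) + k2 (1-q/v) + k3 (1-v))."""
    v = np.asarray(state.v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("blood volume v must be positive")
    q = np.asarray(state.q, dtype=float)
    return hp.V0 * (hp.k1 * (1.0 - q) + hp.k2 * (1.0 - q / v) + hp.k3 * (1.0 - v))


def _bin_mean(x: np.ndarray, q: int) -> np.ndarray:
    m = (x.shape[0] // q) * q
    return x[:m].reshape(-1, q, *x.shape[1:]).mean(axis=1)


def simulate_bold(rate: np.ndarray, in_fs: float,
                  hp: HemodynamicParams | None = None,
                  dt: float = 0.01, tr: float = 2.08,
                  gain: float = 1.0, t_discard: float = 0.0) -> np.ndarray:
    """BOLD-like series from per-region firing rates.

    Parameters
    ----------
    rate : ndarray, shape (n_samples,) or (n_samples, n_regions)
        Combined pyramidal firing rate (Hz).
    in_fs : float
        Sampling rate of ``rate``.
    dt : float
        Hemodynamic Euler step (s); the input is bin-averaged onto this grid.
    tr : float
        Output repetition time (s); the full-rate BOLD is strided at
        round(tr/dt) (the signal band is far below the 10 ms grid's
        Nyquist, so plain striding does not alias).
    gain : float
        Scaling applied to the rate before it enters the vasodilatory
        equation (default 1: rates in Hz are passed through unchanged).
    t_discard : float
        Initial transient (s) removed from the returned series.

    Returns the BOLD series with shape (n_tr, n_regions).
    """
    if hp is None:
        hp = HemodynamicParams()
    z = np.asarray(rate, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("neural input contains non-finite values")
    squeeze = z.ndim == 1
    if squeeze:
        z = z[:, None]
    ratio = in_fs * dt
    if ratio >= 1.0:
        q = int(round(ratio))
        if abs(ratio - q) > 1e-9:
            raise ValueError("in_fs must be an integer multiple of the hemodynamic rate 1/dt")
        z = _bin_mean(z, q) if q > 1 else z
    else:
        rep = int(round(1.0 / ratio))
        if abs(1.0 / ratio - rep) > 1e-9:
            raise ValueError("1/dt must be an integer multiple of in_fs")
        z = np.repeat(z, rep, axis=0)
    z = gain * z
    n_steps, n = z.shape
    st = HemodynamicState.resting(n)
    bold = np.empty((n_steps, n))
    for t in range(n_steps):
        bold[t] = bold_readout(st, hp)
        d = hemo_derivatives(st, z[t], hp)
        st = HemodynamicState(st.s + dt * d.s, st.f + dt * d.f,
                              st.v + dt * d.v, st.q + dt * d.q)
    stride = int(round(tr / dt))
    out = bold[::stride]
    k = int(round(t_discard / tr))
    out = out[k:]
    return out[:, 0] if squeeze else out
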