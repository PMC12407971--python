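"""Parameter containers for the multi-frequency Jansen-Rit model.

Each brain region is modelled as two Jansen-Rit subpopulations (cortical
columns) tuned to oscillate in the alpha (~10 Hz) and gamma (~45 Hz) EEG
bands.  The containers below hold the kinetic constants of one
subpopulation, the local circuit gains, the homeostatic inhibitory
plasticity (ISP) rule, the stochastic background drive, and the simulation
protocol.  Defaults are the model's published operating point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SigmoidParams",
    "SubpopulationParams",
    "LocalCircuitParams",
    "PlasticityParams",
    "DriveParams",
    "SimulationProtocol",
    "NodeState",
    "resolve_gamma_gains",
    "alpha_subpopulation",
    "gamma_subpopulation",
]


@dataclass
class SigmoidParams:
    """Sigmoidal PSP-to-firing-rate transfer S(v) = zeta_max / (1 + e^{r (v_th - v)}).

    Parameters
    ----------
    zeta_max : float
        Maximal population firing rate (Hz).
    r : float
        Slope of the sigmoid (1/mV).
    v_th : float
        Membrane potential at half-maximal rate (mV).
    """

    zeta_max: float = 5.0
    r: float = 0.56
    v_th: float = 6.0

    def __post_init__(self) -> None:
        if self.zeta_max <= 0:
            raise ValueError("zeta_max must be > 0")
        if self.r <= 0:
            raise ValueError("r must be > 0")


@dataclass
class SubpopulationParams:
    """Kinetic constants of one subpopulation's PSP kernels.

    ``A``/``B`` are the maximal amplitudes (mV) and ``a``/``b`` the inverse
    characteristic time constants (1/s) of the excitatory/inhibitory
    alpha-function kernels h(t) = A a t e^{-a t}.
    """

    A: float
    B: float
    a: float
    b: float

    def __post_init__(self) -> None:
        for name in ("A", "B", "a", "b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def resolve_gamma_gains(a_gamma: float, b_gamma: float) -> tuple[float, float]:
    """Gamma-subpopulation gains from its inverse time constants.

    The gamma gains scale with the synaptic rate constants so that the
    kernel area (charge transfer) is preserved as the kinetics speed up:
    A_gamma = 32.5 a_gamma / 1000 and B_gamma = 440 b_gamma / 1000.
    Evaluated at the alpha constants (a=120, b=60) these formulas recover
    the alpha gains (3.9, 26.4) mV.
    """
    if a_gamma <= 0 or b_gamma <= 0:
        raise ValueError("inverse time constants must be strictly positive")
    return 32.5 * a_gamma / 1000.0, 440.0 * b_gamma / 1000.0


def alpha_subpopulation() -> SubpopulationParams:
    """Default alpha (~10 Hz) subpopulation constants."""
    return SubpopulationParams(A=3.9, B=26.4, a=120.0, b=60.0)


def gamma_subpopulation(a_gamma: float = 660.0, b_gamma: float = 330.0) -> SubpopulationParams:
    """Default gamma (~45 Hz) subpopulation; gains derived from the time constants."""
    A, B = resolve_gamma_gains(a_gamma, b_gamma)
    return SubpopulationParams(A=A, B=B, a=a_gamma, b=b_gamma)


@dataclass
class LocalCircuitParams:
    """Local (intra-column) connectivity.

    The four intrinsic gains are ``C1 = c1*C`` (excitatory interneurons ->
    pyramidal), ``C2 = c2*C`` (pyramidal -> excitatory interneurons),
    ``C3 = c3*C`` (pyramidal -> inhibitory interneurons) and the dynamic
    ``C4`` (inhibitory interneurons -> pyramidal feedback), initialised to
    ``C4_init``.  ``r_alpha`` in [0, 1] is the proportion of the alpha
    subpopulation in the column's output.
    """

    C: float = 135.0
    c1: float = 1.0
    c2: float = 0.8
    c3: float = 0.25
    C4_init: float | None = None  # None -> 0.25 * C
    r_alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if not 0.0 <= self.r_alpha <= 1.0:
            raise ValueError("r_alpha must lie in [0, 1]")
        if self.C4_init is None:
            self.C4_init = 0.25 * self.C
        if self.C4_init < 0:
            raise ValueError("C4_init must be >= 0")

    @property
    def C1(self) -> float:
        return self.c1 * self.C

    @property
    def C2(self) -> float:
        return self.c2 * self.C

    @property
    def C3(self) -> float:
        return self.c3 * self.C


@dataclass
class PlasticityParams:
    """Homeostatic inhibitory synaptic plasticity (ISP).

    The inhibitory-to-pyramidal gain C4 evolves as

        tau * dC4/dt = zeta_inh * (zeta_pyr - rho) * ((C4 - C4_min)/C)**beta

    so pyramidal firing is clamped to the target rate ``rho`` (Hz).
    ``tau`` is the inverse learning rate (s); ``beta`` = 1 gives the
    soft-bound rule, with ``C4_min`` the absorbing lower bound.

    The rates entering the rule are slow first-order estimates of the
    population rates (time constant ``t_avg``, default 0.5 s): the
    homeostatic sensor integrates over many oscillation cycles, which
    makes the equilibrium clamp the *time-averaged* pyramidal rate to
    rho (an instantaneous-rate rule instead clamps an
    inhibition-weighted average, which undershoots the target by tens
    of percent on large limit cycles).
    """

    enabled: bool = True
    rho: float = 2.5
    tau: float = 2.0
    beta: float = 1.0
    C4_min: float = 0.0
    t_avg: float = 0.5

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.C4_min < 0:
            raise ValueError("C4_min must be >= 0")
        if self.t_avg <= 0:
            raise ValueError("t_avg must be > 0")


@dataclass
class DriveParams:
    """Stochastic background input p(t) to each region.

    ``noise_mode`` selects how the standard deviation ``p_sd`` is applied:
    "sampled" (default) draws an i.i.d. p ~ N(p_mean, p_sd) per
    integration step, shared by both subpopulations of a region;
    "diffusion" instead injects A_s a_s p_sd sqrt(dt) N(0,1) into each
    dy1 update (the Euler-Maruyama diffusion reading, whose statistics
    are dt-invariant but whose effective per-step input fluctuation
    p_sd/sqrt(dt) is ~30x larger at dt = 1 ms and overwhelms the alpha
    rhythm).
    """

    p_mean: float = 220.0
    p_sd: float = 31.0
    noise_mode: str = "sampled"

    def __post_init__(self) -> None:
        if self.p_sd < 0:
            raise ValueError("p_sd must be >= 0")
        if self.noise_mode not in ("diffusion", "sampled"):
            raise ValueError("noise_mode must be 'diffusion' or 'sampled'")


@dataclass
class SimulationProtocol:
    """Integration and output protocol.

    dt : integration step (s); t_sim : total simulated time (s);
    t_discard : initial transient removed from outputs (s); out_fs :
    output sampling rate after anti-aliased decimation (Hz); seed : RNG
    seed; n_seeds : number of realizations in multi-seed protocols.
    """

    dt: float = 1e-3
    t_sim: float = 180.0
    t_discard: float = 60.0
    out_fs: float = 200.0
    seed: int = 0
    n_seeds: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not self.t_discard < self.t_sim:
            raise ValueError("t_discard must be < t_sim")
        if self.out_fs > 1.0 / self.dt + 1e-9:
            raise ValueError("out_fs cannot exceed the integration rate 1/dt")
        q = (1.0 / self.dt) / self.out_fs
        if abs(q - round(q)) > 1e-9:
            raise ValueError("1/(dt*out_fs) must be an integer decimation factor")

    @property
    def decimation(self) -> int:
        return int(round((1.0 / self.dt) / self.out_fs))

    @property
    def n_steps(self) -> int:
        return int(round(self.t_sim / self.dt))


@dataclass
class NodeState:
    """Dynamical state of ``n`` regions, vectorised over regions.

    Per subpopulation s in {alpha (``_a``), gamma (``_g``)}: the PSP block
    outputs ``x0_s`` (excitatory feedback), ``x1_s`` (pyramidal input),
    ``x2_s`` (inhibitory feedback) in mV with velocities ``y*_s`` (mV/s),
    plus the ISP-controlled inhibitory gain ``c4_s``.
    """

    x0_a: np.ndarray
    y0_a: np.ndarray
    x1_a: np.ndarray
    y1_a: np.ndarray
    x2_a: np.ndarray
    y2_a: np.ndarray
    x0_g: np.ndarray
    y0_g: np.ndarray
    x1_g: np.ndarray
    y1_g: np.ndarray
    x2_g: np.ndarray
    y2_g: np.ndarray
    c4_a: np.ndarray
    c4_g: np.ndarray
    zp_a: np.ndarray
    zi_a: np.ndarray
    zp_g: np.ndarray
    zi_g: np.ndarray

    _FIELDS = (
        "x0_a", "y0_a", "x1_a", "y1_a", "x2_a", "y2_a",
        "x0_g", "y0_g", "x1_g", "y1_g", "x2_g", "y2_g",
        "c4_a", "c4_g",
        "zp_a", "zi_a", "zp_g", "zi_g",
    )

    @classmethod
    def initial(cls, n: int, c4_init: float, zeta0: float = 0.0) -> "NodeState":
        """Origin start: all dynamical variables 0, C4 at its initial gain,
        rate estimates seeded at ``zeta0`` (the sigmoid output at rest)."""
        return cls(
            *(np.zeros(n) for _ in range(12)),
            c4_a=np.full(n, float(c4_init)),
            c4_g=np.full(n, float(c4_init)),
            zp_a=np.full(n, float(zeta0)), zi_a=np.full(n, float(zeta0)),
            zp_g=np.full(n, float(zeta0)), zi_g=np.full(n, float(zeta0)),
        )

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "NodeState":
        return cls(*(arr[i].copy() for i in range(18)))

    def as_array(self) -> np.ndarray:
        """Stack into a (14, n) array in canonical field order."""
        return np.stack([getattr(self, f) for f in self._FIELDS])

    @property
    def n(self) -> int:
        return self.x0_a.shape[0]

    def copy(self) -> "NodeState":
        return NodeState(*(getattr(self, f).copy() for f in self._FIELDS))
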