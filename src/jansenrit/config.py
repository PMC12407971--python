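"""Model configuration: one object bundling all parameter groups.

A flat YAML/JSON mapping with the conventional parameter names
(``A_alpha``, ``a_gamma``, ``r_alpha``, ``rho``, ``tau``, ``beta``,
``K``, ``p_mean``, ``p_sd``, ``dt``, ``t_sim``, ``t_discard``,
``out_fs``, ``seed``, ...) round-trips to a :class:`ModelConfig` plus a
:class:`~jansenrit.params.SimulationProtocol`.  Omitted keys take the
model's default operating point; ``A_gamma``/``B_gamma`` default to the
kinetics-derived formulas 32.5 a_gamma/1000 and 440 b_gamma/1000.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .params import (
    DriveParams,
    LocalCircuitParams,
    PlasticityParams,
    SigmoidParams,
    SimulationProtocol,
    SubpopulationParams,
    alpha_subpopulation,
    gamma_subpopulation,
    resolve_gamma_gains,
)

__all__ = ["ModelConfig", "config_from_dict", "config_to_dict", "load_config", "save_config"]


@dataclass
class ModelConfig:
    """All parameters of the two-subpopulation node model plus global coupling K."""

    sigmoid: SigmoidParams = field(default_factory=SigmoidParams)
    alpha: SubpopulationParams = field(default_factory=alpha_subpopulation)
    gamma: SubpopulationParams = field(default_factory=gamma_subpopulation)
    circuit: LocalCircuitParams = field(default_factory=LocalCircuitParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    drive: DriveParams = field(default_factory=DriveParams)
    K: float = 0.0

    def with_(self, **kw) -> "ModelConfig":
        """Convenience: return a copy with flat-name overrides applied."""
        d = config_to_dict(self)
        d.update(kw)
        cfg, _ = config_from_dict(d)
        return cfg

    def summary_line(self) -> str:
        d = config_to_dict(self)
        h = hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]
        return (
            f"K={self.K} r_alpha={self.circuit.r_alpha} "
            f"isp={self.plasticity.enabled} rho={self.plasticity.rho} "
            f"tau={self.plasticity.tau} config_hash={h}"
        )


def config_to_dict(cfg: ModelConfig, protocol: SimulationProtocol | None = None) -> dict:
    d = {
        "zeta_max": cfg.sigmoid.zeta_max, "r": cfg.sigmoid.r, "v_th": cfg.sigmoid.v_th,
        "A_alpha": cfg.alpha.A, "B_alpha": cfg.alpha.B,
        "a_alpha": cfg.alpha.a, "b_alpha": cfg.alpha.b,
        "A_gamma": cfg.gamma.A, "B_gamma": cfg.gamma.B,
        "a_gamma": cfg.gamma.a, "b_gamma": cfg.gamma.b,
        "C": cfg.circuit.C, "c1": cfg.circuit.c1, "c2": cfg.circuit.c2,
        "c3": cfg.circuit.c3, "C4_init": cfg.circuit.C4_init,
        "r_alpha": cfg.circuit.r_alpha,
        "isp_enabled": cfg.plasticity.enabled, "rho": cfg.plasticity.rho,
        "tau": cfg.plasticity.tau, "beta": cfg.plasticity.beta,
        "C4_min": cfg.plasticity.C4_min, "t_avg": cfg.plasticity.t_avg,
        "p_mean": cfg.drive.p_mean, "p_sd": cfg.drive.p_sd,
        "noise_mode": cfg.drive.noise_mode,
        "K": cfg.K,
    }
    if protocol is not None:
        d.update({
            "dt": protocol.dt, "t_sim": protocol.t_sim,
            "t_discard": protocol.t_discard, "out_fs": protocol.out_fs,
            "seed": protocol.seed, "n_seeds": protocol.n_seeds,
        })
    return d


_PROTOCOL_KEYS = ("dt", "t_sim", "t_discard", "out_fs", "seed", "n_seeds")


def config_from_dict(d: dict) -> tuple[ModelConfig, SimulationProtocol]:
    """Build (ModelConfig, SimulationProtocol) from a flat mapping."""
    d = dict(d)
    unknown = set(d) - set(config_to_dict(ModelConfig(), SimulationProtocol())) \
        - {"A_gamma", "B_gamma"}
    if unknown:
        raise KeyError(f"unknown configuration keys: {sorted(unknown)}")
    a_g = float(d.get("a_gamma", 660.0))
    b_g = float(d.get("b_gamma", 330.0))
    Ag_default, Bg_default = resolve_gamma_gains(a_g, b_g)
    cfg = ModelConfig(
        sigmoid=SigmoidParams(
            zeta_max=float(d.get("zeta_max", 5.0)),
            r=float(d.get("r", 0.56)),
            v_th=float(d.get("v_th", 6.0)),
        ),
        alpha=SubpopulationParams(
            A=float(d.get("A_alpha", 3.9)), B=float(d.get("B_alpha", 26.4)),
            a=float(d.get("a_alpha", 120.0)), b=float(d.get("b_alpha", 60.0)),
        ),
        gamma=SubpopulationParams(
            A=float(d.get("A_gamma", Ag_default)), B=float(d.get("B_gamma", Bg_default)),
            a=a_g, b=b_g,
        ),
        circuit=LocalCircuitParams(
            C=float(d.get("C", 135.0)), c1=float(d.get("c1", 1.0)),
            c2=float(d.get("c2", 0.8)), c3=float(d.get("c3", 0.25)),
            C4_init=(None if d.get("C4_init") is None else float(d["C4_init"])),
            r_alpha=float(d.get("r_alpha", 0.5)),
        ),
        plasticity=PlasticityParams(
            enabled=bool(d.get("isp_enabled", True)), rho=float(d.get("rho", 2.5)),
            tau=float(d.get("tau", 2.0)), beta=float(d.get("beta", 1.0)),
            C4_min=float(d.get("C4_min", 0.0)), t_avg=float(d.get("t_avg", 0.5)),
        ),
        drive=DriveParams(
            p_mean=float(d.get("p_mean", 220.0)), p_sd=float(d.get("p_sd", 31.0)),
            noise_mode=str(d.get("noise_mode", "sampled")),
        ),
        K=float(d.get("K", 0.0)),
    )
    protocol = SimulationProtocol(
        dt=float(d.get("dt", 1e-3)), t_sim=float(d.get("t_sim", 180.0)),
        t_discard=float(d.get("t_discard", 60.0)), out_fs=float(d.get("out_fs", 200.0)),
        seed=int(d.get("seed", 0)), n_seeds=int(d.get("n_seeds", 1)),
    )
    return cfg, protocol


def load_config(path) -> tuple[ModelConfig, SimulationProtocol]:
    """Read a YAML (or JSON; YAML is a superset) config file."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return config_from_dict(d)


def save_config(path, cfg: ModelConfig, protocol: SimulationProtocol | None = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg, protocol), fh, sort_keys=True)
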