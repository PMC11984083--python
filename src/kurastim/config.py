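"""YAML simulation configs: frequencies in Hz on disk, rad/s in memory."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from ._utils import TWO_PI
from .network_model import NetworkParams, StimProtocol

__all__ = ["SimConfig", "load_config", "parse_config"]


@dataclass
class SimConfig:
    params: NetworkParams
    protocol: StimProtocol | None
    dt: float
    duration: float
    seed: int | None
    measurement_noise_sd: float = 0.0
    initial_rho: float | None = None
    initial_psi: float = 0.0


def parse_config(cfg: dict) -> SimConfig:
    z_name = cfg.get("Z", "neg_sin")
    if z_name not in ("neg_sin",):
        raise ValueError(
            f"Z={z_name!r} not available from config; pass a callable in code"
        )
    params = NetworkParams(
        omega0=TWO_PI * float(cfg["omega0_hz"]),
        gamma=TWO_PI * float(cfg["gamma_hz"]),
        K=float(cfg.get("K", 0.0)),
        D=float(cfg.get("D", 0.0)),
        N=int(cfg.get("N", 200)),
    )
    protocol = None
    if "protocol" in cfg and cfg["protocol"] is not None:
        p = cfg["protocol"]
        protocol = StimProtocol(
            target_phase=np.deg2rad(float(p.get("target_phase_deg", 0.0))),
            pulse_magnitude=float(p.get("pulse_magnitude", 0.0)),
            refractory_fraction=float(p.get("refractory_fraction", 0.8)),
            block_layout=[
                (float(b["off_s"]), float(b["on_s"])) for b in p.get("blocks", [])
            ],
        )
    return SimConfig(
        params=params,
        protocol=protocol,
        dt=float(cfg.get("dt_s", 5e-4)),
        duration=float(cfg.get("duration_s", 30.0)),
        seed=cfg.get("seed"),
        measurement_noise_sd=float(cfg.get("measurement_noise_sd", 0.0)),
        initial_rho=cfg.get("initial_rho"),
        initial_psi=float(cfg.get("initial_psi", 0.0)),
    )


def load_config(path) -> SimConfig:
    with Path(path).open() as fh:
        return parse_config(yaml.safe_load(fh))
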