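"""Reduced (mean-field) dynamics of the globally coupled phase network.

In the infinite-N limit with Cauchy-distributed natural frequencies and the
default phase-response function ``Z(theta) = -sin(theta)``, the macroscopic
state collapses onto two ODEs for synchrony ``rho`` and mean phase ``psi``:

    drho/dt = -gamma*rho + (K/2)*rho*(1 - rho^2) + (I/2)*(1 - rho^2)*cos(psi)
    dpsi/dt = omega0     - (I/(2*rho))*(1 + rho^2)*sin(psi)

The last terms are the instantaneous population amplitude-response (ARC)
and phase-response (PRC) to a stimulation drive ``I``.  An impulsive pulse
contributes jumps equal to those terms with ``I`` replaced by the pulse
magnitude (the dt -> 0 limit), which keeps pulse semantics consistent with
the full model's instantaneous kicks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._utils import wrap_phase
from .network_model import RHO_FLOOR, NetworkParams, StimProtocol

__all__ = [
    "ReducedState",
    "ReducedTrajectory",
    "ZeroSynchronyError",
    "reduced_rhs",
    "instantaneous_arc",
    "instantaneous_prc",
    "amplitude_scaling",
    "steady_state_rho",
    "characteristic_curve",
    "pulse_jump",
    "integrate_reduced",
]


class ZeroSynchronyError(ValueError):
    """The PRC term is singular at rho = 0."""


@dataclass
class ReducedState:
    rho: float
    psi: float
    t: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [0, 1]")


@dataclass
class ReducedTrajectory:
    times: np.ndarray
    rho_series: np.ndarray
    psi_series: np.ndarray
    pulse_times: np.ndarray


def instantaneous_arc(rho: float, psi: float, I: float) -> float:
    """Stimulation term of the amplitude equation: ``(I/2)(1-rho^2)cos(psi)``."""
    return 0.5 * I * (1.0 - rho * rho) * math.cos(psi)


def instantaneous_prc(rho: float, psi: float, I: float) -> float:
    """Stimulation term of the phase equation: ``-(I/(2 rho))(1+rho^2)sin(psi)``."""
    if rho == 0.0:
        if I == 0.0:
            return 0.0
        raise ZeroSynchronyError("PRC term undefined at rho = 0")
    return -(I / (2.0 * rho)) * (1.0 + rho * rho) * math.sin(psi)


def reduced_rhs(state: ReducedState, params: NetworkParams, I: float = 0.0):
    """Right-hand side ``(drho/dt, dpsi/dt)`` of the reduced equations."""
    rho, psi = state.rho, state.psi
    drho = (
        -params.gamma * rho
        + 0.5 * params.K * rho * (1.0 - rho * rho)
        + instantaneous_arc(rho, psi, I)
    )
    dpsi = params.omega0 + instantaneous_prc(rho, psi, I)
    return drho, dpsi


def amplitude_scaling(rho):
    """Phase-independent scale of the pulse's amplitude effect: ``(1-rho^2)/2``.

    Strictly decreasing on [0, 1]: stimulation moves synchrony most easily
    in weakly synchronised networks.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0) or np.any(rho > 1):
        raise ValueError("rho must be in [0, 1]")
    out = 0.5 * (1.0 - rho**2)
    return float(out) if out.ndim == 0 else out


def steady_state_rho(params: NetworkParams) -> float:
    """Noise-free steady synchrony: ``sqrt(1 - 2 gamma / K)`` above onset, else 0."""
    if params.K <= 2.0 * params.gamma:
        return 0.0
    return math.sqrt(1.0 - 2.0 * params.gamma / params.K)


def characteristic_curve(params: NetworkParams, rho_grid) -> np.ndarray:
    """Unstimulated ``drho/dt`` on a synchrony grid (the network's operating curve)."""
    rho = np.asarray(rho_grid, dtype=float)
    if np.any(rho < 0) or np.any(rho > 1):
        raise ValueError("rho grid must lie in [0, 1]")
    return -params.gamma * rho + 0.5 * params.K * rho * (1.0 - rho**2)


def pulse_jump(rho: float, psi: float, magnitude: float):
    """Impulsive state change ``(d_rho, d_psi)`` of one pulse of given magnitude.

    Pulses are no-ops below the synchrony floor where the mean phase (and
    hence the PRC term) is undefined.
    """
    if rho < RHO_FLOOR:
        return 0.0, 0.0
    return (
        instantaneous_arc(rho, psi, magnitude),
        instantaneous_prc(rho, psi, magnitude),
    )


def _rk4_step(rho, psi, dt, params):
    def f(r, p):
        drho = -params.gamma * r + 0.5 * params.K * r * (1.0 - r * r)
        return drho, params.omega0

    k1r, k1p = f(rho, psi)
    k2r, k2p = f(rho + 0.5 * dt * k1r, psi + 0.5 * dt * k1p)
    k3r, k3p = f(rho + 0.5 * dt * k2r, psi + 0.5 * dt * k2p)
    k4r, k4p = f(rho + dt * k3r, psi + dt * k3p)
    return (
        rho + dt / 6.0 * (k1r + 2 * k2r + 2 * k3r + k4r),
        psi + dt / 6.0 * (k1p + 2 * k2p + 2 * k3p + k4p),
    )


def integrate_reduced(
    initial: ReducedState,
    params: NetworkParams,
    duration: float,
    dt: float = 5e-4,
    pulse_times=None,
    pulse_magnitude: float = 0.0,
    protocol: StimProtocol | None = None,
    use_refractory: bool = True,
) -> ReducedTrajectory:
    """Fixed-step (RK4) integration with impulsive pulses.

    Pulses come either from an explicit ``pulse_times`` schedule or from the
    same phase-locked trigger used by the full model (``protocol``); the
    refractory rule can be disabled for the scheduled-pulse semantics of the
    trigger via ``use_refractory``.  Synchrony is clipped to [0, 1] after
    each jump (a warning is issued if a jump overshoots by more than 1e-6).
    """
    if pulse_times is not None and protocol is not None:
        raise ValueError("give either pulse_times or protocol, not both")
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    rho = np.empty(n_steps + 1)
    psi = np.empty(n_steps + 1)
    fired = np.zeros(n_steps + 1, dtype=bool)

    scheduled = None
    magnitude = pulse_magnitude
    if pulse_times is not None:
        sched = np.atleast_1d(np.asarray(pulse_times, dtype=float))
        scheduled = np.zeros(n_steps + 1, dtype=bool)
        idx = np.clip(np.ceil(sched / dt - 1e-9).astype(int), 0, n_steps)
        scheduled[idx] = True
    if protocol is not None:
        on_mask = protocol.on_mask(n_steps, dt)
        target = protocol.target_phase
        magnitude = protocol.pulse_magnitude
        refr_s = protocol.refractory_seconds(params.omega0) if use_refractory else 0.0

    r, p = initial.rho, initial.psi
    last_pulse_t = -np.inf
    d_prev = None
    for k in range(n_steps + 1):
        rho[k], psi[k] = r, p
        t = times[k]
        fire = False
        if scheduled is not None:
            fire = bool(scheduled[k])
            mag = magnitude
        elif protocol is not None:
            d = float(wrap_phase(p - target))
            if (
                d_prev is not None
                and on_mask[k]
                and r >= RHO_FLOOR
                and d_prev < 0.0 <= d
                and (d - d_prev) < np.pi
                and (t - last_pulse_t) > refr_s
            ):
                fire = True
                last_pulse_t = t
            d_prev = d
            mag = magnitude
        if fire:
            d_rho, d_psi = pulse_jump(r, p, mag)
            r, p = r + d_rho, p + d_psi
            if r > 1.0 + 1e-6 or r < -1e-6:
                warnings.warn(f"pulse jump left [0,1]: rho={r:.6g}", stacklevel=2)
            r = min(max(r, 0.0), 1.0)
            fired[k] = True
        if k < n_steps:
            r, p = _rk4_step(r, p, dt, params)
            r = min(max(r, 0.0), 1.0)
    return ReducedTrajectory(times, rho, psi, times[fired])
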