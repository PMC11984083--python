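"""Finite-N stochastic Kuramoto network with phase-locked pulsatile stimulation.

The network is the classic globally coupled phase-oscillator system with
independent white noise on every oscillator and an additive pulsatile input
acting through a per-oscillator phase-response function ``Z`` (default
``Z(theta) = -sin(theta)``):

    dtheta_i = [omega_i + (K/N) sum_j sin(theta_j - theta_i)] dt
               + sqrt(2 D dt) eta_i + I_pulse * Z(theta_i) at pulse times

Natural frequencies are Cauchy distributed.  Macroscopic state is summarised
by the order parameter ``rho * exp(i * psi)`` and pulses are triggered when
the mean phase ``psi`` crosses a target phase, subject to a refractory
period expressed as a fraction of the mean-frequency cycle.

Integration uses Euler-Maruyama at a fixed step (default 0.5 ms).  The
all-to-all coupling sum is evaluated through the exact identity
``(K/N) sum_j sin(theta_j - theta_i) = K rho sin(psi - theta_i)`` which makes
each step O(N); a numba-compiled kernel is used for the default ``Z``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from ._utils import TWO_PI, spawn_seeds, wrap_phase

__all__ = [
    "NetworkParams",
    "PhaseState",
    "OrderParameter",
    "StimProtocol",
    "Trajectory",
    "neg_sin",
    "sample_natural_frequencies",
    "wrapped_cauchy_phases",
    "order_parameter",
    "step",
    "PhaseLockedController",
    "pulse_decisions",
    "simulate",
    "network_signal",
]

#: synchrony below which the mean phase is meaningless and pulses are held
RHO_FLOOR = 1e-6


def neg_sin(theta):
    """Default per-oscillator phase-response function ``Z(theta) = -sin(theta)``."""
    return -np.sin(theta)


@dataclass(frozen=True)
class NetworkParams:
    """Parameter set of the full network.

    Attributes
    ----------
    omega0 : float
        Mean natural frequency in rad/s.
    gamma : float
        Half-width of the Cauchy natural-frequency distribution (rad/s).
    K : float
        Global coupling constant (rad/s).
    D : float
        Noise intensity (rad^2/s); the per-step Brownian increment has
        variance ``2 * D * dt``.
    N : int
        Number of oscillators.
    Z : callable, optional
        2*pi-periodic phase-response function; ``None`` selects
        ``-sin(theta)``.
    """

    omega0: float
    gamma: float
    K: float
    D: float
    N: int
    Z: Callable | None = None

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if int(self.N) < 1:
            raise ValueError("N must be >= 1")
        if self.Z is not None:
            grid = np.linspace(-np.pi, np.pi, 17)
            if not np.allclose(self.Z(grid), self.Z(grid + TWO_PI), atol=1e-9):
                raise ValueError("Z must be 2*pi-periodic")

    @property
    def z_func(self) -> Callable:
        return self.Z if self.Z is not None else neg_sin

    @property
    def uses_default_z(self) -> bool:
        return self.Z is None or self.Z is neg_sin


@dataclass
class PhaseState:
    """Phases of all oscillators at one instant (phases kept unwrapped)."""

    theta: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.t < 0:
            raise ValueError("t must be >= 0")

    @property
    def wrapped(self) -> np.ndarray:
        return wrap_phase(self.theta)


class OrderParameter(NamedTuple):
    rho: float
    psi: float


@dataclass(frozen=True)
class StimProtocol:
    """Closed-loop stimulation settings.

    ``block_layout`` is an ordered list of ``(off_s, on_s)`` pairs; pulses
    may only be delivered during the on-epochs.  ``pulse_magnitude`` is the
    instantaneous kick strength ``I_pulse`` applied as
    ``dtheta_i = I_pulse * Z(theta_i)``.
    """

    target_phase: float
    pulse_magnitude: float
    refractory_fraction: float = 0.8
    block_layout: tuple = ()

    def __post_init__(self):
        if not (0 <= self.refractory_fraction < 1):
            raise ValueError("refractory_fraction must be in [0, 1)")
        if self.pulse_magnitude < 0:
            raise ValueError("pulse_magnitude must be >= 0")
        layout = tuple((float(a), float(b)) for a, b in self.block_layout)
        for off_s, on_s in layout:
            if off_s <= 0 or on_s <= 0:
                raise ValueError("block durations must be > 0")
        object.__setattr__(self, "block_layout", layout)
        object.__setattr__(self, "target_phase", float(wrap_phase(self.target_phase)))

    def refractory_seconds(self, omega0: float) -> float:
        return self.refractory_fraction * TWO_PI / omega0

    def epochs(self, duration: float) -> list[tuple[str, float, float]]:
        """Expand the block layout into labeled ``(label, start, stop)`` intervals."""
        out = []
        t = 0.0
        for off_s, on_s in self.block_layout:
            out.append(("off", t, min(t + off_s, duration)))
            t += off_s
            if t >= duration:
                break
            out.append(("on", t, min(t + on_s, duration)))
            t += on_s
            if t >= duration:
                break
        if t < duration:
            out.append(("off", t, duration))
        return [(lbl, a, b) for lbl, a, b in out if b > a]

    def on_mask(self, n_steps: int, dt: float) -> np.ndarray:
        """Boolean per-sample mask (length ``n_steps + 1``) of the on-epochs."""
        mask = np.zeros(n_steps + 1, dtype=bool)
        t = np.arange(n_steps + 1) * dt
        for lbl, a, b in self.epochs((n_steps + 1) * dt):
            if lbl == "on":
                mask |= (t >= a) & (t < b)
        return mask


@dataclass
class Trajectory:
    """Recorded macroscopic output of a simulation run."""

    times: np.ndarray
    rho_series: np.ndarray
    psi_series: np.ndarray
    pulse_times: np.ndarray
    signal: np.ndarray
    dt: float = 0.0
    theta_final: np.ndarray | None = None
    theta_series: np.ndarray | None = None
    seeds: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def sample_natural_frequencies(
    params: NetworkParams, seed: int | None = None, method: str = "random"
) -> np.ndarray:
    """Draw the N natural frequencies from ``Cauchy(omega0, gamma)``.

    ``method='quantile'`` places the draws at the mid-point quantiles of the
    distribution (deterministic, useful for matching the mean-field limit at
    moderate N); ``'random'`` is an i.i.d. draw.
    """
    if params.gamma == 0:
        return np.full(params.N, params.omega0)
    if method == "quantile":
        u = (np.arange(params.N) + 0.5) / params.N
        return stats.cauchy.ppf(u, loc=params.omega0, scale=params.gamma)
    if method != "random":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    return stats.cauchy.rvs(
        loc=params.omega0, scale=params.gamma, size=params.N, random_state=rng
    )


def wrapped_cauchy_phases(
    rho0: float, psi0: float, n: int, seed: int | None = None, method: str = "quantile"
) -> np.ndarray:
    """Sample N phases whose population order parameter is ``rho0 e^{i psi0}``.

    The phases follow a wrapped-Cauchy density with mean resultant length
    ``rho0`` — the distribution family preserved by the mean-field dynamics —
    so a network initialised this way starts on the manifold described by the
    reduced model.
    """
    if not 0 <= rho0 < 1:
        raise ValueError("rho0 must be in [0, 1)")
    if method == "quantile":
        u = (np.arange(n) + 0.5) / n
    else:
        u = np.random.default_rng(seed).random(n)
    if rho0 == 0:
        return wrap_phase(-np.pi + TWO_PI * u + psi0)
    theta = stats.wrapcauchy.ppf(u, c=rho0)  # support [0, 2*pi), centred at 0
    return wrap_phase(theta + psi0)


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def order_parameter(theta: np.ndarray) -> OrderParameter:
    """Complex mean of the unit phase vectors, as ``(rho, psi)``.

    ``psi`` is reported as 0 when ``rho`` is numerically zero (the mean phase
    of an incoherent population is undefined).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size == 0:
        raise ValueError("order_parameter of an empty phase vector")
    z = np.exp(1j * theta).mean()
    rho = abs(z)
    psi = float(np.angle(z)) if rho >= 1e-12 else 0.0
    return OrderParameter(float(rho), psi)


def step(
    state: PhaseState,
    params: NetworkParams,
    dt: float,
    kick: bool = False,
    rng: np.random.Generator | None = None,
    omega: np.ndarray | None = None,
    pulse_magnitude: float = 0.0,
) -> PhaseState:
    """One Euler-Maruyama step of the full model.

    ``omega`` holds the per-oscillator natural frequencies; if omitted all
    oscillators run at ``params.omega0``.  When ``kick`` is set the pulse
    term ``pulse_magnitude * Z(theta)`` is added within the step.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    theta = state.theta
    if omega is None:
        omega = np.full(theta.size, params.omega0)
    rho, psi = order_parameter(theta)
    drift = omega + params.K * rho * np.sin(psi - theta)
    new = theta + dt * drift
    if params.D > 0:
        if rng is None:
            rng = np.random.default_rng()
        new = new + math.sqrt(2.0 * params.D * dt) * rng.standard_normal(theta.size)
    if kick:
        new = new + pulse_magnitude * params.z_func(theta)
    return PhaseState(new, state.t + dt)


class PhaseLockedController:
    """Stateful pulse trigger: fire on upward crossings of the target phase.

    A pulse is emitted at the first sample past a crossing of
    ``wrap(psi - target)`` through zero in the direction of phase increase,
    provided the sample lies in an on-epoch, more than
    ``refractory_fraction * (2 pi / omega0)`` seconds have elapsed since the
    previous pulse, and the synchrony is above ``RHO_FLOOR``.
    """

    def __init__(self, protocol: StimProtocol, params: NetworkParams):
        self.protocol = protocol
        self.refractory_s = protocol.refractory_seconds(params.omega0)
        self.last_pulse_t = -np.inf
        self._d_prev: float | None = None

    def update(self, t: float, psi: float, rho: float, stim_on: bool) -> bool:
        d = float(wrap_phase(psi - self.protocol.target_phase))
        d_prev, self._d_prev = self._d_prev, d
        if d_prev is None or not stim_on or rho < RHO_FLOOR:
            return False
        crossed = d_prev < 0.0 <= d and (d - d_prev) < np.pi
        if crossed and (t - self.last_pulse_t) > self.refractory_s:
            self.last_pulse_t = t
            return True
        return False


def pulse_decisions(
    times: np.ndarray,
    psi: np.ndarray,
    protocol: StimProtocol,
    params: NetworkParams,
    rho: np.ndarray | None = None,
    stim_on: np.ndarray | None = None,
) -> np.ndarray:
    """Vector version of the controller, for a precomputed mean-phase series."""
    times = np.asarray(times, float)
    psi = np.asarray(psi, float)
    if rho is None:
        rho = np.ones_like(psi)
    if stim_on is None:
        stim_on = np.ones(psi.shape, dtype=bool)
    ctrl = PhaseLockedController(protocol, params)
    out = np.zeros(psi.shape, dtype=bool)
    for k, (t, p, r, on) in enumerate(zip(times, psi, rho, stim_on)):
        out[k] = ctrl.update(t, p, r, bool(on))
    return out


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

_NUMBA_KERNEL = None


def _get_kernel():
    global _NUMBA_KERNEL
    if _NUMBA_KERNEL is None:
        from ._kernels import simulate_negsin

        _NUMBA_KERNEL = simulate_negsin
    return _NUMBA_KERNEL


def simulate(
    params: NetworkParams,
    protocol: StimProtocol | None = None,
    duration: float = 30.0,
    dt: float = 5e-4,
    seed: int | None = None,
    initial_theta: np.ndarray | None = None,
    omega: np.ndarray | None = None,
    measurement_noise_sd: float = 0.0,
    frequency_sampling: str = "random",
    store_theta: bool = False,
) -> Trajectory:
    """Integrate the full network and record ``(rho, psi)``, pulses and signal.

    The observation ``signal`` is ``rho * cos(psi)`` plus optional white
    measurement noise.  Reproducible: all randomness (frequency draw,
    dynamics noise, measurement noise) derives from ``seed``.
    """
    if duration < dt:
        raise ValueError("duration must be >= dt")
    n_steps = int(round(duration / dt))
    freq_seed, dyn_seed, init_seed, meas_seed = spawn_seeds(seed, 4)
    if omega is None:
        omega = sample_natural_frequencies(params, seed=freq_seed, method=frequency_sampling)
    omega = np.asarray(omega, dtype=float)
    if initial_theta is None:
        theta0 = np.random.default_rng(init_seed).uniform(-np.pi, np.pi, params.N)
    else:
        theta0 = np.asarray(initial_theta, dtype=float).copy()
    if theta0.size != params.N or omega.size != params.N:
        raise ValueError("initial_theta/omega must have length N")

    if protocol is None:
        on_mask = np.zeros(n_steps + 1, dtype=bool)
        target, i_pulse, refr_s = 0.0, 0.0, np.inf
    else:
        on_mask = protocol.on_mask(n_steps, dt)
        target = protocol.target_phase
        i_pulse = protocol.pulse_magnitude
        refr_s = protocol.refractory_seconds(params.omega0)

    if params.uses_default_z and not store_theta:
        kernel = _get_kernel()
        # pre-scaled Brownian increments from the fast numpy generator when
        # the array fits comfortably in memory; otherwise the kernel draws
        # its own noise per step
        if params.D > 0 and params.N * n_steps <= 50_000_000:
            noise = np.random.default_rng(dyn_seed).standard_normal(
                (n_steps, params.N)
            )
            noise *= math.sqrt(2.0 * params.D * dt)
        else:
            noise = np.empty((0, 0))
        rho, psi, pulse_flags, theta_final = kernel(
            theta0,
            omega,
            params.K,
            params.D,
            dt,
            n_steps,
            on_mask.astype(np.uint8),
            target,
            i_pulse,
            refr_s,
            np.uint64(dyn_seed % (2**32)),
            noise,
        )
        theta_series = None
    else:
        rho, psi, pulse_flags, theta_final, theta_series = _simulate_python(
            theta0, omega, params, dt, n_steps, on_mask, target, i_pulse, refr_s,
            dyn_seed, store_theta,
        )

    times = np.arange(n_steps + 1) * dt
    signal = rho * np.cos(psi)
    if measurement_noise_sd > 0:
        signal = signal + measurement_noise_sd * np.random.default_rng(
            meas_seed
        ).standard_normal(signal.size)
    return Trajectory(
        times=times,
        rho_series=rho,
        psi_series=psi,
        pulse_times=times[pulse_flags.astype(bool)],
        signal=signal,
        dt=dt,
        theta_final=theta_final,
        theta_series=theta_series,
        seeds={
            "master": seed,
            "frequencies": freq_seed,
            "dynamics": dyn_seed,
            "initial_phases": init_seed,
            "measurement": meas_seed,
        },
    )


def _simulate_python(
    theta0, omega, params, dt, n_steps, on_mask, target, i_pulse, refr_s,
    dyn_seed, store_theta,
):
    """Pure-numpy reference path (pluggable Z, optional full theta storage)."""
    rng = np.random.default_rng(dyn_seed)
    z_func = params.z_func
    theta = theta0.copy()
    n = theta.size
    rho = np.empty(n_steps + 1)
    psi = np.empty(n_steps + 1)
    pulse_flags = np.zeros(n_steps + 1, dtype=bool)
    theta_series = np.empty((n_steps + 1, n)) if store_theta else None
    noise_scale = math.sqrt(2.0 * params.D * dt)
    last_pulse_t = -np.inf
    d_prev = None
    for k in range(n_steps + 1):
        z = np.exp(1j * theta).mean()
        r, p = abs(z), (float(np.angle(z)) if abs(z) >= 1e-12 else 0.0)
        rho[k], psi[k] = r, p
        if store_theta:
            theta_series[k] = theta
        t = k * dt
        d = float(wrap_phase(p - target))
        if (
            d_prev is not None
            and on_mask[k]
            and r >= RHO_FLOOR
            and d_prev < 0.0 <= d
            and (d - d_prev) < np.pi
            and (t - last_pulse_t) > refr_s
        ):
            pulse_flags[k] = True
            last_pulse_t = t
            theta = theta + i_pulse * z_func(theta)
        d_prev = d
        if k < n_steps:
            z2 = np.exp(1j * theta).mean()
            r2, p2 = abs(z2), float(np.angle(z2)) if abs(z2) >= 1e-12 else 0.0
            # same expansion as the compiled kernel for bit-level parity
            drift = omega + params.K * r2 * (
                np.sin(p2) * np.cos(theta) - np.cos(p2) * np.sin(theta)
            )
            theta = theta + dt * drift
            if params.D > 0:
                theta = theta + noise_scale * rng.standard_normal(n)
    return rho, psi, pulse_flags, theta, theta_series


def network_signal(
    trajectory: Trajectory,
    measurement_noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Observation model ``x(t) = rho(t) * cos(psi(t))`` (+ optional noise)."""
    x = trajectory.rho_series * np.cos(trajectory.psi_series)
    if measurement_noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + measurement_noise_sd * rng.standard_normal(x.size)
    return x
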