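"""Hodgkin-Huxley single-neuron demo of a biphasic (type II) phase response.

Classic squid-axon conductances and rate functions, integrated with forward
Euler at 0.01 ms.  A constant drive (default 10 uA/cm^2, chosen to give
steady repetitive spiking; the tonic rate is ~68 Hz) puts the neuron on a
limit cycle, and a brief square current pulse (50 us) probes the phase
response: pulses shortly after a spike delay the next spike, pulses late in
the cycle advance it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["HHState", "simulate_hh", "empirical_prc"]

# squid-axon parameter set (mV, ms, mS/cm^2, uF/cm^2)
C_M = 1.0
G_NA, G_K, G_L = 120.0, 36.0, 0.3
E_NA, E_K, E_L = 50.0, -77.0, -54.387

SPIKE_THRESHOLD_MV = 0.0


@dataclass
class HHState:
    V: float
    m: float
    h: float
    n: float
    t: float = 0.0

    def __post_init__(self):
        for g in (self.m, self.h, self.n):
            if not 0.0 <= g <= 1.0:
                raise ValueError("gating variables must lie in [0, 1]")


def _alpha_m(v):
    return 0.1 * (v + 40.0) / (1.0 - math.exp(-(v + 40.0) / 10.0))


def _beta_m(v):
    return 4.0 * math.exp(-(v + 65.0) / 18.0)


def _alpha_h(v):
    return 0.07 * math.exp(-(v + 65.0) / 20.0)


def _beta_h(v):
    return 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))


def _alpha_n(v):
    return 0.01 * (v + 55.0) / (1.0 - math.exp(-(v + 55.0) / 10.0))


def _beta_n(v):
    return 0.125 * math.exp(-(v + 65.0) / 80.0)


def resting_state(v0: float = -65.0) -> HHState:
    """Gating variables at their steady state for the given potential."""
    m = _alpha_m(v0) / (_alpha_m(v0) + _beta_m(v0))
    h = _alpha_h(v0) / (_alpha_h(v0) + _beta_h(v0))
    n = _alpha_n(v0) / (_alpha_n(v0) + _beta_n(v0))
    return HHState(v0, m, h, n)


def simulate_hh(
    i_drive: float = 10.0,
    duration_ms: float = 200.0,
    dt_ms: float = 0.01,
    pulse_time_ms: float | None = None,
    pulse_amp: float = 0.0,
    pulse_width_ms: float = 0.05,
    initial: HHState | None = None,
    record: bool = False,
):
    """Forward-Euler integration; returns spike times (0 mV upward crossings).

    ``pulse_time_ms`` schedules one square current pulse of ``pulse_amp``
    (uA/cm^2) lasting ``pulse_width_ms``.  With ``record=True`` the voltage
    trace is returned as well.
    """
    state = initial or resting_state()
    v, m, h, n = state.V, state.m, state.h, state.n
    n_steps = int(round(duration_ms / dt_ms))
    spikes = []
    trace = {key: np.empty(n_steps + 1) for key in "Vmhn"} if record else None
    v_prev = v
    for k in range(n_steps + 1):
        if record:
            trace["V"][k], trace["m"][k], trace["h"][k], trace["n"][k] = v, m, h, n
        t = k * dt_ms
        if k > 0 and v_prev < SPIKE_THRESHOLD_MV <= v:
            spikes.append(t)
        if k == n_steps:
            break
        i_ext = i_drive
        if (
            pulse_time_ms is not None
            and pulse_time_ms <= t < pulse_time_ms + pulse_width_ms
        ):
            i_ext += pulse_amp
        i_na = G_NA * m**3 * h * (v - E_NA)
        i_k = G_K * n**4 * (v - E_K)
        i_l = G_L * (v - E_L)
        dv = (i_ext - i_na - i_k - i_l) / C_M
        dm = _alpha_m(v) * (1.0 - m) - _beta_m(v) * m
        dh = _alpha_h(v) * (1.0 - h) - _beta_h(v) * h
        dn = _alpha_n(v) * (1.0 - n) - _beta_n(v) * n
        v_prev = v
        v += dt_ms * dv
        m = min(max(m + dt_ms * dm, 0.0), 1.0)
        h = min(max(h + dt_ms * dh, 0.0), 1.0)
        n = min(max(n + dt_ms * dn, 0.0), 1.0)
    if not spikes:
        warnings.warn("no spikes: drive below the repetitive-spiking regime",
                      stacklevel=2)
    spikes = np.asarray(spikes)
    return (spikes, trace) if record else spikes


def empirical_prc(
    n_phases: int = 16,
    pulse_amp: float = 200.0,
    i_drive: float = 10.0,
    dt_ms: float = 0.01,
    pulse_width_ms: float = 0.05,
    reference_spike: int = 5,
):
    """Probe the phase response on a grid of stimulation phases.

    For each phase the pulse is delivered at that fraction of the cycle
    after a reference spike of the unperturbed run; the shift is
    ``(unperturbed next-spike time - perturbed) / period * 2 pi`` so
    positive values are phase advances.
    """
    if n_phases < 16:
        raise ValueError("need at least 16 grid phases")
    base = simulate_hh(i_drive=i_drive, dt_ms=dt_ms)
    if base.size < reference_spike + 3:
        raise ValueError("drive gives too few spikes for a PRC probe")
    t_ref = base[reference_spike]
    period = float(np.mean(np.diff(base[reference_spike:])))
    t_next_unpert = base[reference_spike + 1]
    phases = 2 * np.pi * (np.arange(n_phases) + 0.5) / n_phases
    shifts = np.empty(n_phases)
    for j, phi in enumerate(phases):
        t_pulse = t_ref + phi / (2 * np.pi) * period
        pert = simulate_hh(
            i_drive=i_drive,
            dt_ms=dt_ms,
            pulse_time_ms=t_pulse,
            pulse_amp=pulse_amp,
            pulse_width_ms=pulse_width_ms,
        )
        after = pert[pert > t_ref + 1e-9]
        t_next_pert = after[0]
        shifts[j] = (t_next_unpert - t_next_pert) / period * 2 * np.pi
    return phases, shifts
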