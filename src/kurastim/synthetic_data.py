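"""Generators for every input the pipeline needs, with stored ground truth.

Three kinds of synthetic inputs:

* ``generate_recording`` — an unstimulated network run observed through the
  ``rho * cos(psi)`` observation model (ECoG-like narrowband trace).
* ``generate_trial_set`` — a full phase-locked experiment: one trial per
  target phase (default eight), each a sequence of off/on blocks driven by
  the actual closed-loop controller, with pulse times and epochs annotated.
* ``make_constructed_signal`` — a sinusoid with exactly known per-pulse
  phase jumps and envelope steps, for validating the block estimators
  against analytic truth.

Every generator returns a :class:`GroundTruth` sidecar holding the
parameters, protocol and seeds needed to regenerate the dataset bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import TWO_PI, spawn_seeds
from .network_model import NetworkParams, StimProtocol, simulate
from .signal_processing import Epoch, Recording

__all__ = [
    "GroundTruth",
    "generate_recording",
    "generate_trial_set",
    "make_constructed_signal",
    "target_phase_grid",
    "amplitude_dependence_experiment",
    "save_ground_truth",
    "load_ground_truth",
]


@dataclass
class GroundTruth:
    """Everything needed to regenerate a dataset and validate estimators on it."""

    kind: str
    params: dict | None = None
    protocol: dict | None = None
    mean_rho: float | None = None
    injected_prc: float | None = None
    injected_arc: list | None = None
    seeds: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


def target_phase_grid(n: int = 8) -> np.ndarray:
    """``n`` equally spaced target phases in [-pi, pi)."""
    return -np.pi + TWO_PI * np.arange(n) / n


def _params_dict(params: NetworkParams) -> dict:
    return {
        "omega0": params.omega0,
        "gamma": params.gamma,
        "K": params.K,
        "D": params.D,
        "N": params.N,
    }


def _protocol_dict(protocol: StimProtocol) -> dict:
    return {
        "target_phase": protocol.target_phase,
        "pulse_magnitude": protocol.pulse_magnitude,
        "refractory_fraction": protocol.refractory_fraction,
        "block_layout": list(protocol.block_layout),
    }


def generate_recording(
    params: NetworkParams,
    duration: float = 30.0,
    fs: float = 2000.0,
    measurement_noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[Recording, GroundTruth]:
    """Unstimulated network recording through the observation model."""
    dt = 1.0 / fs
    traj = simulate(
        params,
        protocol=None,
        duration=duration,
        dt=dt,
        seed=seed,
        measurement_noise_sd=measurement_noise_sd,
    )
    rec = Recording(samples=traj.signal, fs=fs)
    gt = GroundTruth(
        kind="recording",
        params=_params_dict(params),
        mean_rho=float(traj.rho_series[int(1.0 / dt):].mean()),
        seeds={"master": seed, **traj.seeds},
        extra={"duration": duration, "fs": fs,
               "measurement_noise_sd": measurement_noise_sd},
    )
    return rec, gt


def generate_trial_set(
    params: NetworkParams,
    pulse_magnitude: float,
    n_blocks: int = 12,
    n_phases: int = 8,
    off_s: float = 5.0,
    on_s: float = 20.0,
    refractory_fraction: float = 0.8,
    tail_s: float = 1.0,
    measurement_noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[list[tuple[Recording, GroundTruth]], np.ndarray]:
    """One closed-loop trial per target phase, run through the network controller.

    Each trial is ``n_blocks`` repetitions of ``off_s`` seconds off followed
    by ``on_s`` seconds of phase-locked stimulation, plus a short tail so the
    final on-epoch is clear of Hilbert edge trimming.
    """
    if not (10 <= n_blocks <= 14):
        raise ValueError("n_blocks must be within [10, 14]")
    phases = target_phase_grid(n_phases)
    trial_seeds = spawn_seeds(seed, n_phases)
    duration = n_blocks * (off_s + on_s) + tail_s
    out = []
    for phase, tseed in zip(phases, trial_seeds):
        protocol = StimProtocol(
            target_phase=float(phase),
            pulse_magnitude=pulse_magnitude,
            refractory_fraction=refractory_fraction,
            block_layout=[(off_s, on_s)] * n_blocks,
        )
        traj = simulate(
            params,
            protocol=protocol,
            duration=duration,
            dt=5e-4,
            seed=tseed,
            measurement_noise_sd=measurement_noise_sd,
        )
        epochs = tuple(
            Epoch(lbl, a, b, target_phase=float(phase) if lbl == "on" else None)
            for lbl, a, b in protocol.epochs(duration)
        )
        rec = Recording(
            samples=traj.signal,
            fs=1.0 / traj.dt,
            pulse_times=traj.pulse_times,
            epochs=epochs,
        )
        gt = GroundTruth(
            kind="trial",
            params=_params_dict(params),
            protocol=_protocol_dict(protocol),
            mean_rho=float(traj.rho_series.mean()),
            seeds={"master": seed, "trial": tseed, **traj.seeds},
            extra={"duration": duration, "n_blocks": n_blocks,
                   "measurement_noise_sd": measurement_noise_sd},
        )
        out.append((rec, gt))
    return out, phases


def make_constructed_signal(
    base_freq: float = 27.0,
    base_amplitude: float = 1.0,
    phase_jump: float = 0.0,
    amp_step: float = 0.0,
    n_blocks: int = 4,
    off_s: float = 5.0,
    on_s: float = 20.0,
    pulses_per_on: int = 30,
    fs: float = 2000.0,
    noise_sd: float = 0.0,
    tail_s: float = 1.0,
    seed: int | None = None,
) -> tuple[Recording, GroundTruth]:
    """Sinusoid with exactly known per-pulse phase jumps and envelope steps.

    The unwrapped phase gains ``phase_jump`` at each pulse (positive =
    advance) and the envelope gains ``amp_step`` at each pulse, resetting to
    ``base_amplitude`` at the start of every off-epoch.  The analytic
    per-block ARC implied by the construction is stored in the ground truth.
    """
    duration = n_blocks * (off_s + on_s) + tail_s
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs

    layout = [(off_s, on_s)] * n_blocks
    protocol = StimProtocol(
        target_phase=0.0, pulse_magnitude=0.0, block_layout=layout
    )
    epochs_raw = protocol.epochs(duration)

    pulse_times = []
    for lbl, a, b in epochs_raw:
        if lbl != "on":
            continue
        # pulses spread uniformly through the on-epoch interior
        pulse_times.extend(a + (b - a) * (np.arange(pulses_per_on) + 0.5) / pulses_per_on)
    pulse_times = np.array(pulse_times)

    phase = TWO_PI * base_freq * t
    for tp in pulse_times:
        phase[int(np.ceil(tp * fs)):] += phase_jump

    # envelope: chronological event walk (pulse steps accumulate, off-epoch
    # starts reset to the baseline)
    events = [(int(np.ceil(tp * fs)), "pulse") for tp in pulse_times]
    events += [
        (int(np.ceil(a * fs)), "reset") for lbl, a, b in epochs_raw if lbl == "off"
    ]
    events.sort()
    env = np.empty(n)
    level, prev = base_amplitude, 0
    for k, kind in events:
        env[prev:k] = level
        level = base_amplitude if kind == "reset" else level + amp_step
        prev = k
    env[prev:] = level

    x = env * np.cos(phase)
    if noise_sd > 0:
        x = x + noise_sd * np.random.default_rng(seed).standard_normal(n)

    epochs = tuple(
        Epoch(lbl, a, b, target_phase=0.0 if lbl == "on" else None)
        for lbl, a, b in epochs_raw
    )
    rec = Recording(samples=x, fs=fs, pulse_times=pulse_times, epochs=epochs)

    injected_arc = []
    for (off_lbl, oa, ob), (on_lbl, na, nb) in zip(epochs_raw, epochs_raw[1:]):
        if off_lbl == "off" and on_lbl == "on":
            i0, i1 = int(np.ceil(oa * fs)), int(np.floor(ob * fs))
            j0, j1 = int(np.ceil(na * fs)), int(np.floor(nb * fs))
            injected_arc.append(float(env[j0:j1].mean() - env[i0:i1].mean()))
    gt = GroundTruth(
        kind="constructed",
        injected_prc=phase_jump,
        injected_arc=injected_arc,
        seeds={"master": seed},
        extra={
            "base_freq": base_freq,
            "base_amplitude": base_amplitude,
            "phase_jump": phase_jump,
            "amp_step": amp_step,
            "n_blocks": n_blocks,
            "off_s": off_s,
            "on_s": on_s,
            "pulses_per_on": pulses_per_on,
            "fs": fs,
            "noise_sd": noise_sd,
            "tail_s": tail_s,
        },
    )
    return rec, gt


def amplitude_dependence_experiment(
    coupling_ratios=(0.5, 1.5, 2.4, 3.2, 4.5, 8.0, 16.0),
    omega0: float = TWO_PI * 27.0,
    gamma: float = TWO_PI * 1.0,
    D: float = 3.0,
    N: int = 200,
    pulse_magnitude: float = 0.3,
    n_blocks: int = 10,
    off_s: float = 5.0,
    on_s: float = 20.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Block amplitude change versus operating synchrony, in the full model.

    For each coupling level (``K = ratio * gamma``) three conditions are
    simulated with matched seeds — no stimulation, most amplifying phase
    (target 0) and most suppressive phase (target pi) — and the per-block
    change in synchrony (on-epoch mean minus preceding off-epoch mean) is
    tabulated against the pre-stimulation level.
    """
    rows = []
    level_seeds = spawn_seeds(seed, len(coupling_ratios))
    duration = n_blocks * (off_s + on_s) + 1.0
    layout = [(off_s, on_s)] * n_blocks
    conditions = {"reference": None, "amplifying": 0.0, "suppressive": np.pi}
    for ratio, lseed in zip(coupling_ratios, level_seeds):
        params = NetworkParams(omega0=omega0, gamma=gamma, K=ratio * gamma, D=D, N=N)
        for cond, target in conditions.items():
            protocol = None
            if target is not None:
                protocol = StimProtocol(
                    target_phase=target,
                    pulse_magnitude=pulse_magnitude,
                    block_layout=layout,
                )
            traj = simulate(
                params, protocol=protocol, duration=duration, dt=5e-4, seed=lseed
            )
            ref_protocol = StimProtocol(
                target_phase=0.0, pulse_magnitude=0.0, block_layout=layout
            )
            fs = 1.0 / traj.dt
            for b, (lbl_pair) in enumerate(_block_pairs(ref_protocol.epochs(duration))):
                (oa, ob), (na, nb) = lbl_pair
                i0, i1 = int(np.ceil(oa * fs)), int(np.floor(ob * fs))
                j0, j1 = int(np.ceil(na * fs)), int(np.floor(nb * fs))
                pre = float(traj.rho_series[i0:i1].mean())
                on = float(traj.rho_series[j0:j1].mean())
                rows.append(
                    {
                        "coupling_ratio": ratio,
                        "K": params.K,
                        "condition": cond,
                        "block": b,
                        "pre_amp": pre,
                        "arc_value": on - pre,
                    }
                )
    return pd.DataFrame(rows)


def _block_pairs(epochs):
    prev = None
    for lbl, a, b in epochs:
        if lbl == "off":
            prev = (a, b)
        elif prev is not None:
            yield prev, (a, b)
            prev = None


# ---------------------------------------------------------------------------
# ground-truth sidecar I/O
# ---------------------------------------------------------------------------

def save_ground_truth(gt: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(asdict(gt), indent=2, sort_keys=True))


def load_ground_truth(path) -> GroundTruth:
    return GroundTruth(**json.loads(Path(path).read_text()))
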