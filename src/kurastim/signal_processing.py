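"""ECoG-style conditioning chain and the dynamic features used for fitting.

Chain: pulse-artifact interpolation (1.5 ms post-pulse windows) ->
anti-aliased downsampling to 2 kHz -> zero-phase 4th-order Butterworth
bandpass -> Hilbert envelope and phase.  The three "dynamic features" of a
conditioned signal are the Welch PSD of the (z-scored) signal, the
probability density of the Hilbert envelope, and the Welch PSD of the
mean-removed envelope.

Filtering is applied forward-backward (zero phase) so Hilbert phases carry
no group-delay bias; the effective magnitude order is therefore doubled.
The first and last 0.5 s of envelope/phase are excluded from downstream
estimators to avoid Hilbert edge effects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "Epoch",
    "Recording",
    "AnalyticBand",
    "DynamicFeatures",
    "remove_artifacts",
    "downsample",
    "bandpass",
    "analytic",
    "dynamic_features",
    "save_recording",
    "load_recording",
]

#: seconds trimmed from each end of envelope/phase before estimation
EDGE_TRIM_S = 0.5
#: default number of envelope-PDF bins
N_ENV_BINS = 64


@dataclass(frozen=True)
class Epoch:
    label: str  # "off" | "on"
    start: float
    stop: float
    target_phase: float | None = None

    def __post_init__(self):
        if self.label not in ("off", "on"):
            raise ValueError("epoch label must be 'off' or 'on'")
        if self.stop <= self.start:
            raise ValueError("epoch stop must exceed start")


@dataclass
class Recording:
    """Single-channel sampled signal with pulse-time and epoch annotations."""

    samples: np.ndarray
    fs: float
    pulse_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    epochs: tuple = ()

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        dur = self.duration
        if self.pulse_times.size and (
            self.pulse_times.min() < 0 or self.pulse_times.max() > dur
        ):
            raise ValueError("pulse_times must lie within the record")
        eps = tuple(self.epochs)
        for a, b in zip(eps, eps[1:]):
            if b.start < a.stop - 1e-12:
                raise ValueError("epochs must be ordered and non-overlapping")
        self.epochs = eps

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def replace(self, **kw) -> "Recording":
        d = dict(
            samples=self.samples, fs=self.fs, pulse_times=self.pulse_times,
            epochs=self.epochs,
        )
        d.update(kw)
        return Recording(**d)


@dataclass
class AnalyticBand:
    """Envelope and phase of a band-limited signal (phase stored unwrapped)."""

    envelope: np.ndarray
    phase_unwrapped: np.ndarray
    fs: float
    band: tuple | None = None

    def __post_init__(self):
        self.envelope = np.asarray(self.envelope, dtype=float)
        self.phase_unwrapped = np.asarray(self.phase_unwrapped, dtype=float)
        if self.envelope.size != self.phase_unwrapped.size:
            raise ValueError("envelope and phase must have equal length")
        if np.any(self.envelope < 0):
            raise ValueError("envelope must be non-negative")

    @property
    def phase(self) -> np.ndarray:
        """Wrapped view of the phase, in [-pi, pi)."""
        return np.mod(self.phase_unwrapped + np.pi, 2 * np.pi) - np.pi

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.envelope.size) / self.fs


@dataclass
class DynamicFeatures:
    """The three fitted signal features, each on an explicit grid."""

    psd_freqs: np.ndarray
    signal_psd: np.ndarray
    env_bin_edges: np.ndarray
    env_pdf: np.ndarray
    env_psd_freqs: np.ndarray
    env_psd: np.ndarray

    def as_vectors(self):
        return (self.signal_psd, self.env_pdf, self.env_psd)

    def grids(self):
        return (self.psd_freqs, self.env_bin_edges, self.env_psd_freqs)


# ---------------------------------------------------------------------------
# conditioning chain
# ---------------------------------------------------------------------------

def remove_artifacts(rec: Recording, post_ms: float = 1.5) -> Recording:
    """Linearly interpolate over each ``[pulse, pulse + post_ms]`` window."""
    if rec.pulse_times.size == 0:
        return rec
    x = rec.samples.copy()
    n = x.size
    for tp in rec.pulse_times:
        # replace every sample with t in [pulse, pulse + post_ms]; boundaries
        # are the last sample strictly before the pulse and the first sample
        # strictly after the window
        i0 = int(np.ceil(tp * rec.fs - 1e-9)) - 1
        i1 = int(np.floor((tp + post_ms * 1e-3) * rec.fs + 1e-9)) + 1
        i0 = max(i0, 0)
        if i1 >= n:
            warnings.warn(
                "artifact window exceeds record end; truncating", stacklevel=2
            )
            x[i0 + 1 :] = x[i0]
            continue
        if i1 - i0 < 2:
            continue
        inner = np.arange(i0 + 1, i1)
        x[inner] = np.interp(inner, [i0, i1], [x[i0], x[i1]])
    return rec.replace(samples=x)


def downsample(rec: Recording, target_fs: float = 2000.0) -> Recording:
    """Anti-aliased decimation to ``target_fs`` (integer ratio required).

    Pulse times and epochs are expressed in seconds and carry over unchanged.
    """
    if rec.fs < target_fs:
        raise ValueError("target_fs exceeds the recording sample rate")
    ratio = rec.fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9:
        raise ValueError(f"non-integer decimation ratio {ratio}")
    if q == 1:
        return rec
    x = rec.samples
    # stage large factors to keep the anti-aliasing filters well conditioned
    for factor in _decimation_stages(q):
        x = sps.decimate(x, factor, ftype="fir", zero_phase=True)
    return rec.replace(samples=x, fs=target_fs)


def _decimation_stages(q: int) -> list[int]:
    stages = []
    while q > 13:
        for f in (10, 8, 5, 4, 3, 2):
            if q % f == 0:
                stages.append(f)
                q //= f
                break
        else:
            break
    stages.append(q)
    return [s for s in stages if s > 1]


def bandpass(rec: Recording, band=(20.0, 35.0), order: int = 4) -> Recording:
    """Zero-phase 4th-order Butterworth bandpass."""
    low, high = band
    if not (0 < low < high < rec.fs / 2):
        raise ValueError(f"invalid band {band} for fs={rec.fs}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    return rec.replace(samples=sps.sosfiltfilt(sos, rec.samples))


def analytic(rec: Recording, band=None) -> AnalyticBand:
    """Hilbert envelope and unwrapped phase of a band-limited recording."""
    z = sps.hilbert(rec.samples)
    return AnalyticBand(
        envelope=np.abs(z),
        phase_unwrapped=np.unwrap(np.angle(z)),
        fs=rec.fs,
        band=tuple(band) if band is not None else None,
    )


# ---------------------------------------------------------------------------
# dynamic features
# ---------------------------------------------------------------------------

def _welch(x: np.ndarray, fs: float, resolution: float):
    nperseg = int(round(fs / resolution))
    nperseg = min(nperseg, x.size)
    return sps.welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)


def dynamic_features(
    signal: np.ndarray,
    fs: float,
    psd_resolution: float = 1.0,
    env_bin_edges: np.ndarray | None = None,
    n_env_bins: int = N_ENV_BINS,
    env_headroom: float = 1.0,
    edge_trim_s: float = EDGE_TRIM_S,
) -> DynamicFeatures:
    """Compute the three dynamic features of a conditioned signal.

    The signal is z-scored first, making every feature invariant to affine
    rescaling of the raw trace.  ``env_bin_edges`` fixes the envelope-PDF
    grid; pass the same edges for a data/model pair so their features are
    directly comparable (envelope values are clipped into the grid so the
    PDF always integrates to one).
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2 * fs:
        raise ValueError("signal must be at least 2 s long")
    sd = x.std()
    if sd == 0:
        raise ValueError("constant signal has no dynamic features")
    x = (x - x.mean()) / sd

    freqs, psd = _welch(x, fs, psd_resolution)

    z = sps.hilbert(x)
    env = np.abs(z)
    k = int(round(edge_trim_s * fs))
    if 2 * k >= env.size:
        raise ValueError("signal too short for the requested edge trim")
    env = env[k : env.size - k] if k else env

    if env_bin_edges is None:
        # headroom > 1 leaves room above the observed maximum so a second
        # signal binned on the same grid is not clipped into the top bin
        upper = float(env.max()) * env_headroom
        env_bin_edges = np.linspace(0.0, upper if upper > 0 else 1.0, n_env_bins + 1)
    env_bin_edges = np.asarray(env_bin_edges, dtype=float)
    clipped = np.clip(env, env_bin_edges[0], env_bin_edges[-1])
    env_pdf, _ = np.histogram(clipped, bins=env_bin_edges, density=True)

    env_freqs, env_psd = _welch(env - env.mean(), fs, psd_resolution)
    return DynamicFeatures(
        psd_freqs=freqs,
        signal_psd=psd,
        env_bin_edges=env_bin_edges,
        env_pdf=env_pdf,
        env_psd_freqs=env_freqs,
        env_psd=env_psd,
    )


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def save_recording(rec: Recording, path) -> None:
    """Write a recording as columnar text with a JSON metadata header."""
    path = Path(path)
    meta = {
        "fs": rec.fs,
        "pulse_times": rec.pulse_times.tolist(),
        "epochs": [
            {
                "label": e.label,
                "start": e.start,
                "stop": e.stop,
                "target_phase": e.target_phase,
            }
            for e in rec.epochs
        ],
    }
    with path.open("w") as fh:
        fh.write("# kurastim-recording " + json.dumps(meta) + "\n")
        np.savetxt(fh, rec.samples, fmt="%.17g")


def load_recording(path) -> Recording:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("# kurastim-recording "):
            raise ValueError(f"{path} is not a kurastim recording file")
        meta = json.loads(header[len("# kurastim-recording "):])
        samples = np.loadtxt(fh)
    epochs = tuple(
        Epoch(e["label"], e["start"], e["stop"], e.get("target_phase"))
        for e in meta["epochs"]
    )
    return Recording(
        samples=np.atleast_1d(samples),
        fs=meta["fs"],
        pulse_times=np.asarray(meta["pulse_times"], dtype=float),
        epochs=epochs,
    )
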