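# kurastim

Phase-locked stimulation of noisy Kuramoto networks: simulation, response-curve
estimation, and feature-based model fitting.

The package models a beta-band neural population as N globally coupled phase
oscillators with Cauchy-distributed natural frequencies, white noise and a
biphasic per-oscillator phase-response function (default `Z(theta) = -sin`).
A closed-loop controller delivers pulses when the network mean phase crosses a
target phase (with an 80 %-of-cycle refractory period). On top of that it
provides:

- **`network_model`** — finite-N Euler–Maruyama simulator (numba-accelerated,
  0.5 ms steps), order parameter, phase-locked stimulation controller,
  `x = rho cos(psi)` observation model.
- **`mean_field`** — the reduced two-ODE model for synchrony `rho` and mean
  phase `psi`, instantaneous amplitude/phase response terms, steady states,
  characteristic curve, fixed-step RK4 integration with impulsive pulses.
- **`signal_processing`** — ECoG-style conditioning chain (pulse-artifact
  interpolation, anti-aliased downsampling to 2 kHz, zero-phase 4th-order
  Butterworth bandpass, Hilbert envelope/phase) and the three dynamic
  features used for fitting (signal PSD, envelope PDF, envelope PSD).
- **`response_curves`** — block-based ARC/PRC estimators (on-epoch vs
  preceding off-epoch; OLS extrapolation of the unwrapped off-epoch phase),
  pulse-based ARC, circular central-difference PRC derivative,
  most-suppressive alignment, one-way ANOVA / Pearson / Spearman statistics
  and amplitude-dependence regressions. **PRC sign convention:** the default
  `"advance"` reports the actual per-pulse phase change (positive = phase
  advanced); `"delay"` reports the negated value. See the module docstring.
- **`fitting`** — normalised feature-matching objective, derivative-free
  global fitting of `(omega0, gamma, K, sigma)` under a fixed evaluation
  budget (`D = sigma**2/2`), mean-synchrony extraction and a
  parameter-recovery harness (synchrony is identifiable; raw parameters are
  degenerate).
- **`synthetic_data`** — generators for everything the pipeline consumes:
  ECoG-like recordings, full 8-phase closed-loop trial sets (10–14 blocks of
  20 s on / 5 s off), and constructed signals with exactly known per-pulse
  phase jumps and envelope steps. Every dataset ships with a `GroundTruth`
  sidecar sufficient for bit-exact regeneration.
- **`hh_demo`** — classic Hodgkin–Huxley neuron demonstrating the biphasic
  (type II) phase response that motivates `Z = -sin`.
- **`experiments`** — seeded reference experiments used by the acceptance
  tests and the acceptance report.

## CLI

```sh
kurastim simulate --config sim.yaml --out out/          # full model
kurastim simulate --config sim.yaml --out out/ --reduced
kurastim features --in rec.txt --band 20 35 --out feat/
kurastim curves   --in trialdir/ --mode block --out curves/
kurastim synth    recording|trials|constructed --config cfg.yaml --out data/
kurastim fit      --features feat/features.json --budget 500 --reps 10 --out fit/
kurastim hh-prc   --amplitude 200 --out hh/
```

Example simulation config (frequencies in Hz; converted to rad/s internally):

```yaml
omega0_hz: 27.0
gamma_hz: 1.0
K: 30.0          # rad/s
D: 1.0           # rad^2/s
N: 200
dt_s: 0.0005
duration_s: 30.0
seed: 1
protocol:
  target_phase_deg: 0.0
  pulse_magnitude: 0.2
  refractory_fraction: 0.8
  blocks: [{off_s: 5, on_s: 20}]
```

Recordings are plain text: a one-line JSON metadata header (sample rate,
pulse times, epochs) followed by one sample per line
(`signal_processing.save_recording` / `load_recording`).

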