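"""Numba-compiled inner loop for the default phase-response function.

Semantics are identical to ``network_model._simulate_python`` with
``Z(theta) = -sin(theta)``: record the macroscopic state, run the
phase-locked trigger on the recorded mean phase, apply the kick within the
triggering step, then take one Euler-Maruyama step using the exact
mean-field form of the coupling sum.
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def simulate_negsin(
    theta0,
    omega,
    K,
    D,
    dt,
    n_steps,
    on_mask,
    target,
    i_pulse,
    refractory_s,
    seed,
    noise,
):
    # `noise` holds pre-scaled Brownian increments, shape (n_steps, n); an
    # empty array selects the in-kernel generator instead (large problems,
    # where materialising the increments would cost too much memory)
    np.random.seed(seed)
    use_noise_array = noise.shape[0] == n_steps and noise.shape[1] == theta0.size
    n = theta0.size
    theta = theta0.copy()
    ct = np.empty(n)
    st = np.empty(n)
    rho = np.empty(n_steps + 1)
    psi = np.empty(n_steps + 1)
    pulse_flags = np.zeros(n_steps + 1, dtype=np.uint8)
    noise_scale = np.sqrt(2.0 * D * dt)
    last_pulse_t = -1.0e30
    d_prev = 0.0
    two_pi = 2.0 * np.pi
    for k in range(n_steps + 1):
        cr = 0.0
        sr = 0.0
        for i in range(n):
            c = np.cos(theta[i])
            s = np.sin(theta[i])
            ct[i] = c
            st[i] = s
            cr += c
            sr += s
        cr /= n
        sr /= n
        r = np.sqrt(cr * cr + sr * sr)
        p = np.arctan2(sr, cr) if r >= 1e-12 else 0.0
        rho[k] = r
        psi[k] = p
        t = k * dt
        d = np.mod(p - target + np.pi, two_pi) - np.pi
        if (
            k > 0
            and on_mask[k] == 1
            and r >= 1e-6
            and d_prev < 0.0 <= d
            and (d - d_prev) < np.pi
            and (t - last_pulse_t) > refractory_s
        ):
            pulse_flags[k] = 1
            last_pulse_t = t
            cr = 0.0
            sr = 0.0
            for i in range(n):
                theta[i] = theta[i] - i_pulse * st[i]
                c = np.cos(theta[i])
                s = np.sin(theta[i])
                ct[i] = c
                st[i] = s
                cr += c
                sr += s
            cr /= n
            sr /= n
            r = np.sqrt(cr * cr + sr * sr)
            p = np.arctan2(sr, cr) if r >= 1e-12 else 0.0
        d_prev = d
        if k < n_steps:
            # sin(p - theta_i) expanded so the per-oscillator sin/cos are reused
            kr_sin = K * r * np.sin(p)
            kr_cos = K * r * np.cos(p)
            if use_noise_array:
                for i in range(n):
                    theta[i] = (
                        theta[i]
                        + dt * (omega[i] + kr_sin * ct[i] - kr_cos * st[i])
                        + noise[k, i]
                    )
            elif D > 0.0:
                for i in range(n):
                    theta[i] = (
                        theta[i]
                        + dt * (omega[i] + kr_sin * ct[i] - kr_cos * st[i])
                        + noise_scale * np.random.standard_normal()
                    )
            else:
                for i in range(n):
                    theta[i] = theta[i] + dt * (
                        omega[i] + kr_sin * ct[i] - kr_cos * st[i]
                    )
    return rho, psi, pulse_flags, theta
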