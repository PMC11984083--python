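"""Small shared helpers: phase wrapping and per-component seed derivation."""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_phase(theta):
    """Wrap angle(s) to the interval [-pi, pi)."""
    return np.mod(np.asarray(theta) + np.pi, TWO_PI) - np.pi


def spawn_seeds(seed: int | None, n: int) -> list[int]:
    """Derive ``n`` independent child seeds from a master seed.

    Uses :class:`numpy.random.SeedSequence` so distinct components
    (frequency draw, dynamics noise, measurement noise, ...) get
    decorrelated streams that are still reproducible from one integer.
    """
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0]) for child in ss.spawn(n)]
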