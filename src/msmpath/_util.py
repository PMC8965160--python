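"""Shared constants and RNG plumbing.

All randomness in the package flows from a single integer seed through
:func:`numpy.random.SeedSequence` spawning; no function touches global RNG
state.
"""

from __future__ import annotations

import numpy as np

#: Boltzmann constant in kcal/mol/K.
KB_KCAL_PER_MOL_K = 0.0019872

#: Default temperature (K) for free-energy conversions.
DEFAULT_TEMPERATURE = 300.0


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Split one integer seed into ``n`` independent generators."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def rng_from_seed(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed))


def wrap_degrees(angles: np.ndarray) -> np.ndarray:
    """Wrap angles (degrees) into the half-open interval [-180, 180)."""
    return np.mod(np.asarray(angles, dtype=float) + 180.0, 360.0) - 180.0
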