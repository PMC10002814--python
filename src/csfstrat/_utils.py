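"""Shared helpers: seed derivation and train-referenced standardization."""

from __future__ import annotations

import numpy as np

MAX_SEED = 2**31 - 1


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds from one master seed.

    Uses numpy's SeedSequence spawning so every stage / repeat of the
    pipeline consumes a documented, collision-resistant stream. Returned
    seeds fit in a signed 32-bit int (sklearn's ``random_state`` range).
    """
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0]) & MAX_SEED for child in ss.spawn(n)]


def as_float_array(x, name: str = "values") -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr
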