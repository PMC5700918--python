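"""Small shared helpers: RNG plumbing and the logistic function."""

from __future__ import annotations

import numpy as np
from scipy.special import expit  # noqa: F401  (re-exported)

_MAX_SEED = 2 ** 31 - 1


def as_rng(seed: np.random.Generator | int | None) -> np.random.Generator:
    """Coerce a seed or Generator into a Generator (fresh entropy if None)."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministically derive ``n`` independent child seeds (< 2**31).

    One master seed drives a SeedSequence; child ``i`` can be reproduced in
    isolation as ``spawn_seeds(master, i + 1)[i]``.
    """
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1)[0] % _MAX_SEED) for c in ss.spawn(n)]
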