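"""Small shared helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["as_rng"]


def as_rng(seed) -> np.random.Generator:
    """Coerce a seed or Generator into a numpy Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
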