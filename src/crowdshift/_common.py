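"""Shared exceptions and random-state plumbing."""

from __future__ import annotations

import numpy as np


class ConfigurationError(ValueError):
    """An invalid configuration (counts, ranges, incompatible design)."""


class DomainError(ValueError):
    """An argument outside the mathematical domain of an operation."""


def as_generator(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed, SeedSequence or Generator into a Generator.

    All stochastic operations in the package accept either, so that a single
    root seed can drive the full pipeline with no hidden global state.
    """
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
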