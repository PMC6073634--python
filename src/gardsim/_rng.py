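"""Seeded, named random-number streams.

A single root seed spawns independent per-component streams (growth, split,
victim selection, ...) so that toggling one experimental arm does not perturb
the random numbers consumed by another.  This is what makes paired null
experiments (e.g. a weight-0 environment shift) reproduce their control runs
bit for bit.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "streams", "derive_seed"]

_MASK = 2**31 - 1


def _key(name: str) -> int:
    return zlib.crc32(name.encode("utf8"))


def stream(seed: int | None, name: str) -> np.random.Generator:
    """Return the named child Generator of ``seed``.

    Deterministic: the same (seed, name) pair always yields the same stream.
    ``seed=None`` draws fresh OS entropy.
    """
    if seed is None:
        return np.random.default_rng()
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), _key(name)])))


def streams(seed: int | None, *names: str) -> dict[str, np.random.Generator]:
    return {name: stream(seed, name) for name in names}


def derive_seed(seed: int, name: str) -> int:
    """A small integer sub-seed for code that wants a seed rather than a stream."""
    return int(np.random.SeedSequence([int(seed), _key(name)]).generate_state(1)[0]) & _MASK
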