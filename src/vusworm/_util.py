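"""Shared helpers: validation error type and seeded substream derivation."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["ValidationError", "substream"]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition or invariant."""


def substream(seed: int, *tags: str) -> np.random.Generator:
    """Derive an independent random generator from a master seed and string tags.

    Each (seed, tags) pair maps to its own substream, so e.g. the dye-fill
    draws for one strain do not shift when another strain or assay is added
    to a panel.  The tag hash is a CRC32 of the joined tags, keeping the
    derived entropy stable across platforms and sessions.
    """
    tag_hash = zlib.crc32("|".join(tags).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag_hash]))
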