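"""Small shared helpers: reproducible per-block seeding and warnings."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def derive_seed(master_seed: int, *tags: str) -> int:
    """Derive a stable child seed from a master seed and string tags.

    Uses a CRC32 hash of the joined tags so that group runs are reproducible
    while per-(subject, condition) draws stay independent.  The result is
    always in ``[0, 2**31)``.
    """
    digest = zlib.crc32("|".join(str(t) for t in tags).encode("utf-8"))
    mixed = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, digest])
    return int(mixed.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def rng_for(master_seed: int, *tags: str) -> np.random.Generator:
    """Generator seeded by :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master_seed, *tags))
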