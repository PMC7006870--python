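"""Deterministic seed derivation.

Every stochastic operation in the package receives its RNG through
:func:`rng_for`, which derives a child seed from a master seed plus a stable
string label. No global numpy RNG state is ever consumed.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(master: int, *labels: object) -> int:
    """Derive a deterministic 31-bit child seed from a master seed and labels."""
    tag = "/".join(str(lab) for lab in labels)
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, zlib.crc32(tag.encode())])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def rng_for(master: int, *labels: object) -> np.random.Generator:
    """A numpy Generator seeded from ``(master, labels)``."""
    return np.random.default_rng(child_seed(master, *labels))
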