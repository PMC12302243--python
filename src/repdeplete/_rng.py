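"""Deterministic seed derivation.

Every stochastic step in the package draws from a numpy Generator seeded by
hashing a root seed together with a tuple of string/int keys (donor id,
timepoint, locus, purpose).  Streams are therefore independent of iteration
order, and adding a sample to a cohort never perturbs another sample's draws.
Derived seeds stay below 2**31.
"""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(root: int, *keys: object) -> int:
    """Hash ``root`` and ``keys`` into a stable 31-bit integer seed."""
    h = hashlib.sha256()
    h.update(str(int(root)).encode())
    for k in keys:
        h.update(b"\x1f")
        h.update(str(k).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def rng_for(root: int, *keys: object) -> np.random.Generator:
    """A Generator on an independent stream identified by ``keys``."""
    return np.random.default_rng(derive_seed(root, *keys))
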