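"""Deterministic seed fan-out.

Every run derives all of its randomness from a single integer seed.  Named
sub-streams are obtained by hashing (seed, *names) so that adding a new
consumer never perturbs existing streams.
"""

import hashlib

import numpy as np


def child_seed(seed: int, *names) -> int:
    """Derive a stable 63-bit child seed from a parent seed and a name path."""
    h = hashlib.sha256()
    h.update(str(int(seed)).encode())
    for name in names:
        h.update(b"/")
        h.update(str(name).encode())
    return int.from_bytes(h.digest()[:8], "big") >> 1


def child_rng(seed: int, *names) -> np.random.Generator:
    """Generator seeded by :func:`child_seed`."""
    return np.random.default_rng(child_seed(seed, *names))
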