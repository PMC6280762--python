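"""Small shared helpers: seeded substreams and numeric transforms."""
from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible random stream derived from one root seed.

    All randomness in the package flows through these so that a single root
    seed pins every module's output without coupling their draw orders.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode("utf-8"))])
    )


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def expit(x):
    x = np.asarray(x, dtype=float)
    return 1.0 / (1.0 + np.exp(-x))


def count_logit(alt, depth):
    """Variance-stabilizing transform of allele fractions.

    ``logit((alt + 0.5) / (depth + 1))`` — defined at zero counts and
    monotone in VAF.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    return logit((alt + 0.5) / (depth + 1.0))
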