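"""Named substreams of a single master seed.

Every source of randomness in the package is derived from one master seed
through named substreams, so that (a) the initial graph and activations for a
given instantiation index are identical across parameter families (matched
initialization), and (b) baseline/null ensembles are independent of the
simulation streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _token_int(token) -> int:
    if isinstance(token, (int, np.integer)):
        return int(token)
    return zlib.crc32(str(token).encode("utf-8"))


def substream(master_seed: int, *tokens) -> np.random.Generator:
    """Return a Generator for the substream named by ``tokens``.

    The same (master_seed, tokens) pair always yields the same stream;
    different token tuples yield statistically independent streams.
    """
    key = tuple(_token_int(t) for t in tokens)
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))
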