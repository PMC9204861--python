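"""Deterministic per-stage seed derivation.

A single master seed drives every stochastic stage of the pipeline. Each stage
(or cell within a stage) derives its own child seed by hashing the master seed
together with a tuple of string/int labels, so stages can be rerun in isolation
and adding a stage never perturbs the seeds of existing ones.
"""

from __future__ import annotations

import zlib

_MOD = 2**31  # derived seeds stay below 2**31 so they fit any downstream RNG API


def derive_seed(master: int, *labels: object) -> int:
    """Return a child seed determined by ``master`` and the label path.

    Labels may be strings, ints, or anything with a stable ``str()``. The same
    (master, labels) pair always maps to the same child seed.
    """
    h = zlib.crc32(repr(int(master)).encode())
    for lab in labels:
        h = zlib.crc32(str(lab).encode(), h)
    return (int(master) * 2654435761 + h) % _MOD
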