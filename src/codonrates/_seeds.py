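"""Named deterministic random substreams.

Every stochastic operation takes an explicit integer seed; no global state.
Substreams are derived from a root seed plus a stable string label so that
adding a stage never perturbs the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, label: str) -> np.random.Generator:
    """Generator for the given root seed and stage label."""
    if not isinstance(seed, (int, np.integer)):
        raise TypeError("seed must be an integer")
    tag = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
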