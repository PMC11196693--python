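"""Named RNG streams derived from one master seed.

Each component of the synthetic generator (gradient, occupancy, baselines,
slopes, residuals, each covariate) draws from its own stream, so changing one
component's sample size never perturbs the others and any component can be
regenerated independently.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for component ``name`` under master ``seed``."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode("utf-8"))])
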