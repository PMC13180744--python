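"""Seed-derivation helpers.

One user-facing integer seed expands into named, independent substreams so
adding a new stochastic component never perturbs the draws of an existing
one, and per-iteration streams are stable under parallel execution.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["component_rng", "derive_seed", "spawn_streams"]


def _label_key(label: str) -> int:
    # crc32 keeps the key stable across processes/platforms (unlike hash()).
    return zlib.crc32(label.encode("utf-8")) & 0x7FFFFFFF


def component_rng(seed: int, label: str, index: int = 0) -> np.random.Generator:
    """Generator for the named component, independent of other labels."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _label_key(label), int(index)])
    )


def derive_seed(seed: int, label: str, index: int = 0) -> int:
    """A plain integer seed (< 2**31) for libraries that want one."""
    ss = np.random.SeedSequence([int(seed), _label_key(label), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def spawn_streams(seed: int, label: str, n: int) -> list[np.random.Generator]:
    """n independent substreams: iteration i always gets stream i."""
    return [component_rng(seed, label, i) for i in range(n)]
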