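"""Deterministic seed derivation.

A single run seed deterministically derives every stage/iteration seed via
:class:`numpy.random.SeedSequence` spawn keys, so any stage can be re-run in
isolation.  Derived seeds are kept below 2**31 for consumers that require a
signed 32-bit integer (e.g. xgboost's ``random_state``).
"""

from __future__ import annotations

import numpy as np

__all__ = ["derive_seed"]


def derive_seed(seed: int, *key: int) -> int:
    """Derive a child seed from ``seed`` and an integer key path.

    The same ``(seed, *key)`` always yields the same child; distinct key
    paths yield (statistically) independent children.
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
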