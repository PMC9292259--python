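"""Small shared numerics: angle wrapping and reproducible seed derivation."""

from __future__ import annotations

import numpy as np


def wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    wrapped = -(np.mod(-a + np.pi, 2.0 * np.pi) - np.pi)
    return wrapped if wrapped.ndim else float(wrapped)


def child_seed(master_seed: int, *key) -> int:
    """Derive a stable 31-bit child seed from a master seed and a key tuple.

    Uses numpy's SeedSequence so that per-(participant, maze, trial) streams
    are independent and reproducible regardless of evaluation order.
    """
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
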