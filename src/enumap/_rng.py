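"""Seed-stream derivation.

Every stochastic stage draws from its own generator derived from a single
root seed plus a stage label, so stages can be re-run or re-ordered without
perturbing each other's streams.
"""

from __future__ import annotations

import hashlib

import numpy as np


def _label_key(label: str) -> int:
    digest = hashlib.blake2b(label.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "big")


def stage_rng(root_seed: int, label: str) -> np.random.Generator:
    """Return a generator for stage ``label`` derived from ``root_seed``.

    The mapping is stable across processes and Python versions (no use of
    the salted builtin ``hash``).
    """
    return np.random.default_rng(np.random.SeedSequence([int(root_seed), _label_key(label)]))
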