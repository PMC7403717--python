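"""Randomized, blinded presentation order for phenotype scoring.

Movies (or any samples) are presented to the scorer in a seeded uniform
random order under opaque ids that carry no information about the
experimental group; a separate key maps the opaque ids back to the true
identities once scoring is complete.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import write_json

__all__ = ["BlindedOrder", "blinded_order"]


@dataclass
class BlindedOrder:
    seed: int
    order: list  # opaque ids in presentation order
    key: dict  # opaque id -> true identity

    def unblind(self, opaque_id: str):
        return self.key[opaque_id]

    def write_key(self, path) -> None:
        write_json(path, {"seed": self.seed, "key": self.key})


def blinded_order(items, seed: int) -> BlindedOrder:
    """Uniform seeded permutation of ``items`` under opaque sample ids.

    Opaque ids are sequential in *presentation* order (sample_0001, ...),
    so the id itself reveals nothing about the underlying sample.
    """
    items = list(items)
    if not items:
        raise ValueError("need at least one item to shuffle")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(items))
    order = [f"sample_{i + 1:04d}" for i in range(len(items))]
    key = {opaque: items[int(p)] for opaque, p in zip(order, perm)}
    return BlindedOrder(seed=seed, order=order, key=key)
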