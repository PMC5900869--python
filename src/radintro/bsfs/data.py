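"""Containers for blockwise site-type tallies."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class BlockConfig:
    """Counts of the four variable-site classes in one block.

    k1: heterozygous sites exclusive to the outcrossing species (rivale)
    k2: heterozygous sites exclusive to the selfing species (urbanum)
    k3: heterozygous sites shared by both individuals
    k4: fixed differences between the two homozygous genotypes
    """

    k1: int
    k2: int
    k3: int
    k4: int

    def __post_init__(self):
        if min(self.k1, self.k2, self.k3, self.k4) < 0:
            raise ValueError("site counts must be non-negative")

    @property
    def is_monomorphic(self) -> bool:
        return (self.k1, self.k2, self.k3, self.k4) == (0, 0, 0, 0)

    def astuple(self):
        return (self.k1, self.k2, self.k3, self.k4)


@dataclass
class BsfsData:
    """A multiset of block configurations over B blocks.

    ``configs`` is an integer array of shape (B, 4).  After tallying,
    monomorphic blocks are excluded (the likelihood is conditioned on
    observing variable blocks), so ``configs`` must contain no all-zero row.
    """

    configs: np.ndarray
    block_length: int = 117

    def __post_init__(self):
        self.configs = np.asarray(self.configs, dtype=np.int64)
        if self.configs.ndim != 2 or self.configs.shape[1] != 4:
            raise ValueError("configs must have shape (B, 4)")
        if len(self.configs) < 1:
            raise ValueError("need at least one block")

    @classmethod
    def from_blocks(cls, blocks, block_length: int = 117) -> "BsfsData":
        return cls(np.array([b.astuple() for b in blocks]), block_length)

    @property
    def n_blocks(self) -> int:
        return len(self.configs)

    @property
    def n_monomorphic(self) -> int:
        return int((self.configs.sum(axis=1) == 0).sum())

    def drop_monomorphic(self) -> "BsfsData":
        keep = self.configs.sum(axis=1) > 0
        return BsfsData(self.configs[keep], self.block_length)

    def blocks(self):
        return [BlockConfig(*row) for row in self.configs]
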