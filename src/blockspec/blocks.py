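"""Blocks of successive cleavage-site positions and their Shannon entropies.

A block is a contiguous run of substrate positions that ends (non-prime) or
starts (prime) at the scissile bond:

    B4 = P4 P3 P2 P1      B1 = P1        B1' = P1'       B4' = P1'..P4'

Each window contributes one k-mer ("combination") per block, provided every
position inside the block's span is a real residue; windows with a gap in
the span are skipped for that block only.  The Shannon entropy (in bits) of
a block's k-mer frequency distribution quantifies how permissive the
protease is over those successive subsites: 0 bits means one invariant
combination, log2(m) bits means m combinations used uniformly.  A protease
is summarised by the eight-entropy profile (E4, E3, E2, E1, E1', E2', E3',
E4').
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .core_io import AMINO_ACIDS, GAP, SubstrateSet

__all__ = [
    "BlockIndex",
    "BLOCKS",
    "BLOCK_BY_LABEL",
    "ENTROPY_LABELS",
    "BlockCombination",
    "BlockCountTable",
    "EntropyProfile",
    "EmptyBlockError",
    "build_blocks",
    "block_entropy",
    "entropy_profile",
]


@dataclass(frozen=True)
class BlockIndex:
    """One of the eight blocks; ``start:stop`` is its window-index span."""

    label: str
    width: int
    start: int
    stop: int
    prime: bool

    def kmer_of(self, residues: str) -> str | None:
        """The window's combination at this block, or None if a gap intrudes."""
        kmer = residues[self.start : self.stop]
        return None if GAP in kmer else kmer

    def __str__(self) -> str:
        return self.label


#: Canonical N->C order, matching the entropy profile (E4, E3, .., E4').
BLOCKS: tuple[BlockIndex, ...] = (
    BlockIndex("B4", 4, 0, 4, False),
    BlockIndex("B3", 3, 1, 4, False),
    BlockIndex("B2", 2, 2, 4, False),
    BlockIndex("B1", 1, 3, 4, False),
    BlockIndex("B1'", 1, 4, 5, True),
    BlockIndex("B2'", 2, 4, 6, True),
    BlockIndex("B3'", 3, 4, 7, True),
    BlockIndex("B4'", 4, 4, 8, True),
)

BLOCK_BY_LABEL = {b.label: b for b in BLOCKS}

#: Entropy column headers matching the block order above.
ENTROPY_LABELS = ("E4", "E3", "E2", "E1", "E1'", "E2'", "E3'", "E4'")


class EmptyBlockError(ValueError):
    """Entropy is undefined for a block no window contributes to."""


@dataclass(frozen=True)
class BlockCombination:
    """A specific k-mer occupying one block, e.g. ``LK`` at B2."""

    block: BlockIndex
    kmer: str

    def __post_init__(self) -> None:
        if len(self.kmer) != self.block.width:
            raise ValueError(
                f"kmer {self.kmer!r} has length {len(self.kmer)}, "
                f"but block {self.block.label} has width {self.block.width}"
            )
        bad = set(self.kmer) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"illegal symbol(s) {sorted(bad)} in kmer {self.kmer!r}")

    def __str__(self) -> str:
        return f"{self.kmer}@{self.block.label}"


@dataclass
class BlockCountTable:
    """Per-block k-mer occurrence counts for one substrate set."""

    counts: dict[BlockIndex, Counter] = field(
        default_factory=lambda: {b: Counter() for b in BLOCKS}
    )

    def total(self, block: BlockIndex) -> int:
        """Number of windows contributing to ``block``."""
        return sum(self.counts[block].values())


@dataclass(frozen=True)
class EntropyProfile:
    """The eight block entropies of one protease, in bits, order E4..E4'."""

    protease_id: str
    entropies: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.entropies) != len(BLOCKS):
            raise ValueError("profile needs exactly 8 entropies")
        if any(not math.isfinite(e) or e < 0 for e in self.entropies):
            raise ValueError("entropies must be finite and non-negative")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.entropies, dtype=float)


def build_blocks(sset: SubstrateSet) -> BlockCountTable:
    """Count the k-mer at every block of every window.

    A window increments a block's table only when the block's whole span is
    gap-free, so terminus-truncated windows still inform the blocks they do
    cover.
    """
    table = BlockCountTable()
    for window in sset.windows:
        for block in BLOCKS:
            kmer = block.kmer_of(window.residues)
            if kmer is not None:
                table.counts[block][kmer] += 1
    return table


def block_entropy(table: BlockCountTable, block: BlockIndex) -> float:
    """Plug-in Shannon entropy (bits) of the block's k-mer distribution.

    Frequencies are counts over the block's own contributing total, so
    gap-excluded windows do not distort the distribution.  0*log(0) is 0.
    """
    counts = np.fromiter(table.counts[block].values(), dtype=float)
    total = counts.sum()
    if total == 0:
        raise EmptyBlockError(f"entropy undefined for empty block {block.label}")
    p = counts / total
    return float(-(p * np.log2(p)).sum()) + 0.0  # + 0.0 normalises -0.0


def entropy_profile(sset: SubstrateSet) -> EntropyProfile:
    """The (E4, E3, E2, E1, E1', E2', E3', E4') entropy vector of a set."""
    table = build_blocks(sset)
    entropies = []
    for block in BLOCKS:
        try:
            entropies.append(block_entropy(table, block))
        except EmptyBlockError:
            raise EmptyBlockError(
                f"{sset.protease_id}: entropy undefined for empty block {block.label}"
            ) from None
    return EntropyProfile(sset.protease_id, tuple(entropies))
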