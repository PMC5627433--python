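"""Prominent block combinations via Fisher's exact test on simulated nulls.

A combination (block k-mer) is called *prominent* when it is significantly
enriched in the observed substrate windows relative to windows simulated
from the protease's own amino-acid frequencies.  For each block:

1. Estimate a background model from the observed residues (per-position by
   default, optionally pooled over positions).
2. Repeat ``reps`` times (default 1000): simulate a background set of the
   same size, and for every combination observed in the experiment build
   the 2x2 table

   =================  =====  ====
                       yes    no
   =================  =====  ====
   experiment windows   a      b
   background windows   c      d
   =================  =====  ====

   and compute the one-sided (enrichment) Fisher exact p-value from the
   hypergeometric point probability

       p(a) = (a+b)! (c+d)! (a+c)! (b+d)! / (a! b! c! d! n!)

3. Bonferroni-correct within the block: a repetition *votes* for the
   combination when p < alpha / N, N being the number of distinct
   combinations observed at that block.  A combination is prominent when it
   collects votes in more than half of the repetitions.

All randomness flows from one master seed: repetition r draws from an
independent substream spawned from ``numpy.random.SeedSequence(seed)``, so
results are reproducible and repetitions could be computed in any order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core_io import AMINO_ACIDS, GAP, WINDOW_LENGTH, SubstrateSet, SubstrateWindow
from .blocks import BLOCKS, BlockCombination, BlockIndex

__all__ = [
    "BackgroundModel",
    "ContingencyTable",
    "ProminenceRecord",
    "BlockCoverage",
    "COVERAGE_BIN_EDGES",
    "estimate_background",
    "simulate_background",
    "hypergeom_point_prob",
    "fisher_exact_greater",
    "find_prominent",
    "substrate_coverage",
    "protease_block_proportions",
]

log = logging.getLogger(__name__)

_N_AA = len(AMINO_ACIDS)


@dataclass(frozen=True)
class BackgroundModel:
    """Amino-acid frequencies used to simulate null substrate windows.

    ``per_position`` mode keeps an (8, 20) table, one distribution per
    window position; ``pooled`` mode keeps a single 20-vector shared by all
    positions.
    """

    mode: str
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        freq = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freq)
        if self.mode == "per_position":
            expected = (WINDOW_LENGTH, _N_AA)
        elif self.mode == "pooled":
            expected = (_N_AA,)
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        if freq.shape != expected:
            raise ValueError(f"{self.mode} frequencies must have shape {expected}, "
                             f"got {freq.shape}")
        if (freq < 0).any():
            raise ValueError("frequencies must be non-negative")
        sums = freq.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("frequency rows must sum to 1")

    def position_table(self) -> np.ndarray:
        """Frequencies as an (8, 20) table regardless of mode."""
        if self.mode == "pooled":
            return np.tile(self.frequencies, (WINDOW_LENGTH, 1))
        return self.frequencies


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: (a, b) experiment with/without, (c, d) background likewise."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("contingency table is empty (n = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ProminenceRecord:
    """One tested combination with its enrichment evidence."""

    combination: BlockCombination
    experiment_count: int      # a: experiment windows carrying the combination
    experiment_total: int      # a + b: experiment windows contributing to the block
    n_tests: int               # N: distinct combinations at this block
    alpha_corrected: float     # alpha / N
    reps: int
    votes: int                 # repetitions with p < alpha / N
    median_p: float            # median p across repetitions (ranking only)
    prominent: bool            # votes > reps / 2


# --- background -----------------------------------------------------------

def estimate_background(sset: SubstrateSet, mode: str = "per_position") -> BackgroundModel:
    """Empirical residue frequencies of a set's non-gap symbols.

    ``per_position`` (default) normalises each window position separately
    and raises if any position has no observations; ``pooled`` aggregates
    all positions into a single distribution.
    """
    if not sset.windows:
        raise ValueError("cannot estimate a background from an empty set")
    counts = np.zeros((WINDOW_LENGTH, _N_AA), dtype=float)
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for window in sset.windows:
        for pos, symbol in enumerate(window.residues):
            if symbol != GAP:
                counts[pos, aa_index[symbol]] += 1
    if mode == "per_position":
        totals = counts.sum(axis=1)
        empty = np.nonzero(totals == 0)[0]
        if empty.size:
            from .core_io import POSITIONS
            names = ", ".join(POSITIONS[i] for i in empty)
            raise ValueError(f"no non-gap observations at position(s) {names}")
        return BackgroundModel("per_position", counts / totals[:, None])
    if mode == "pooled":
        pooled = counts.sum(axis=0)
        return BackgroundModel("pooled", pooled / pooled.sum())
    raise ValueError(f"unknown background mode {mode!r}")


def _sample_residue_matrix(model: BackgroundModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n gap-free windows as an (n, 8) residue-index matrix."""
    table = model.position_table()
    mat = np.empty((n, WINDOW_LENGTH), dtype=np.int64)
    for pos in range(WINDOW_LENGTH):
        mat[:, pos] = rng.choice(_N_AA, size=n, p=table[pos])
    return mat


def simulate_background(model: BackgroundModel, n: int, seed: int) -> SubstrateSet:
    """Simulate ``n`` gap-free windows, each position drawn from the model."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    mat = _sample_residue_matrix(model, n, rng)
    windows = ["".join(AMINO_ACIDS[i] for i in row) for row in mat]
    return SubstrateSet("background", [SubstrateWindow(w) for w in windows])


# --- Fisher's exact test --------------------------------------------------

_LGAMMA_LIMIT = 4096
_LFACT = np.zeros(_LGAMMA_LIMIT)
for _i in range(2, _LGAMMA_LIMIT):
    _LFACT[_i] = _LFACT[_i - 1] + math.log(_i)


def _log_factorial(k: int) -> float:
    if k < _LGAMMA_LIMIT:
        return float(_LFACT[k])
    return math.lgamma(k + 1)


def _log_point_prob(a: int, b: int, c: int, d: int) -> float:
    """Log of the hypergeometric probability of one 2x2 table given margins."""
    n = a + b + c + d
    return (
        _log_factorial(a + b) + _log_factorial(c + d)
        + _log_factorial(a + c) + _log_factorial(b + d)
        - _log_factorial(a) - _log_factorial(b)
        - _log_factorial(c) - _log_factorial(d)
        - _log_factorial(n)
    )


def hypergeom_point_prob(t: ContingencyTable) -> float:
    """Probability of exactly this table under fixed margins (log-space)."""
    return math.exp(_log_point_prob(t.a, t.b, t.c, t.d))


def _fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided enrichment p: sum of point probs over tables with a' >= a."""
    r1, r2 = a + b, c + d
    m = a + c  # column total, fixed along the tail
    a_max = min(r1, m)
    # table at a' = ap keeps all margins: (ap, r1-ap, m-ap, r2-m+ap)
    logs = [_log_point_prob(ap, r1 - ap, m - ap, r2 - m + ap)
            for ap in range(a, a_max + 1)]
    if not logs:
        return 1.0
    top = max(logs)
    total = top + math.log(sum(math.exp(x - top) for x in logs))
    return min(1.0, math.exp(total))


def fisher_exact_greater(t: ContingencyTable) -> float:
    """One-sided Fisher exact p-value for enrichment (tail a' >= a)."""
    return _fisher_greater(t.a, t.b, t.c, t.d)


# --- prominence calling ---------------------------------------------------

def _encode_kmer(kmer: str) -> int:
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    code = 0
    for ch in kmer:
        code = code * _N_AA + aa_index[ch]
    return code


def _encode_block_columns(mat: np.ndarray, block: BlockIndex) -> np.ndarray:
    codes = np.zeros(mat.shape[0], dtype=np.int64)
    for pos in range(block.start, block.stop):
        codes = codes * _N_AA + mat[:, pos]
    return codes


def _median_from_sorted_counts(values: np.ndarray, counts: np.ndarray, total: int) -> float:
    """Median of a multiset given ascending unique values and multiplicities."""
    cum = np.cumsum(counts)
    if total % 2:
        k = total // 2
        return float(values[np.searchsorted(cum, k + 1)])
    k1, k2 = total // 2 - 1, total // 2
    lo = float(values[np.searchsorted(cum, k1 + 1)])
    hi = float(values[np.searchsorted(cum, k2 + 1)])
    return 0.5 * (lo + hi)


def find_prominent(
    sset: SubstrateSet,
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    background_mode: str = "per_position",
) -> list[ProminenceRecord]:
    """Call prominent combinations for one (already filtered) substrate set.

    For each block the distinct observed combinations are tested against
    ``reps`` simulated background sets of the same size as the input; a
    combination is prominent when its Bonferroni-corrected one-sided Fisher
    p-value falls below alpha/N in more than half of the repetitions.
    Records are sorted by block (N->C), then descending experiment count,
    then k-mer.  Fully reproducible given ``seed``.
    """
    if reps <= 0:
        raise ValueError("reps must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not sset.windows:
        raise ValueError("cannot analyse an empty substrate set")

    model = estimate_background(sset, mode=background_mode)
    n_bg = len(sset.windows)

    # distinct experiment combinations per block
    exp: dict[BlockIndex, tuple[np.ndarray, np.ndarray, int]] = {}
    for block in BLOCKS:
        kmers = [k for w in sset.windows if (k := block.kmer_of(w.residues)) is not None]
        if not kmers:
            log.warning("%s: block %s has no contributing windows; skipped",
                        sset.protease_id, block.label)
            continue
        codes = np.array([_encode_kmer(k) for k in kmers], dtype=np.int64)
        uniq, counts = np.unique(codes, return_counts=True)
        exp[block] = (uniq, counts, len(codes))

    # background combination counts: C[block][j, r] = count of combination j
    # in repetition r's simulated set
    bg_counts = {block: np.zeros((len(uniq), reps), dtype=np.int32)
                 for block, (uniq, _, _) in exp.items()}
    children = np.random.SeedSequence(seed).spawn(reps)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        mat = _sample_residue_matrix(model, n_bg, rng)
        for block, (uniq, _, _) in exp.items():
            codes = np.sort(_encode_block_columns(mat, block))
            left = np.searchsorted(codes, uniq, side="left")
            right = np.searchsorted(codes, uniq, side="right")
            bg_counts[block][:, r] = right - left

    p_cache: dict[tuple[int, int, int, int], float] = {}
    records: list[ProminenceRecord] = []
    for block in BLOCKS:
        if block not in exp:
            continue
        uniq, counts, total = exp[block]
        n_tests = len(uniq)
        threshold = alpha / n_tests
        order = np.lexsort((uniq, -counts))
        for j in order:
            a = int(counts[j])
            b = total - a
            cvals, cmult = np.unique(bg_counts[block][j], return_counts=True)
            pvals = np.empty(len(cvals))
            for i, c in enumerate(cvals):
                key = (a, b, int(c), n_bg - int(c))
                p = p_cache.get(key)
                if p is None:
                    p = _fisher_greater(*key)
                    p_cache[key] = p
                pvals[i] = p
            # p is non-decreasing in c at fixed a (more background hits =>
            # weaker enrichment), so cvals ascending means pvals ascending
            votes = int(cmult[pvals < threshold].sum())
            median_p = _median_from_sorted_counts(pvals, cmult, reps)
            kmer = _decode_kmer(int(uniq[j]), block.width)
            records.append(ProminenceRecord(
                combination=BlockCombination(block, kmer),
                experiment_count=a,
                experiment_total=total,
                n_tests=n_tests,
                alpha_corrected=threshold,
                reps=reps,
                votes=votes,
                median_p=median_p,
                prominent=votes > reps / 2,
            ))
    return records


def _decode_kmer(code: int, width: int) -> str:
    chars = []
    for _ in range(width):
        code, rem = divmod(code, _N_AA)
        chars.append(AMINO_ACIDS[rem])
    return "".join(reversed(chars))


# --- summaries ------------------------------------------------------------

#: Upper edges of the four lower coverage shade bins; the fifth is [0.8, 1].
COVERAGE_BIN_EDGES = (0.2, 0.4, 0.6, 0.8)


@dataclass(frozen=True)
class BlockCoverage:
    """Fraction of a set's windows covered by prominent combinations at one block.

    ``bin`` is the five-way shade index 0 (fraction < 0.2) .. 4 (>= 0.8), or
    None when the block has no prominent combination at all (a distinct
    state, not the darkest bin).
    """

    fraction: float
    bin: int | None

    @property
    def state(self) -> str:
        return "none" if self.bin is None else "covered"


def _coverage_bin(fraction: float) -> int:
    for i, edge in enumerate(COVERAGE_BIN_EDGES):
        if fraction < edge:
            return i
    return len(COVERAGE_BIN_EDGES)


def substrate_coverage(
    sset: SubstrateSet, records: Sequence[ProminenceRecord]
) -> dict[str, BlockCoverage]:
    """Per-block fraction of windows whose k-mer is any prominent combination."""
    prominent: dict[BlockIndex, set[str]] = {}
    for rec in records:
        if rec.prominent:
            prominent.setdefault(rec.combination.block, set()).add(rec.combination.kmer)
    n = len(sset.windows)
    out: dict[str, BlockCoverage] = {}
    for block in BLOCKS:
        kmers = prominent.get(block)
        if not kmers:
            out[block.label] = BlockCoverage(0.0, None)
            continue
        hits = sum(1 for w in sset.windows if block.kmer_of(w.residues) in kmers)
        fraction = hits / n if n else 0.0
        out[block.label] = BlockCoverage(fraction, _coverage_bin(fraction))
    return out


def protease_block_proportions(
    results: Mapping[str, Sequence[ProminenceRecord]]
) -> dict[str, float]:
    """Percentage of proteases with >= 1 prominent combination, per block."""
    if not results:
        raise ValueError("need results for at least one protease")
    n = len(results)
    out: dict[str, float] = {}
    for block in BLOCKS:
        hit = sum(
            1 for records in results.values()
            if any(r.prominent and r.combination.block == block for r in records)
        )
        out[block.label] = 100.0 * hit / n
    return out
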