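"""Length filtering and greedy redundancy removal for substrate windows.

Curated cleavage collections contain many near-identical windows (the same
substrate reported by several studies, single-site variants, overlapping
truncations).  Left in place they inflate apparent specificity, so before
any statistics the pipeline (1) drops windows carrying fewer than two
residues and (2) thins the set with a Hobohm-style greedy algorithm until no
retained pair is >= 87.5 % identical -- i.e. every retained pair differs at
two or more of the eight positions.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .core_io import GAP, WINDOW_LENGTH, SubstrateSet, SubstrateWindow, encode_windows

__all__ = [
    "DEFAULT_SIMILARITY_THRESHOLD",
    "pairwise_similarity",
    "min_length_filter",
    "greedy_filter",
]

log = logging.getLogger(__name__)

#: Remove one of any pair at >= 7/8 positional identity.
DEFAULT_SIMILARITY_THRESHOLD = 0.875


def pairwise_similarity(a: SubstrateWindow, b: SubstrateWindow) -> float:
    """Fraction of the 8 positions where both windows carry the same residue.

    Gap-gap positions do not count as matches: two windows truncated at the
    same terminus are not made artificially similar by shared absence of
    data.  Symmetric; no alignment is performed because windows are already
    anchored at the cleavage bond.
    """
    matches = sum(
        1 for x, y in zip(a.residues, b.residues) if x == y and x != GAP
    )
    return matches / WINDOW_LENGTH


def min_length_filter(sset: SubstrateSet, min_residues: int = 2) -> SubstrateSet:
    """Retain windows with at least ``min_residues`` non-gap positions.

    Windows carrying fewer than two residues say nothing about subsite
    cooperation and are discarded before any statistics.  Order preserved.
    """
    kept = [w for w in sset.windows if w.n_residues >= min_residues]
    removed = len(sset.windows) - len(kept)
    if removed:
        log.info("%s: length filter removed %d of %d windows (<%d residues)",
                 sset.protease_id, removed, len(sset.windows), min_residues)
    return SubstrateSet(sset.protease_id, kept)


def _similarity_counts(codes: np.ndarray) -> np.ndarray:
    """Pairwise count of matching non-gap positions; (n, n) int16 matrix."""
    n = codes.shape[0]
    counts = np.zeros((n, n), dtype=np.int16)
    for pos in range(codes.shape[1]):
        col = codes[:, pos]
        counts += (col[:, None] == col[None, :]) & (col[:, None] >= 0)
    return counts


def greedy_filter(
    sset: SubstrateSet, threshold: float = DEFAULT_SIMILARITY_THRESHOLD
) -> SubstrateSet:
    """Greedily delete windows until no retained pair reaches ``threshold``.

    Builds the conflict graph (edge iff similarity >= threshold) and
    repeatedly deletes the window with the most current conflicts, ties
    broken toward the larger input index, recomputing degrees after each
    deletion.  Deterministic, idempotent, and O(n^2) in the window count --
    acceptable for database-scale sets (n up to ~1e4 per protease).
    """
    n = len(sset.windows)
    if n <= 1:
        return SubstrateSet(sset.protease_id, list(sset.windows))
    codes = encode_windows(sset.windows)
    counts = _similarity_counts(codes)
    min_matches = math.ceil(threshold * WINDOW_LENGTH - 1e-9)
    adj = counts >= min_matches
    np.fill_diagonal(adj, False)
    degrees = adj.sum(axis=1).astype(np.int64)
    alive = np.ones(n, dtype=bool)
    while degrees.max(initial=0) > 0:
        top = degrees.max()
        # ties: delete the window appearing later in the input
        victim = int(np.nonzero(degrees == top)[0][-1])
        degrees -= adj[:, victim]
        degrees[victim] = 0
        adj[victim, :] = False
        adj[:, victim] = False
        alive[victim] = False
    kept = [w for i, w in enumerate(sset.windows) if alive[i]]
    if len(kept) < n:
        log.info("%s: greedy filter removed %d of %d windows (threshold %.3f)",
                 sset.protease_id, n - len(kept), n, threshold)
    return SubstrateSet(sset.protease_id, kept)
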