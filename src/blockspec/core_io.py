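"""Data model and I/O for protease cleavage-site windows.

A cleavage event is described by the eight substrate residues flanking the
scissile bond, indexed P4, P3, P2, P1 on the N-terminal side and P1', P2',
P3', P4' on the C-terminal side (Schechter-Berger nomenclature).  The bond
is hydrolysed between P1 and P1'.  Windows that run past a protein terminus
are padded with the gap symbol ``-``; gaps are therefore only legal as a
contiguous prefix and/or suffix, never in the interior.

The module reads and writes two plain-text representations:

* TSV -- one row per window: ``protease_id<TAB>window`` (8 characters) or the
  expanded 9-column variant with one residue per column.  Lines starting
  with ``#`` are comments.
* FASTA -- one record per window, the first whitespace-separated token of
  the header being the protease identifier.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO, Union

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "WINDOW_LENGTH",
    "POSITIONS",
    "SubstrateWindow",
    "SubstrateSet",
    "PositionFrequencyMatrix",
    "SubstrateTableError",
    "read_substrate_table",
    "write_substrate_table",
    "window_from_sequence",
    "export_pfm",
]

log = logging.getLogger(__name__)

#: The 20 standard amino acids, one-letter codes, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Terminus-padding symbol.
GAP = "-"
#: P4..P4' -- four residues on each side of the scissile bond.
WINDOW_LENGTH = 8
#: Position labels in N->C order; the bond sits between P1 and P1'.
POSITIONS = ("P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'")

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_ALLOWED = set(AMINO_ACIDS) | {GAP}
#: Ambiguity / non-standard codes that may appear in real annotations.
AMBIGUOUS_CODES = set("BJZXUO")


class SubstrateTableError(ValueError):
    """Malformed window table; the message names the offending line."""


@dataclass(frozen=True)
class SubstrateWindow:
    """One 8-position cleavage window, P4..P4' in N->C order.

    Parameters
    ----------
    residues:
        String of exactly eight symbols over the 20 standard one-letter
        amino-acid codes plus ``-`` for positions beyond a terminus.
    """

    residues: str

    def __post_init__(self) -> None:
        r = self.residues
        if len(r) != WINDOW_LENGTH:
            raise ValueError(
                f"window must have exactly {WINDOW_LENGTH} symbols, got {len(r)}: {r!r}"
            )
        bad = set(r) - _ALLOWED
        if bad:
            raise ValueError(f"illegal symbol(s) {sorted(bad)} in window {r!r}")
        core = r.strip(GAP)
        if not core:
            raise ValueError(f"window {r!r} contains no residues")
        if GAP in core:
            raise ValueError(f"interior gap in window {r!r}; gaps may only pad termini")

    @property
    def n_residues(self) -> int:
        """Number of non-gap positions."""
        return WINDOW_LENGTH - self.residues.count(GAP)

    def __str__(self) -> str:
        return self.residues


@dataclass
class SubstrateSet:
    """All cleavage windows attributed to one protease, input order kept."""

    protease_id: str
    windows: list[SubstrateWindow] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.protease_id:
            raise ValueError("protease_id must be non-empty")
        self.windows = list(self.windows)

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[SubstrateWindow]:
        return iter(self.windows)


@dataclass
class PositionFrequencyMatrix:
    """Residue counts per window position (20 amino acids x 8 positions).

    Column sums equal the number of windows with a non-gap residue at that
    position; this is the standard input for sequence-logo renderers.
    """

    counts: np.ndarray  # shape (20, 8), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(AMINO_ACIDS), WINDOW_LENGTH):
            raise ValueError(f"PFM must be 20x8, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("PFM counts must be non-negative")

    def normalized(self) -> np.ndarray:
        """Column-normalised frequencies; all-zero columns stay zero."""
        totals = self.counts.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(totals > 0, self.counts / np.maximum(totals, 1), 0.0)
        return freq

    def write(self, sink: TextIO) -> None:
        """Emit a tab-separated 20x8 count table with P4..P4' headers."""
        sink.write("aa\t" + "\t".join(POSITIONS) + "\n")
        for i, aa in enumerate(AMINO_ACIDS):
            sink.write(aa + "\t" + "\t".join(str(c) for c in self.counts[i]) + "\n")


def _parse_window(text: str, where: str, on_ambiguous: str) -> SubstrateWindow | None:
    """Build a window from raw text; returns None for a dropped ambiguous one."""
    text = text.upper()
    amb = set(text) & AMBIGUOUS_CODES
    if amb:
        if on_ambiguous == "drop":
            log.warning("%s: dropping window %r with ambiguous code(s) %s",
                        where, text, sorted(amb))
            return None
        raise SubstrateTableError(
            f"{where}: ambiguous residue code(s) {sorted(amb)} in window {text!r}"
        )
    try:
        return SubstrateWindow(text)
    except ValueError as exc:
        raise SubstrateTableError(f"{where}: {exc}") from None


def _as_text_stream(source: Union[str, os.PathLike, TextIO]):
    if isinstance(source, (str, os.PathLike)):
        return open(source, "rt", encoding="utf-8"), True
    return source, False


def read_substrate_table(
    source: Union[str, os.PathLike, TextIO],
    dialect: str = "tsv",
    on_ambiguous: str = "error",
) -> list[SubstrateSet]:
    """Read cleavage windows grouped per protease.

    Parameters
    ----------
    source:
        Path or open text stream.
    dialect:
        ``"tsv"`` (2- or 9-column rows) or ``"fasta"``.
    on_ambiguous:
        ``"error"`` (default) rejects windows containing B/J/Z/X/U/O;
        ``"drop"`` discards them with a logged warning.

    Returns
    -------
    One :class:`SubstrateSet` per distinct protease identifier, in order of
    first appearance; windows keep file order.  Empty input yields an empty
    list, not an error.
    """
    if dialect not in ("tsv", "fasta"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'fasta'")
    if on_ambiguous not in ("error", "drop"):
        raise ValueError("on_ambiguous must be 'error' or 'drop'")
    stream, opened = _as_text_stream(source)
    try:
        if dialect == "tsv":
            pairs = _iter_tsv(stream, on_ambiguous)
        else:
            pairs = _iter_fasta(stream, on_ambiguous)
        sets: dict[str, SubstrateSet] = {}
        for protease_id, window in pairs:
            if window is None:
                continue
            sets.setdefault(protease_id, SubstrateSet(protease_id)).windows.append(window)
        return list(sets.values())
    finally:
        if opened:
            stream.close()


def _iter_tsv(stream: TextIO, on_ambiguous: str):
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        where = f"line {lineno}"
        if len(fields) == 2:
            protease_id, window_text = fields
        elif len(fields) == 1 + WINDOW_LENGTH:
            protease_id = fields[0]
            for f in fields[1:]:
                if len(f) != 1:
                    raise SubstrateTableError(
                        f"{where}: expected single-character residue column, got {f!r}"
                    )
            window_text = "".join(fields[1:])
        else:
            raise SubstrateTableError(
                f"{where}: expected 2 or {1 + WINDOW_LENGTH} tab-separated columns, "
                f"got {len(fields)}"
            )
        if not protease_id:
            raise SubstrateTableError(f"{where}: empty protease identifier")
        yield protease_id, _parse_window(window_text, where, on_ambiguous)


def _iter_fasta(stream: TextIO, on_ambiguous: str):
    from Bio import SeqIO

    for i, record in enumerate(SeqIO.parse(stream, "fasta"), start=1):
        protease_id = record.id.split()[0] if record.id else ""
        if not protease_id:
            raise SubstrateTableError(f"record {i}: empty protease identifier")
        yield protease_id, _parse_window(str(record.seq), f"record {i} ({protease_id})",
                                         on_ambiguous)


def write_substrate_table(sets: Iterable[SubstrateSet], sink: TextIO) -> None:
    """Write sets as 2-column TSV; round-trips through :func:`read_substrate_table`."""
    for sset in sets:
        for window in sset.windows:
            sink.write(f"{sset.protease_id}\t{window.residues}\n")


def window_from_sequence(protein: str, cleavage_after: int) -> SubstrateWindow:
    """Extract the P4..P4' window around the bond following residue ``cleavage_after``.

    ``cleavage_after`` is 1-based: the scissile bond lies between residues
    ``cleavage_after`` (P1) and ``cleavage_after + 1`` (P1').  Positions that
    fall outside the protein are padded with the gap symbol.
    """
    protein = protein.upper()
    bad = set(protein) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"illegal residue(s) {sorted(bad)} in protein sequence")
    if not 1 <= cleavage_after <= len(protein) - 1:
        raise ValueError(
            f"cleavage_after={cleavage_after} out of range: a bond needs residues on "
            f"both sides of it (protein length {len(protein)})"
        )
    chars = []
    for offset in range(-3, 5):  # P4..P4' are residues cleavage_after-3 .. +4
        idx = cleavage_after + offset - 1  # 0-based
        chars.append(protein[idx] if 0 <= idx < len(protein) else GAP)
    return SubstrateWindow("".join(chars))


def export_pfm(sset: SubstrateSet) -> PositionFrequencyMatrix:
    """Tally non-gap residues per position into a position frequency matrix."""
    counts = np.zeros((len(AMINO_ACIDS), WINDOW_LENGTH), dtype=np.int64)
    for window in sset.windows:
        for pos, symbol in enumerate(window.residues):
            if symbol != GAP:
                counts[AA_INDEX[symbol], pos] += 1
    return PositionFrequencyMatrix(counts)


def encode_windows(windows: Sequence[SubstrateWindow]) -> np.ndarray:
    """Integer-encode windows into an (n, 8) array; gap encodes as -1."""
    arr = np.full((len(windows), WINDOW_LENGTH), -1, dtype=np.int8)
    for i, window in enumerate(windows):
        for j, symbol in enumerate(window.residues):
            if symbol != GAP:
                arr[i, j] = AA_INDEX[symbol]
    return arr
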