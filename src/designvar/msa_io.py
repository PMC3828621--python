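"""Aligned-FASTA I/O, reference-based site mapping, and per-column counts.

An :class:`Alignment` is a list of equal-length residue strings with one row
designated as the *reference*: the sequence whose ungapped residues correspond
one-to-one to positions on the native structure. The :class:`SiteMap` records
that correspondence (0-based alignment column -> 1-based structure position);
columns where the reference is gapped are dropped from all downstream
statistics. Per-column amino-acid counts exclude gaps and unknown characters,
so frequencies downstream are renormalised over observed residues only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Fixed ordering of the 20 canonical residues used for every count/frequency
#: matrix in the package. Index j of any 20-vector refers to this ordering.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class AminoAcidAlphabet:
    """The 20-letter amino-acid alphabet plus gap/unknown character policy."""

    letters: str = CANONICAL_AA
    gap_symbols: frozenset[str] = frozenset({"-", "."})
    unknown_symbols: frozenset[str] = frozenset({"X", "B", "Z", "J", "U", "O"})

    def __post_init__(self) -> None:
        if len(self.letters) != 20 or len(set(self.letters)) != 20:
            raise ValueError("alphabet must contain exactly 20 distinct letters")

    def index(self, aa: str) -> int:
        return self.letters.index(aa)

    def classify(self, ch: str) -> str:
        """Return 'canonical', 'gap', or 'unknown' for a single character."""
        if ch in self.letters:
            return "canonical"
        if ch in self.gap_symbols:
            return "gap"
        return "unknown"


DEFAULT_ALPHABET = AminoAcidAlphabet()


@dataclass
class Alignment:
    """Equal-length sequence records with a designated reference row.

    Parameters
    ----------
    records
        ``(id, sequence)`` pairs, all sequences of identical aligned length.
    reference_id
        Id of the row whose ungapped sequence matches the native structure.
    source_label
        Free tag such as ``"natural"``, ``"designed"`` or ``"hybrid"``.
    condition
        Optional design-condition tag (``"FB"``, ``"T=0.6"``, ...).
    """

    records: list[tuple[str, str]]
    reference_id: str
    source_label: str = "unlabeled"
    condition: str | None = None

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("alignment needs at least 2 records")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        ids = [rid for rid, _ in self.records]
        if self.reference_id not in ids:
            raise ValueError(f"reference_id {self.reference_id!r} not among records")

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def reference_seq(self) -> str:
        for rid, seq in self.records:
            if rid == self.reference_id:
                return seq
        raise AssertionError("unreachable: validated in __post_init__")

    def column(self, i: int) -> str:
        return "".join(seq[i] for _, seq in self.records)


@dataclass(frozen=True)
class SiteMap:
    """Ordered pairs (alignment_column 0-based, structure_position 1-based)."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        cols = [c for c, _ in self.pairs]
        pos = [p for _, p in self.pairs]
        if cols != sorted(set(cols)) or pos != sorted(set(pos)):
            raise ValueError("site map columns/positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def columns(self) -> list[int]:
        return [c for c, _ in self.pairs]

    @property
    def positions(self) -> list[int]:
        return [p for _, p in self.pairs]


@dataclass
class CountMatrix:
    """Per-site 20-letter residue counts at mapped structure positions.

    ``counts[i, j]`` is the number of sequences carrying canonical residue
    ``alphabet.letters[j]`` at mapped site ``i``; gaps and unknowns are not
    counted, so ``site_totals[i] <= n_records``.
    """

    counts: np.ndarray  # (L, 20) int
    site_totals: np.ndarray  # (L,) int
    positions: np.ndarray  # (L,) structure positions, 1-based
    alphabet: AminoAcidAlphabet = field(default_factory=AminoAcidAlphabet)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.site_totals = np.asarray(self.site_totals, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.counts.shape != (len(self.site_totals), 20):
            raise ValueError("counts must be L x 20")
        if not np.array_equal(self.counts.sum(axis=1), self.site_totals):
            raise ValueError("row sums must equal site_totals")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]


def read_alignment(
    path,
    reference_id: str = "first",
    source_label: str = "unlabeled",
    condition: str | None = None,
    alphabet: AminoAcidAlphabet = DEFAULT_ALPHABET,
) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    ``reference_id="first"`` designates the first record as reference.
    Parsing is case-insensitive; characters outside the canonical/gap/unknown
    sets are mapped to ``'X'`` with a logged warning count.
    """
    records: list[tuple[str, str]] = []
    n_mapped_unknown = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        cleaned = []
        for ch in seq:
            if (
                ch in alphabet.letters
                or ch in alphabet.gap_symbols
                or ch in alphabet.unknown_symbols
            ):
                cleaned.append(ch)
            else:
                cleaned.append("X")
                n_mapped_unknown += 1
        records.append((rec.id, "".join(cleaned)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if n_mapped_unknown:
        logger.warning(
            "%d unrecognized characters mapped to 'X' while reading %s",
            n_mapped_unknown,
            path,
        )
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        offender = next(
            rid for rid, s in records if len(s) != len(records[0][1])
        )
        raise ValueError(
            f"ragged alignment in {path}: record {offender!r} has a different length"
        )
    ref = records[0][0] if reference_id == "first" else reference_id
    if ref not in {rid for rid, _ in records}:
        raise ValueError(f"reference_id {ref!r} not found in {path}")
    return Alignment(records, ref, source_label=source_label, condition=condition)


def write_alignment(aln: Alignment, path) -> None:
    """Write an alignment as FASTA, reference row first so that re-reading
    with ``reference_id='first'`` round-trips the reference designation."""
    ordered = [(rid, s) for rid, s in aln.records if rid == aln.reference_id]
    ordered += [(rid, s) for rid, s in aln.records if rid != aln.reference_id]
    seq_records = [
        SeqRecord(Seq(s), id=rid, description="") for rid, s in ordered
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def build_site_map(aln: Alignment, alphabet: AminoAcidAlphabet = DEFAULT_ALPHABET) -> SiteMap:
    """Map alignment columns to 1-based structure positions of the reference.

    One pair per non-gap reference character; reference-gapped columns are
    excluded from all downstream statistics.
    """
    pairs = []
    pos = 0
    for col, ch in enumerate(aln.reference_seq):
        if ch in alphabet.gap_symbols:
            continue
        pos += 1
        pairs.append((col, pos))
    if not pairs:
        raise ValueError("reference sequence consists only of gaps")
    return SiteMap(tuple(pairs))


def column_counts(
    aln: Alignment,
    site_map: SiteMap,
    alphabet: AminoAcidAlphabet = DEFAULT_ALPHABET,
) -> CountMatrix:
    """Count canonical residues per mapped column, excluding gaps/unknowns.

    Sites where no sequence carries a countable residue are dropped with a
    warning (they cannot support a frequency estimate).
    """
    idx = {aa: j for j, aa in enumerate(alphabet.letters)}
    rows, totals, positions = [], [], []
    n_empty = 0
    for col, pos in site_map.pairs:
        row = np.zeros(20, dtype=np.int64)
        for ch in aln.column(col):
            j = idx.get(ch)
            if j is not None:
                row[j] += 1
        if row.sum() == 0:
            n_empty += 1
            continue
        rows.append(row)
        totals.append(int(row.sum()))
        positions.append(pos)
    if n_empty:
        logger.warning("%d mapped sites had no countable residues; excluded", n_empty)
    return CountMatrix(
        np.array(rows, dtype=np.int64).reshape(len(rows), 20),
        np.array(totals, dtype=np.int64),
        np.array(positions, dtype=np.int64),
        alphabet=alphabet,
    )
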