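"""Derive a flexible-gap motif from aligned functional-center sequences.

The input is a gapped alignment of the key region (e.g. the heme-binding
centers of NO-responsive domains from several species) together with a
set of *critical columns*: alignment columns that carry functionally
annotated residues and must be unanimous across rows.  Each critical
column becomes a fixed token; each stretch between consecutive critical
columns becomes a bounded gap whose limits are the min/max number of
non-gap characters any row places there.  Applied to an alignment whose
critical columns hold H, P, Y, S, R with intervening stretch counts of
12, 14-16, 1, 1 this yields ``Hx(12)Px(14,16)YxSxR``.

Critical columns are user-supplied functional annotation, not inferred
by conservation scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, TextIO

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .motif import Motif, MotifError, _merge_gaps, fixed, gap

GAP_CHARS = frozenset("-.")


class AlignmentError(ValueError):
    """Alignment that cannot support motif extraction."""


@dataclass(frozen=True)
class AlignmentRow:
    row_id: str
    aligned: str


@dataclass(frozen=True)
class CenterAlignment:
    """Equal-length gapped rows plus 1-based critical column indices."""

    rows: tuple[AlignmentRow, ...]
    critical_columns: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("alignment has no rows")
        if not self.critical_columns:
            raise AlignmentError("no critical columns given")
        if list(self.critical_columns) != sorted(set(self.critical_columns)):
            raise AlignmentError("critical columns must be strictly increasing")

    @property
    def width(self) -> int:
        return len(self.rows[0].aligned)

    def column(self, col: int) -> list[str]:
        """Characters in 1-based column ``col``."""
        return [r.aligned[col - 1] for r in self.rows]


def read_alignment(
    source: str | Path | TextIO, critical_columns: Sequence[int]
) -> CenterAlignment:
    """Load an aligned FASTA (rows may contain ``-``/``.`` gaps)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_alignment(fh, critical_columns)
    rows = []
    for title, seq in SimpleFastaParser(source):
        row_id = title.split(None, 1)[0] if title.split() else "<unnamed>"
        rows.append(AlignmentRow(row_id, seq.replace(" ", "").upper()))
    return CenterAlignment(tuple(rows), tuple(int(c) for c in critical_columns))


def validate_alignment(alignment: CenterAlignment) -> list[str]:
    """Report every violation of the motif-extraction preconditions.

    An empty report means :func:`build_motif` will succeed.  Entries cover
    row-length mismatches, empty rows, out-of-range / gap-bearing /
    non-unanimous critical columns, and zero-length gap stretches.
    """
    report: list[str] = []
    width = alignment.width
    for row in alignment.rows:
        if not row.aligned:
            report.append(f"row {row.row_id!r} is empty")
        elif len(row.aligned) != width:
            report.append(
                f"row {row.row_id!r} has length {len(row.aligned)}, expected {width}"
            )
    if report:
        return report  # column checks are meaningless on ragged rows

    for col in alignment.critical_columns:
        if not (1 <= col <= width):
            report.append(f"critical column {col} outside alignment width {width}")
            continue
        chars = set(alignment.column(col))
        if chars & GAP_CHARS:
            report.append(f"critical column {col} contains a gap character")
        residues = sorted(chars - GAP_CHARS)
        if len(residues) > 1:
            report.append(
                f"critical column {col} is not unanimous: {{{', '.join(residues)}}}"
            )

    cols = [c for c in alignment.critical_columns if 1 <= c <= width]
    for a, b in zip(cols, cols[1:]):
        for row in alignment.rows:
            stretch = row.aligned[a : b - 1]
            if sum(1 for ch in stretch if ch not in GAP_CHARS) == 0 and b - a > 1:
                report.append(
                    f"zero-length stretch between columns {a} and {b} "
                    f"in row {row.row_id!r}"
                )
            elif b - a == 1:
                pass  # adjacent critical columns: no gap token emitted
    return report


def build_motif(alignment: CenterAlignment) -> Motif:
    """Extract the consensus flexible-gap motif from the alignment.

    Raises AlignmentError (naming the column and residues involved) if any
    critical column is non-unanimous or gap-bearing, or if a between-column
    stretch has zero residues in some row, which would break the anchored
    gap(min>=1) semantics.
    """
    problems = validate_alignment(alignment)
    if problems:
        raise AlignmentError("; ".join(problems))
    tokens = []
    cols = alignment.critical_columns
    for i, col in enumerate(cols):
        residue = next(ch for ch in alignment.column(col) if ch not in GAP_CHARS)
        try:
            tokens.append(fixed(residue))
        except MotifError as exc:
            raise AlignmentError(f"critical column {col}: {exc}") from exc
        if i + 1 < len(cols):
            nxt = cols[i + 1]
            if nxt - col == 1:
                continue
            counts = [
                sum(1 for ch in row.aligned[col : nxt - 1] if ch not in GAP_CHARS)
                for row in alignment.rows
            ]
            tokens.append(gap(min(counts), max(counts)))
    return Motif(tuple(_merge_gaps(tokens)))
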