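"""Scan protein sequences with a flexible-gap motif and aggregate candidates.

Coordinates are 1-based and inclusive throughout, mirroring the residue
numbering used for protein annotation (e.g. a histidine reported at
position 357).  Matching enumerates *realizations*: a match is a concrete
choice of start position and gap lengths under which every fixed token
agrees with the sequence.  Sequence letters outside the 20 standard codes
(X, B, Z, U, O, ...) may occupy gap positions but never satisfy a fixed
token.  ``*`` acts as a hard segment break: no match crosses it.

Candidates are aggregated at two levels: distinct matching sequence IDs
(gene models), and loci after collapsing AGI-style gene-model suffixes
(``At4g01160.1`` and ``At4g01160.2`` collapse to locus ``AT4G01160``).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .motif import Motif, span_bounds

ALL_REALIZATIONS = "ALL_REALIZATIONS"
LEFTMOST_SHORTEST_PER_ANCHOR = "LEFTMOST_SHORTEST_PER_ANCHOR"
_POLICIES = (ALL_REALIZATIONS, LEFTMOST_SHORTEST_PER_ANCHOR)

_AGI_RE = re.compile(r"^AT[1-5CM]G\d{5}(\.\d+)?$", re.IGNORECASE)


class ScanError(ValueError):
    """Invalid input to the scanner."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its identifier and description line."""

    seq_id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ScanError(f"record {self.seq_id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def segments(self) -> list[tuple[int, str]]:
        """(0-based offset, subsequence) pieces between ``*`` terminators."""
        out = []
        start = 0
        for i, ch in enumerate(self.sequence):
            if ch == "*":
                if i > start:
                    out.append((start, self.sequence[start:i]))
                start = i + 1
        if len(self.sequence) > start:
            out.append((start, self.sequence[start:]))
        return out


@dataclass(frozen=True)
class Match:
    """One realization of a motif on a sequence.

    ``start``/``end`` are 1-based inclusive; ``gap_lengths`` gives the
    realized length of each GAP token in order; ``key_residues`` maps each
    fixed-token label (letter + per-letter ordinal, e.g. ``"H1"``) to its
    1-based position.
    """

    seq_id: str
    start: int
    end: int
    gap_lengths: tuple[int, ...]
    key_residues: dict[str, int] = field(hash=False)

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# FASTA input

def read_fasta(source: str | Path | TextIO) -> list[ProteinRecord]:
    """Read a multi-record FASTA into sanitized :class:`ProteinRecord` objects.

    Sequences are upper-cased; whitespace and digits are stripped; ``-``
    and ``.`` are stripped with a warning; ``*`` is kept as a segment
    break.  Raises on an empty file or on records with empty sequences,
    listing the offenders; duplicate IDs are allowed but warned about.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_fasta(fh)
    records: list[ProteinRecord] = []
    empty: list[str] = []
    seen: set[str] = set()
    stripped_aln = False
    for title, seq in SimpleFastaParser(source):
        parts = title.split(None, 1)
        seq_id = parts[0] if parts else ""
        desc = parts[1] if len(parts) > 1 else ""
        seq = re.sub(r"[\s\d]", "", seq).upper()
        if "-" in seq or "." in seq:
            stripped_aln = True
            seq = seq.replace("-", "").replace(".", "")
        if not seq or not seq.strip("*"):
            empty.append(seq_id or "<unnamed>")
            continue
        if seq_id in seen:
            warnings.warn(f"duplicate FASTA id {seq_id!r}", stacklevel=2)
        seen.add(seq_id)
        records.append(ProteinRecord(seq_id, desc, seq))
    if stripped_aln:
        warnings.warn("alignment characters '-'/'.' stripped from sequences", stacklevel=2)
    if empty:
        raise ScanError(f"records with empty sequences: {', '.join(empty)}")
    if not records:
        raise ScanError("no records found in FASTA input")
    return records


# ---------------------------------------------------------------------------
# matching

def _key_positions(motif: Motif, start: int, gap_lengths: Sequence[int]) -> dict[str, int]:
    """Fixed-token positions for a realization anchored at 1-based ``start``."""
    labels = iter(motif.fixed_labels())
    gaps = iter(gap_lengths)
    pos = start
    out: dict[str, int] = {}
    for tok in motif.tokens:
        if tok.is_fixed:
            out[next(labels)] = pos
            pos += 1
        else:
            pos += next(gaps)
    return out


def _scan_segment(motif: Motif, seq: str, offset: int, seq_id: str) -> list[Match]:
    n = len(seq)
    bounds = span_bounds(motif)
    if n < bounds.min_span:
        return []
    first = motif.tokens[0].residue
    tokens = motif.tokens
    matches: list[Match] = []

    def walk(pos: int, ti: int, gaps: list[int]) -> None:
        if ti == len(tokens):
            start = offset + (pos - (sum(gaps) + len(motif.fixed_indices))) + 1
            end = offset + pos
            matches.append(
                Match(
                    seq_id=seq_id,
                    start=start,
                    end=end,
                    gap_lengths=tuple(gaps),
                    key_residues=_key_positions(motif, start, gaps),
                )
            )
            return
        tok = tokens[ti]
        if tok.is_fixed:
            if pos < n and seq[pos] == tok.residue:
                walk(pos + 1, ti + 1, gaps)
        else:
            hi = min(tok.max_len, n - pos)
            for g in range(tok.min_len, hi + 1):
                gaps.append(g)
                walk(pos + g, ti + 1, gaps)
                gaps.pop()

    for s0 in range(n - bounds.min_span + 1):
        if seq[s0] == first:
            walk(s0, 0, [])
    return matches


def find_matches(
    motif: Motif, record: ProteinRecord, policy: str = ALL_REALIZATIONS
) -> list[Match]:
    """Enumerate motif matches on one record.

    ``ALL_REALIZATIONS`` returns every distinct (start, end, gap_lengths)
    triple, ordered by (start, end, gap vector).  With
    ``LEFTMOST_SHORTEST_PER_ANCHOR`` only the lexicographically smallest
    gap vector per anchor start is kept.
    """
    if policy not in _POLICIES:
        raise ScanError(f"unknown policy {policy!r}; choose from {_POLICIES}")
    matches: list[Match] = []
    for offset, seg in record.segments():
        matches.extend(_scan_segment(motif, seg, offset, record.seq_id))
    matches.sort(key=lambda m: (m.start, m.end, m.gap_lengths))
    if policy == LEFTMOST_SHORTEST_PER_ANCHOR:
        best: dict[int, Match] = {}
        for m in matches:
            cur = best.get(m.start)
            if cur is None or m.gap_lengths < cur.gap_lengths:
                best[m.start] = m
        matches = [best[s] for s in sorted(best)]
    return matches


def map_key_residues(
    match: Match, motif: Motif, record: ProteinRecord | None = None
) -> dict[str, int]:
    """Recompute fixed-token positions by token arithmetic and verify them.

    Positions are strictly increasing and, when ``record`` is supplied,
    each is checked to carry the token's letter in the sequence.  Raises
    ScanError on an inconsistent match/motif pairing.
    """
    if len(match.gap_lengths) != motif.n_gaps:
        raise ScanError(
            f"match has {len(match.gap_lengths)} gap lengths but motif "
            f"has {motif.n_gaps} gap tokens"
        )
    expected_end = match.start + len(motif.fixed_indices) + sum(match.gap_lengths) - 1
    if expected_end != match.end:
        raise ScanError(
            f"match span {match.start}-{match.end} inconsistent with gap "
            f"lengths {match.gap_lengths}"
        )
    for gi, g in zip(motif.gap_indices, match.gap_lengths):
        tok = motif.tokens[gi]
        if not (tok.min_len <= g <= tok.max_len):
            raise ScanError(f"gap length {g} outside bounds of token {gi}")
    positions = _key_positions(motif, match.start, match.gap_lengths)
    if record is not None:
        for label, pos in positions.items():
            letter = label.rstrip("0123456789")
            if pos > len(record.sequence) or record.sequence[pos - 1] != letter:
                raise ScanError(
                    f"key residue {label} at {pos} does not carry {letter!r} "
                    f"in {record.seq_id}"
                )
    return positions


def residues_in_span(
    record: ProteinRecord, span: tuple[int, int], letter: str
) -> list[int]:
    """1-based positions of ``letter`` within the inclusive span, ascending.

    Used e.g. to enumerate cysteines inside a matched H-NOX center span
    as candidate S-nitrosylation sites.
    """
    start, end = span
    if not (1 <= start <= end <= len(record.sequence)):
        raise ScanError(
            f"span ({start},{end}) out of range for {record.seq_id} "
            f"of length {len(record.sequence)}"
        )
    letter = letter.upper()
    return [i for i in range(start, end + 1) if record.sequence[i - 1] == letter]


# ---------------------------------------------------------------------------
# proteome-level aggregation

@dataclass
class MatchSet:
    """All matches of one motif over a record collection, plus tallies."""

    motif_text: str
    matches: list[Match]
    per_record: dict[str, int]
    policy: str = ALL_REALIZATIONS

    @property
    def n_matching_records(self) -> int:
        return sum(1 for v in self.per_record.values() if v > 0)

    @property
    def n_realizations(self) -> int:
        return len(self.matches)

    def matching_ids(self) -> list[str]:
        return [k for k, v in self.per_record.items() if v > 0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.matches:
            rows.append(
                {
                    "seq_id": m.seq_id,
                    "locus": normalize_locus(m.seq_id),
                    "start": m.start,
                    "end": m.end,
                    "gap_lengths": ",".join(map(str, m.gap_lengths)),
                    "key_residues": ";".join(
                        f"{k}={v}" for k, v in m.key_residues.items()
                    ),
                }
            )
        cols = ["seq_id", "locus", "start", "end", "gap_lengths", "key_residues"]
        return pd.DataFrame(rows, columns=cols)

    def to_json(self) -> str:
        return json.dumps(
            {
                "motif": self.motif_text,
                "policy": self.policy,
                "n_matching_records": self.n_matching_records,
                "n_realizations": self.n_realizations,
                "matches": [
                    {
                        "seq_id": m.seq_id,
                        "start": m.start,
                        "end": m.end,
                        "gap_lengths": list(m.gap_lengths),
                        "key_residues": m.key_residues,
                    }
                    for m in self.matches
                ],
            },
            indent=2,
        )


def scan_proteome(
    motif: Motif, records: Iterable[ProteinRecord], policy: str = ALL_REALIZATIONS
) -> MatchSet:
    """Scan records in order; output ordering is fully deterministic."""
    all_matches: list[Match] = []
    per_record: dict[str, int] = {}
    for rec in records:
        hits = find_matches(motif, rec, policy)
        per_record[rec.seq_id] = per_record.get(rec.seq_id, 0) + len(hits)
        all_matches.extend(hits)
    from .motif import format_motif

    return MatchSet(format_motif(motif), all_matches, per_record, policy)


def normalize_locus(seq_id: str) -> str:
    """AGI gene-model IDs collapse to their locus (upper-case, suffix stripped)."""
    if _AGI_RE.match(seq_id):
        return re.sub(r"\.\d+$", "", seq_id).upper()
    return seq_id


@dataclass
class CandidateTable:
    """Per-locus aggregation of matches across gene models."""

    rows: list[dict]

    def to_frame(self) -> pd.DataFrame:
        cols = ["locus", "gene_models", "n_gene_models", "n_matches", "spans"]
        out = []
        for r in self.rows:
            out.append(
                {
                    "locus": r["locus"],
                    "gene_models": ",".join(r["gene_models"]),
                    "n_gene_models": len(r["gene_models"]),
                    "n_matches": r["n_matches"],
                    "spans": ";".join(f"{s}-{e}" for s, e in r["spans"]),
                }
            )
        return pd.DataFrame(out, columns=cols)

    @property
    def n_loci(self) -> int:
        return len(self.rows)


def collapse_to_loci(matchset: MatchSet) -> CandidateTable:
    """Group matching gene models under their locus; rows sorted by locus."""
    by_locus: dict[str, dict] = {}
    for m in matchset.matches:
        locus = normalize_locus(m.seq_id)
        row = by_locus.setdefault(
            locus, {"locus": locus, "gene_models": [], "n_matches": 0, "spans": []}
        )
        if m.seq_id not in row["gene_models"]:
            row["gene_models"].append(m.seq_id)
        row["n_matches"] += 1
        row["spans"].append((m.start, m.end))
    return CandidateTable([by_locus[k] for k in sorted(by_locus)])
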