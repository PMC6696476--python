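"""Flexible-gap protein motifs: parse, format, relax, and reason about them.

A motif is an ordered list of tokens, each either a FIXED one-letter residue
or a bounded wildcard GAP written ``x``, ``x(n)`` or ``x(n,m)``.  The dialect
is the one used for H-NOX-center searches, e.g. ``Hx(12)Px(14,16)YxSxR``:
a histidine, exactly 12 arbitrary residues, a proline, 14 to 16 arbitrary
residues, then the YxSxR signature.  Motifs are *anchored*: the first and
last tokens are always fixed residues, so a match has a well-defined span.

Canonical form merges adjacent gaps (summing both bounds) and renders
``gap(1,1)`` as ``x`` and ``gap(n,n)`` as ``x(n)``.  Relaxing a motif —
turning an interior fixed residue into a wildcard, as in dropping the
proline to obtain ``Hx(27,29)YxSxR`` — only ever widens the matched
language and preserves the span bounds.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

FIXED = "FIXED"
GAP = "GAP"


class MotifError(ValueError):
    """Invalid motif structure or operation."""


class MotifParseError(MotifError):
    """Motif text that does not conform to the grammar."""


@dataclass(frozen=True)
class MotifToken:
    """One motif element: a fixed residue or a bounded gap.

    FIXED tokens carry a single uppercase standard amino-acid letter and
    have implicit length 1.  GAP tokens carry inclusive length bounds
    ``1 <= min_len <= max_len``.
    """

    kind: str
    residue: str | None = None
    min_len: int = 1
    max_len: int = 1

    def __post_init__(self) -> None:
        if self.kind == FIXED:
            if self.residue not in STANDARD_AA:
                raise MotifError(
                    f"fixed token residue {self.residue!r} is not one of the "
                    f"20 standard amino-acid letters"
                )
            if (self.min_len, self.max_len) != (1, 1):
                raise MotifError("fixed tokens have implicit length 1")
        elif self.kind == GAP:
            if self.residue is not None:
                raise MotifError("gap tokens carry no residue")
            if not (1 <= self.min_len <= self.max_len):
                raise MotifError(
                    f"gap bounds must satisfy 1 <= min <= max, "
                    f"got ({self.min_len},{self.max_len})"
                )
        else:
            raise MotifError(f"unknown token kind {self.kind!r}")

    @property
    def is_fixed(self) -> bool:
        return self.kind == FIXED

    @property
    def is_gap(self) -> bool:
        return self.kind == GAP


def fixed(residue: str) -> MotifToken:
    return MotifToken(FIXED, residue.upper())


def gap(min_len: int, max_len: int | None = None) -> MotifToken:
    return MotifToken(GAP, None, min_len, max_len if max_len is not None else min_len)


@dataclass(frozen=True)
class SpanBounds:
    """Inclusive bounds on the residue span a motif can cover."""

    min_span: int
    max_span: int

    def __post_init__(self) -> None:
        if not (1 <= self.min_span <= self.max_span):
            raise MotifError("span bounds must satisfy 1 <= min <= max")

    def __contains__(self, length: int) -> bool:
        return self.min_span <= length <= self.max_span


@dataclass(frozen=True)
class Motif:
    """An anchored flexible-gap motif in canonical form."""

    tokens: tuple[MotifToken, ...]
    source_text: str = ""

    def __post_init__(self) -> None:
        if not self.tokens:
            raise MotifError("motif has no tokens")
        if not (self.tokens[0].is_fixed and self.tokens[-1].is_fixed):
            raise MotifError("motif must start and end with a fixed residue")
        for a, b in zip(self.tokens, self.tokens[1:]):
            if a.is_gap and b.is_gap:
                raise MotifError("adjacent gaps are not canonical (merge them)")

    # -- structure helpers -------------------------------------------------

    @property
    def fixed_indices(self) -> tuple[int, ...]:
        return tuple(i for i, t in enumerate(self.tokens) if t.is_fixed)

    @property
    def gap_indices(self) -> tuple[int, ...]:
        return tuple(i for i, t in enumerate(self.tokens) if t.is_gap)

    @property
    def n_gaps(self) -> int:
        return len(self.gap_indices)

    def fixed_labels(self) -> tuple[str, ...]:
        """Label each fixed token as letter + per-letter ordinal, e.g. H1, S2."""
        seen: dict[str, int] = {}
        labels = []
        for i in self.fixed_indices:
            letter = self.tokens[i].residue
            seen[letter] = seen.get(letter, 0) + 1
            labels.append(f"{letter}{seen[letter]}")
        return tuple(labels)

    def find_fixed(self, letter: str) -> tuple[int, ...]:
        """Token indices of fixed tokens carrying ``letter``."""
        letter = letter.upper()
        return tuple(
            i for i, t in enumerate(self.tokens) if t.is_fixed and t.residue == letter
        )

    def gap_vectors(self) -> Iterator[tuple[int, ...]]:
        """All realized gap-length vectors, in lexicographic order."""
        ranges = [
            range(self.tokens[i].min_len, self.tokens[i].max_len + 1)
            for i in self.gap_indices
        ]
        return itertools.product(*ranges)

    def __str__(self) -> str:
        return format_motif(self)


# ---------------------------------------------------------------------------
# parsing / formatting

_TOKEN_RE = re.compile(r"([A-Za-z])(\((\d+)(?:,(\d+))?\))?")


def parse_motif(text: str) -> Motif:
    """Parse motif text such as ``"Hx(12)Px(14,16)YxSxR"`` into canonical form.

    ``x`` (case-insensitive) is a gap of length 1; ``x(n)`` and ``x(n,m)``
    are bounded gaps.  Any other letter is a fixed residue and must be one
    of the 20 standard codes (parse is case-insensitive, canonical output
    uppercase).  Adjacent gaps are merged.  Raises :class:`MotifParseError`
    naming the offending token on malformed input.
    """
    if not text or not text.strip():
        raise MotifParseError("empty motif text")
    text = text.strip()
    tokens: list[MotifToken] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise MotifParseError(
                f"unexpected character {text[pos]!r} at position {pos + 1} in {text!r}"
            )
        letter, bounds, lo, hi = m.group(1), m.group(2), m.group(3), m.group(4)
        if letter in ("x", "X"):
            if bounds is None:
                tokens.append(gap(1, 1))
            else:
                n = int(lo)
                mx = int(hi) if hi is not None else n
                if n == 0:
                    raise MotifParseError(f"gap bound 0 in token {m.group(0)!r}")
                if mx < n:
                    raise MotifParseError(
                        f"inverted gap bounds ({n},{mx}) in token {m.group(0)!r}"
                    )
                tokens.append(gap(n, mx))
        else:
            if bounds is not None:
                raise MotifParseError(
                    f"length bounds on fixed residue in token {m.group(0)!r}"
                )
            upper = letter.upper()
            if upper not in STANDARD_AA:
                raise MotifParseError(
                    f"unknown residue letter {letter!r} at position {pos + 1}"
                )
            tokens.append(fixed(upper))
        pos = m.end()
    merged = _merge_gaps(tokens)
    if merged[0].is_gap:
        raise MotifParseError(f"motif {text!r} starts with a gap (must be anchored)")
    if merged[-1].is_gap:
        raise MotifParseError(f"motif {text!r} ends with a gap (must be anchored)")
    return Motif(tuple(merged), source_text=text)


def _merge_gaps(tokens: Sequence[MotifToken]) -> list[MotifToken]:
    out: list[MotifToken] = []
    for tok in tokens:
        if tok.is_gap and out and out[-1].is_gap:
            prev = out.pop()
            out.append(gap(prev.min_len + tok.min_len, prev.max_len + tok.max_len))
        else:
            out.append(tok)
    return out


def format_motif(motif: Motif) -> str:
    """Render a motif in canonical text: ``gap(1,1)``→``x``, ``gap(n,n)``→``x(n)``."""
    parts = []
    for tok in motif.tokens:
        if tok.is_fixed:
            parts.append(tok.residue)
        elif (tok.min_len, tok.max_len) == (1, 1):
            parts.append("x")
        elif tok.min_len == tok.max_len:
            parts.append(f"x({tok.min_len})")
        else:
            parts.append(f"x({tok.min_len},{tok.max_len})")
    return "".join(parts)


# ---------------------------------------------------------------------------
# algebra

def span_bounds(motif: Motif) -> SpanBounds:
    """Sum of per-token length bounds; the residue span any match must obey."""
    lo = sum(1 if t.is_fixed else t.min_len for t in motif.tokens)
    hi = sum(1 if t.is_fixed else t.max_len for t in motif.tokens)
    return SpanBounds(lo, hi)


def relax(motif: Motif, token_index: int) -> Motif:
    """Turn the interior fixed token at ``token_index`` into a wildcard.

    The dropped residue becomes ``gap(1,1)`` and is merged with any adjacent
    gaps by summing lower and upper bounds, so e.g. omitting the proline from
    ``Hx(12)Px(14,16)YxSxR`` yields ``Hx(27,29)YxSxR``.  The result matches
    everything the input matched (and more); span bounds are unchanged.
    """
    if not (0 <= token_index < len(motif.tokens)):
        raise MotifError(f"token index {token_index} out of range")
    tok = motif.tokens[token_index]
    if not tok.is_fixed:
        raise MotifError(f"token at index {token_index} is a gap, not a fixed residue")
    if token_index in (0, len(motif.tokens) - 1):
        raise MotifError("cannot relax an anchor (first/last) token")
    tokens = list(motif.tokens)
    tokens[token_index] = gap(1, 1)
    return Motif(tuple(_merge_gaps(tokens)))


def relax_letter(motif: Motif, letter: str) -> Motif:
    """Relax the unique interior fixed token carrying ``letter``."""
    interior = [i for i in motif.find_fixed(letter) if 0 < i < len(motif.tokens) - 1]
    if not interior:
        raise MotifError(f"no interior fixed token {letter!r} to relax")
    if len(interior) > 1:
        raise MotifError(
            f"fixed token {letter!r} is ambiguous (indices {interior}); "
            f"relax by index instead"
        )
    return relax(motif, interior[0])


# ---------------------------------------------------------------------------
# language enumeration (exhaustive oracle support)

def realization_length(motif: Motif, gap_vector: Sequence[int]) -> int:
    if len(gap_vector) != motif.n_gaps:
        raise MotifError("gap vector length does not match motif")
    return len(motif.fixed_indices) + sum(gap_vector)


def realize(motif: Motif, gap_vector: Sequence[int], fill: str = "A") -> str:
    """One concrete string matched by the motif, gaps filled with ``fill``."""
    gaps = list(gap_vector)
    out = []
    for tok in motif.tokens:
        if tok.is_fixed:
            out.append(tok.residue)
        else:
            n = gaps.pop(0)
            if not (tok.min_len <= n <= tok.max_len):
                raise MotifError(f"gap length {n} outside ({tok.min_len},{tok.max_len})")
            out.append(fill * n)
    return "".join(out)


def full_match(motif: Motif, s: str) -> bool:
    """True iff the whole string ``s`` is one realization of ``motif``."""
    n = len(s)
    if n not in span_bounds(motif):
        return False

    def walk(pos: int, ti: int) -> bool:
        if ti == len(motif.tokens):
            return pos == n
        tok = motif.tokens[ti]
        if tok.is_fixed:
            return pos < n and s[pos] == tok.residue and walk(pos + 1, ti + 1)
        return any(
            walk(pos + g, ti + 1)
            for g in range(tok.min_len, min(tok.max_len, n - pos) + 1)
        )

    return walk(0, 0)


def enumerate_language(
    motif: Motif, alphabet: Sequence[str], max_len: int, budget: int = 500_000
) -> Iterator[str]:
    """All strings of length <= max_len matched in full by ``motif``.

    Enumerates gap vectors and every alphabet assignment of the gap
    positions.  Refuses explicitly (raises MotifError) if the number of
    strings would exceed ``budget`` — never truncates silently.
    """
    alphabet = sorted(set(a.upper() for a in alphabet))
    total = 0
    vectors = []
    for gv in motif.gap_vectors():
        length = realization_length(motif, gv)
        if length > max_len:
            continue
        total += len(alphabet) ** sum(gv)
        vectors.append(gv)
    if total > budget:
        raise MotifError(
            f"language enumeration needs {total} strings, over the budget of {budget}"
        )
    for gv in vectors:
        slots = sum(gv)
        for letters in itertools.product(alphabet, repeat=slots):
            it = iter(letters)
            parts = []
            gaps = list(gv)
            for tok in motif.tokens:
                if tok.is_fixed:
                    parts.append(tok.residue)
                else:
                    parts.append("".join(next(it) for _ in range(gaps.pop(0))))
            yield "".join(parts)


def language_contains(
    outer: Motif,
    inner: Motif,
    alphabet: Sequence[str],
    max_len: int,
    budget: int = 500_000,
) -> bool:
    """Exhaustively check that outer's language includes inner's, up to max_len.

    Strings not matched by ``inner`` cannot witness a violation, so it
    suffices to enumerate inner's language and test each member against
    ``outer``.  Raises MotifError if the enumeration exceeds ``budget``.
    """
    return all(
        full_match(outer, s) for s in enumerate_language(inner, alphabet, max_len, budget)
    )


# ---------------------------------------------------------------------------
# JSON serialization

def motif_to_json(motif: Motif) -> str:
    items = []
    for tok in motif.tokens:
        if tok.is_fixed:
            items.append({"kind": "FIXED", "residue": tok.residue, "min": 1, "max": 1})
        else:
            items.append(
                {"kind": "GAP", "residue": None, "min": tok.min_len, "max": tok.max_len}
            )
    return json.dumps({"tokens": items, "text": format_motif(motif)}, indent=2)


def motif_from_json(data: str) -> Motif:
    obj = json.loads(data)
    tokens = []
    for item in obj["tokens"]:
        if item["kind"] == "FIXED":
            tokens.append(fixed(item["residue"]))
        elif item["kind"] == "GAP":
            tokens.append(gap(int(item["min"]), int(item["max"])))
        else:
            raise MotifError(f"unknown token kind {item['kind']!r} in JSON")
    return Motif(tuple(_merge_gaps(tokens)))
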