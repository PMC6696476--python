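"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import settings

from hnox_scout.motif import Motif, parse_motif

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")


STRICT_TEXT = "Hx(12)Px(14,16)YxSxR"
RELAXED_TEXT = "Hx(27,29)YxSxR"


@pytest.fixture
def strict_motif() -> Motif:
    return parse_motif(STRICT_TEXT)


@pytest.fixture
def relaxed_motif() -> Motif:
    return parse_motif(RELAXED_TEXT)


def brute_force_matches(motif: Motif, seq: str) -> list[tuple[int, int, tuple[int, ...]]]:
    """Exhaustive (start, gap-vector) oracle for full-token motif matching.

    Independent of the scanner: flat enumeration over every start position
    and every gap-length combination, with plain offset arithmetic.
    Returns sorted (start, end, gaps) triples, 1-based inclusive.
    """
    gap_ranges = [
        range(tok.min_len, tok.max_len + 1) for tok in motif.tokens if tok.is_gap
    ]
    hits = []
    for start0 in range(len(seq)):
        for gv in itertools.product(*gap_ranges):
            pos = start0
            gi = 0
            ok = True
            for tok in motif.tokens:
                if tok.is_fixed:
                    if pos >= len(seq) or seq[pos] != tok.residue:
                        ok = False
                        break
                    pos += 1
                else:
                    pos += gv[gi]
                    gi += 1
                    if pos > len(seq):
                        ok = False
                        break
            if ok:
                hits.append((start0 + 1, pos, gv))
    return sorted(hits)
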