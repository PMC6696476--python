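"""Proteome scanning: FASTA input, realization enumeration, aggregation."""

from __future__ import annotations

import io

import numpy as np
import pytest

from hnox_scout.motif import parse_motif, span_bounds
from hnox_scout.scan import (
    ALL_REALIZATIONS,
    LEFTMOST_SHORTEST_PER_ANCHOR,
    Match,
    ProteinRecord,
    ScanError,
    collapse_to_loci,
    find_matches,
    map_key_residues,
    normalize_locus,
    read_fasta,
    residues_in_span,
    scan_proteome,
)

from conftest import brute_force_matches


TOY_36MER = "M" + "H" + "A" * 12 + "P" + "A" * 16 + "YASAR"


class TestReadFasta:
    def test_two_record_toy_file(self):
        text = ">a first protein\nMKV\n>b\nhhpy\n"
        records = read_fasta(io.StringIO(text))
        assert [(r.seq_id, r.sequence) for r in records] == [("a", "MKV"), ("b", "HHPY")]
        assert records[0].description == "first protein"

    def test_wrapped_and_numbered_sequences_are_sanitized(self):
        text = ">a\n  1 mkvh\n 61 pqr\n"
        (rec,) = read_fasta(io.StringIO(text))
        assert rec.sequence == "MKVHPQR"

    def test_header_only_file_errors(self):
        with pytest.raises(ScanError, match="empty"):
            read_fasta(io.StringIO(">\n"))

    def test_empty_file_errors(self):
        with pytest.raises(ScanError, match="no records"):
            read_fasta(io.StringIO(""))

    def test_duplicate_ids_warn_but_load(self):
        text = ">a\nMK\n>a\nVH\n"
        with pytest.warns(UserWarning, match="duplicate"):
            records = read_fasta(io.StringIO(text))
        assert len(records) == 2

    def test_alignment_characters_stripped_with_warning(self):
        with pytest.warns(UserWarning, match="stripped"):
            (rec,) = read_fasta(io.StringIO(">a\nM-K.V\n"))
        assert rec.sequence == "MKV"


class TestFindMatches:
    def test_toy_36mer_single_realization(self, strict_motif):
        rec = ProteinRecord("toy", "", TOY_36MER)
        (m,) = find_matches(strict_motif, rec)
        assert (m.start, m.end, m.gap_lengths) == (2, 36, (12, 16, 1, 1))
        assert m.key_residues == {"H1": 2, "P1": 15, "Y1": 32, "S1": 34, "R1": 36}

    def test_sequence_shorter_than_min_span_has_no_match(self, strict_motif):
        assert find_matches(strict_motif, ProteinRecord("s", "", "HPYSR")) == []

    def test_two_anchors_can_share_one_end(self, strict_motif):
        # HH then PP lets gap choices 15 (first H) and 14 (second H) land on
        # the same YxSxR block
        seq = "HH" + "A" * 11 + "PP" + "A" * 14 + "YASAR"
        matches = find_matches(strict_motif, ProteinRecord("d", "", seq))
        assert [(m.start, m.end, m.gap_lengths) for m in matches] == [
            (1, 34, (12, 15, 1, 1)),
            (2, 34, (12, 14, 1, 1)),
        ]

    def test_leftmost_shortest_policy_keeps_one_per_anchor(self, relaxed_motif):
        # two YxSxR frames reachable from a single H anchor (gaps 28 and 29)
        seq = "H" + "A" * 27 + "YYSSRR" + "AAA"
        rec = ProteinRecord("p", "", seq)
        all_hits = find_matches(relaxed_motif, rec, ALL_REALIZATIONS)
        kept = find_matches(relaxed_motif, rec, LEFTMOST_SHORTEST_PER_ANCHOR)
        assert len(all_hits) > len(kept) == 1
        assert kept[0].gap_lengths == min(m.gap_lengths for m in all_hits)

    def test_nonstandard_letters_fill_gaps_but_never_fixed_positions(self):
        m = parse_motif("HxR")
        assert find_matches(m, ProteinRecord("g", "", "HXR"))  # X inside the gap
        assert not find_matches(parse_motif("HAR"), ProteinRecord("f", "", "HXR"))

    def test_star_is_a_hard_segment_break(self, relaxed_motif):
        inner = "H" + "A" * 28 + "YASAR"
        assert find_matches(relaxed_motif, ProteinRecord("w", "", inner))
        split = inner[:20] + "*" + inner[20:]
        assert find_matches(relaxed_motif, ProteinRecord("w", "", split)) == []
        # matches in a later segment keep whole-sequence coordinates
        two = "MM*" + inner
        (m,) = find_matches(relaxed_motif, ProteinRecord("w", "", two))
        assert m.start == 4

    def test_unknown_policy_rejected(self, strict_motif):
        with pytest.raises(ScanError, match="policy"):
            find_matches(strict_motif, ProteinRecord("x", "", TOY_36MER), "BOGUS")


def test_all_realizations_agrees_with_brute_force_oracle(strict_motif, relaxed_motif):
    """Scanner output equals flat (start, gap-vector) enumeration on random inputs."""
    rng = np.random.default_rng(2024)
    motifs = [
        strict_motif,
        relaxed_motif,
        parse_motif("Hx(2,4)YxR"),
        parse_motif("AxA"),
        parse_motif("CxxC"),
    ]
    checked = 0
    for _ in range(300):
        alpha_size = int(rng.integers(4, 21))
        alphabet = list("HPYSRACDEFGIKLMNQTVW"[:alpha_size]) + ["X"]
        length = int(rng.integers(1, 61))
        seq = "".join(rng.choice(alphabet, size=length))
        rec = ProteinRecord("r", "", seq)
        for motif in motifs:
            got = [(m.start, m.end, m.gap_lengths) for m in find_matches(motif, rec)]
            assert got == brute_force_matches(motif, seq)
            checked += 1
    assert checked == 1500


def test_strict_matches_are_a_subset_of_relaxed(strict_motif, relaxed_motif):
    rng = np.random.default_rng(7)
    alphabet = list("HPYSRA")  # enriched in motif letters to force hits
    found_strict = 0
    for _ in range(200):
        seq = "".join(rng.choice(alphabet, size=80))
        rec = ProteinRecord("r", "", seq)
        strict_hits = {(m.start, m.end) for m in find_matches(strict_motif, rec)}
        relaxed_hits = {(m.start, m.end) for m in find_matches(relaxed_motif, rec)}
        assert strict_hits <= relaxed_hits
        found_strict += len(strict_hits)
        for m in find_matches(relaxed_motif, rec):
            assert m.span_length in span_bounds(relaxed_motif)


class TestMapKeyResidues:
    def test_toy_match_arithmetic(self, strict_motif):
        rec = ProteinRecord("toy", "", TOY_36MER)
        (m,) = find_matches(strict_motif, rec)
        assert map_key_residues(m, strict_motif, rec) == {
            "H1": 2, "P1": 15, "Y1": 32, "S1": 34, "R1": 36,
        }

    def test_single_token_motif(self):
        m = parse_motif("H")
        rec = ProteinRecord("s", "", "AAH")
        (hit,) = find_matches(m, rec)
        assert map_key_residues(hit, m, rec) == {"H1": 3}

    def test_positions_strictly_increase(self, strict_motif):
        rec = ProteinRecord("toy", "", TOY_36MER)
        (m,) = find_matches(strict_motif, rec)
        positions = list(map_key_residues(m, strict_motif).values())
        assert positions == sorted(positions)

    def test_inconsistent_pairing_errors(self, strict_motif, relaxed_motif):
        rec = ProteinRecord("toy", "", TOY_36MER)
        (m,) = find_matches(strict_motif, rec)
        with pytest.raises(ScanError):
            map_key_residues(m, relaxed_motif)  # wrong gap arity
        bad = Match(m.seq_id, m.start, m.end + 1, m.gap_lengths, dict(m.key_residues))
        with pytest.raises(ScanError, match="inconsistent"):
            map_key_residues(bad, strict_motif)


class TestResiduesInSpan:
    def test_planted_cysteines_found_at_recorded_offsets(self, strict_motif):
        # realization anchored at 357 with cysteines at 372 and 383, the
        # layout reported for the AtLRB3 H-NOX center
        gaps2 = ["A"] * 16        # gap2 covers positions 371-386
        gaps2[372 - 371] = "C"
        gaps2[383 - 371] = "C"
        frag = "H" + "A" * 12 + "P" + "".join(gaps2) + "YASAR"
        seq = "M" * 356 + frag + "M" * 50
        rec = ProteinRecord("At4g01160.2", "", seq)
        (m,) = find_matches(strict_motif, rec)
        assert (m.start, m.end) == (357, 391)
        assert residues_in_span(rec, (357, 391), "C") == [372, 383]

    def test_absent_letter_gives_empty_list(self):
        assert residues_in_span(ProteinRecord("a", "", "ACCA"), (1, 4), "W") == []

    def test_simple_enumeration(self):
        assert residues_in_span(ProteinRecord("a", "", "ACCA"), (1, 4), "C") == [2, 3]

    def test_out_of_range_span_errors(self):
        with pytest.raises(ScanError, match="out of range"):
            residues_in_span(ProteinRecord("a", "", "ACCA"), (2, 9), "C")


class TestAggregation:
    def test_isoforms_collapse_to_one_locus(self, relaxed_motif):
        seq = "H" + "A" * 28 + "YASAR"
        records = [
            ProteinRecord("At4g01160.1", "", seq),
            ProteinRecord("At4g01160.2", "", seq),
        ]
        table = collapse_to_loci(scan_proteome(relaxed_motif, records))
        assert table.n_loci == 1
        row = table.rows[0]
        assert row["locus"] == "AT4G01160"
        assert row["gene_models"] == ["At4g01160.1", "At4g01160.2"]

    def test_non_agi_ids_group_verbatim(self, relaxed_motif):
        seq = "H" + "A" * 28 + "YASAR"
        table = collapse_to_loci(scan_proteome(relaxed_motif, [ProteinRecord("myseq", "", seq)]))
        assert table.rows[0]["locus"] == "myseq"

    def test_distinct_loci_stay_distinct_and_sorted(self, relaxed_motif):
        seq = "H" + "A" * 28 + "YASAR"
        records = [
            ProteinRecord("At5g19160.1", "", seq),
            ProteinRecord("At1g62580.1", "", seq),
        ]
        table = collapse_to_loci(scan_proteome(relaxed_motif, records))
        assert [r["locus"] for r in table.rows] == ["AT1G62580", "AT5G19160"]

    def test_empty_record_list_gives_empty_matchset(self, relaxed_motif):
        ms = scan_proteome(relaxed_motif, [])
        assert ms.n_matching_records == 0 and ms.n_realizations == 0
        assert collapse_to_loci(ms).n_loci == 0

    def test_match_frame_has_locus_and_key_residue_columns(self, strict_motif):
        ms = scan_proteome(strict_motif, [ProteinRecord("At4g01160.2", "", TOY_36MER)])
        frame = ms.to_frame()
        assert list(frame["locus"]) == ["AT4G01160"]
        assert frame["key_residues"][0].startswith("H1=2;")


@pytest.mark.parametrize(
    "seq_id, locus",
    [
        ("At4g01160.2", "AT4G01160"),
        ("AT4G01160", "AT4G01160"),
        ("AtMg00020.1", "ATMG00020"),
        ("myseq", "myseq"),
        ("At4g01160.2.extra", "At4g01160.2.extra"),
    ],
)
def test_locus_normalization_rules(seq_id, locus):
    assert normalize_locus(seq_id) == locus
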