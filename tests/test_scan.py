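"""Pair reconstitution, unique-mapping filter, and scan tallies."""

import random

import pysam
import pytest

from telofuse import (
    HeaderMismatchError,
    ScanCounts,
    ScanInputError,
    passes_unique_filter,
    scan_alignments,
    scan_file,
)
from telofuse.scan import write_pairs_tsv

from conftest import make_pair


def flat(pairs):
    return [rec for pair in pairs for rec in pair]


@pytest.fixture
def spec_fixture_pairs(toy_header):
    """Six passing pairs plus one failing MAPQ, enumerated by hand.

    3 intrachromosomal proper pairs; 2 interchromosomal each with one
    mate at pos 50,000 (inside the 100 kb window) and one mid-chromosome;
    1 interchromosomal with both mates mid-chromosome; 1 interchromosomal
    pair rejected by the MAPQ filter.
    Expected: pairs_seen=7, pairs_passing=6, n=3, k=2, m=2, n_intra=3.
    """
    return [
        make_pair(toy_header, "intra1", "chr1", 400_000, "chr1", 400_400),
        make_pair(toy_header, "intra2", "chr2", 500_000, "chr2", 500_350),
        make_pair(toy_header, "intra3", "chr1", 120_000, "chr1", 120_500),
        make_pair(toy_header, "interA", "chr1", 50_000, "chr2", 400_000),
        make_pair(toy_header, "interB", "chr2", 50_000, "chr1", 300_000),
        make_pair(toy_header, "interMid", "chr1", 500_000, "chr2", 600_000),
        make_pair(toy_header, "lowq", "chr1", 10, "chr2", 10, mapq1=5),
    ]


class TestUniqueFilter:
    def test_primary_mapped_passes(self, toy_header):
        rec = make_pair(toy_header, "p", "chr1", 100, "chr2", 100, mapq1=42)[0]
        assert passes_unique_filter(rec, 20)

    @pytest.mark.parametrize("mapq,expected", [(19, False), (20, True), (21, True)])
    def test_mapq_threshold_boundary(self, toy_header, mapq, expected):
        rec = make_pair(toy_header, "p", "chr1", 100, "chr2", 100, mapq1=mapq)[0]
        assert passes_unique_filter(rec, 20) is expected

    @pytest.mark.parametrize("flag_kw", ["secondary", "duplicate"])
    def test_flag_exclusions(self, toy_header, flag_kw):
        rec = make_pair(
            toy_header, "p", "chr1", 100, "chr2", 100, mapq1=60, **{flag_kw: True}
        )[0]
        assert not passes_unique_filter(rec, 20)

    def test_supplementary_and_unmapped_excluded(self, toy_header):
        rec = make_pair(toy_header, "p", "chr1", 100, "chr2", 100)[0]
        rec.flag |= 0x800
        assert not passes_unique_filter(rec, 20)
        rec2 = pysam.AlignedSegment(toy_header)
        rec2.query_name = "u"
        rec2.flag = 0x1 | 0x4 | 0x40
        assert not passes_unique_filter(rec2, 0)


class TestScanAlignments:
    def test_empty_stream(self, toy_submap):
        counts, _ = scan_alignments([], toy_submap)
        assert counts.pairs_seen == 0
        assert counts.n_inter == counts.k_subtel == counts.m_subtel_mates == 0

    def test_hand_enumerated_fixture(self, spec_fixture_pairs, toy_submap):
        counts, pairs = scan_alignments(
            flat(spec_fixture_pairs), toy_submap, collect_pairs=True
        )
        assert counts.pairs_seen == 7
        assert counts.pairs_passing == 6
        assert counts.n_inter == 3
        assert counts.k_subtel == 2
        assert counts.m_subtel_mates == 2
        assert counts.n_intra == 3
        assert {p.qname for p in pairs} == {"interA", "interB", "interMid"}
        counts.check_invariants()

    def test_order_independence(self, spec_fixture_pairs, toy_submap):
        records = flat(spec_fixture_pairs)
        baseline, _ = scan_alignments(records, toy_submap)
        rng = random.Random(42)
        for _ in range(5):
            shuffled = records[:]
            rng.shuffle(shuffled)
            counts, _ = scan_alignments(shuffled, toy_submap)
            assert counts.to_dict() == baseline.to_dict()

    def test_duplicate_copies_do_not_alter_counts(
        self, spec_fixture_pairs, toy_header, toy_submap
    ):
        records = flat(spec_fixture_pairs)
        baseline, _ = scan_alignments(records, toy_submap)
        dup = make_pair(
            toy_header, "interA", "chr1", 50_000, "chr2", 400_000, duplicate=True
        )
        counts, _ = scan_alignments(records + dup, toy_submap)
        assert counts.to_dict() == baseline.to_dict()

    def test_secondary_records_ignored(self, toy_header, toy_submap):
        primary = make_pair(toy_header, "a", "chr1", 50_000, "chr2", 500_000)
        extra = make_pair(
            toy_header, "a", "chr1", 60_000, "chr2", 600_000, secondary=True
        )
        counts, _ = scan_alignments(primary + extra, toy_submap)
        assert counts.n_inter == 1
        assert counts.k_subtel == 1

    def test_three_primaries_is_corrupt_input(self, toy_header, toy_submap):
        records = flat(
            [make_pair(toy_header, "a", "chr1", 50_000, "chr2", 500_000)]
        )
        records.append(
            make_pair(toy_header, "a", "chr1", 70_000, "chr2", 700_000)[0]
        )
        with pytest.raises(ScanInputError, match="more than two"):
            scan_alignments(records, toy_submap)

    def test_orphan_and_unpaired_records_skipped(self, toy_header, toy_submap):
        orphan = make_pair(toy_header, "solo", "chr1", 1000, "chr2", 2000)[:1]
        unpaired = pysam.AlignedSegment(toy_header)
        unpaired.query_name = "frag"
        unpaired.flag = 0
        unpaired.reference_name = "chr1"
        unpaired.reference_start = 10
        unpaired.mapping_quality = 60
        counts, _ = scan_alignments(orphan + [unpaired], toy_submap)
        assert counts.pairs_seen == 0
        assert counts.skipped == 2

    def test_both_mates_subtelomeric_counts_once_in_k_twice_in_m(
        self, toy_header, toy_submap
    ):
        records = flat(
            [make_pair(toy_header, "both", "chr1", 10_000, "chr2", 995_000)]
        )
        counts, _ = scan_alignments(records, toy_submap)
        assert counts.n_inter == 1
        assert counts.k_subtel == 1
        assert counts.m_subtel_mates == 2

    def test_pair_fails_if_either_mate_fails(self, toy_header, toy_submap):
        records = flat(
            [make_pair(toy_header, "half", "chr1", 1000, "chr2", 2000, mapq2=0)]
        )
        counts, _ = scan_alignments(records, toy_submap)
        assert counts.pairs_seen == 1
        assert counts.pairs_passing == 0


class TestScanFile:
    def write_sam(self, path, header, records):
        with pysam.AlignmentFile(str(path), "w", header=header) as handle:
            for rec in records:
                handle.write(rec)

    def test_round_trip_matches_in_memory(
        self, tmp_path, toy_header, toy_genome, toy_submap, spec_fixture_pairs
    ):
        records = flat(spec_fixture_pairs)
        sam = tmp_path / "lib.sam"
        self.write_sam(sam, toy_header, records)
        counts, _ = scan_file(sam, toy_submap)
        expected, _ = scan_alignments(records, toy_submap)
        assert counts.to_dict() == expected.to_dict()

    def test_header_mismatch_reports_discrepancies(self, tmp_path, toy_submap):
        header = pysam.AlignmentHeader.from_dict(
            {"SQ": [{"SN": "chr1", "LN": 999}, {"SN": "chrZ", "LN": 5}]}
        )
        sam = tmp_path / "bad.sam"
        self.write_sam(sam, header, [])
        with pytest.raises(HeaderMismatchError) as err:
            scan_file(sam, toy_submap)
        message = str(err.value)
        assert "length mismatch for 'chr1'" in message
        assert "'chrZ'" in message
        assert "'chr2'" in message

    def test_counts_json_round_trip(self, tmp_path, toy_submap, spec_fixture_pairs):
        counts, _ = scan_alignments(flat(spec_fixture_pairs), toy_submap)
        path = tmp_path / "counts.json"
        counts.to_json(path)
        loaded = ScanCounts.from_json(path)
        assert loaded.to_dict() == counts.to_dict()

    def test_pairs_tsv(self, tmp_path, toy_submap, spec_fixture_pairs):
        _, pairs = scan_alignments(
            flat(spec_fixture_pairs), toy_submap, collect_pairs=True
        )
        path = tmp_path / "pairs.tsv"
        write_pairs_tsv(pairs, path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("qname\t")
        assert len(lines) == 1 + len(pairs)
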