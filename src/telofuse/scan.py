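"""Stream paired-end alignments and count interchromosomal mate pairs.

The scanner reconstitutes mate pairs from primary alignment records,
applies a unique-mapping filter to both mates, classifies each passing
pair as intra- or interchromosomal, and tallies subtelomere involvement
among the interchromosomal pairs.

"Uniquely mapped" has no explicit SAM flag; the operational proxy used
here is: primary (not secondary, not supplementary), not
duplicate-flagged, both mates mapped, and MAPQ >= ``mapq_min`` on both
records. The threshold defaults to 20 and is exposed everywhere because
the uniqueness criterion is aligner-dependent.

Records may arrive in any order (name-sorted, coordinate-sorted, or
unsorted): pairs are collated by query name in a pending-mate table and
flushed when both primaries have been seen, so memory is proportional to
the number of pairs whose mates are far apart in the stream. Both
records must be seen before the pair can be judged because a record does
not carry its mate's MAPQ.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pysam

from .genome import ChromosomeSet, SubtelomereMap

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class ScanInputError(ValueError):
    """Raised for corrupt alignment input (e.g. >2 primary records per name)."""


class HeaderMismatchError(ScanInputError):
    """Alignment header @SQ lines disagree with the chromosome set."""


@dataclass(frozen=True)
class PairObservation:
    """One reconstituted, filter-passing mate pair."""

    qname: str
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    subtel_mates: int

    @property
    def interchromosomal(self) -> bool:
        return self.chrom_a != self.chrom_b

    @property
    def subtelomeric(self) -> bool:
        return self.subtel_mates >= 1


@dataclass
class ScanCounts:
    """Tallies from scanning one library.

    ``n_inter`` (n), ``k_subtel`` (k) and ``m_subtel_mates`` (m) feed the
    enrichment tests: k counts interchromosomal pairs with at least one
    subtelomeric mate (pair level), m counts subtelomeric mate positions
    among interchromosomal pairs (mate level, so k <= m <= 2k — a pair
    with both mates subtelomeric adds 1 to k and 2 to m).
    """

    pairs_seen: int = 0
    pairs_passing: int = 0
    n_inter: int = 0
    k_subtel: int = 0
    m_subtel_mates: int = 0
    n_intra: int = 0
    skipped: int = 0
    window: Optional[int] = None
    mapq_min: Optional[int] = None

    def check_invariants(self) -> None:
        assert 0 <= self.k_subtel <= self.n_inter <= self.pairs_passing
        assert self.pairs_passing <= self.pairs_seen
        assert self.k_subtel <= self.m_subtel_mates <= 2 * self.k_subtel
        assert self.n_inter + self.n_intra == self.pairs_passing

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "pairs_seen": self.pairs_seen,
            "pairs_passing": self.pairs_passing,
            "n_inter": self.n_inter,
            "k_subtel": self.k_subtel,
            "m_subtel_mates": self.m_subtel_mates,
            "n_intra": self.n_intra,
            "skipped": self.skipped,
            "window": self.window,
            "mapq_min": self.mapq_min,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_dict(), handle, indent=2)
            handle.write("\n")

    @classmethod
    def from_dict(cls, data: dict) -> "ScanCounts":
        fields = {
            key: data[key]
            for key in (
                "pairs_seen",
                "pairs_passing",
                "n_inter",
                "k_subtel",
                "m_subtel_mates",
                "n_intra",
                "skipped",
                "window",
                "mapq_min",
            )
            if key in data
        }
        return cls(**fields)

    @classmethod
    def from_json(cls, path: str | Path) -> "ScanCounts":
        with open(path) as handle:
            return cls.from_dict(json.load(handle))


def passes_unique_filter(rec: pysam.AlignedSegment, mapq_min: int = 20) -> bool:
    """Unique-mapping predicate for one primary record.

    True iff the record is paired, mapped with a mapped mate, primary
    (neither secondary nor supplementary), not duplicate-flagged, and has
    MAPQ >= ``mapq_min``.
    """
    return (
        rec.is_paired
        and not rec.is_unmapped
        and not rec.mate_is_unmapped
        and not rec.is_secondary
        and not rec.is_supplementary
        and not rec.is_duplicate
        and rec.mapping_quality >= mapq_min
    )


def _is_primary(rec: pysam.AlignedSegment) -> bool:
    return not rec.is_secondary and not rec.is_supplementary


def scan_alignments(
    stream: Iterable[pysam.AlignedSegment],
    submap: SubtelomereMap,
    mapq_min: int = 20,
    collect_pairs: bool = False,
) -> tuple[ScanCounts, list[PairObservation]]:
    """Collate mate pairs from ``stream`` and accumulate :class:`ScanCounts`.

    A pair is counted once both of its primary records have appeared; it
    passes iff both records pass :func:`passes_unique_filter`.
    Classification uses each mate's leftmost mapped position.
    Secondary/supplementary records are ignored; unpaired or
    out-of-range records are skipped with a warning tally. A query name
    contributing more than two primary records is corrupt input and
    raises :class:`ScanInputError`.

    Returns the counts and (if ``collect_pairs``) the list of passing
    :class:`PairObservation` objects.
    """
    chroms = submap.chromosomes
    counts = ScanCounts(window=submap.window, mapq_min=mapq_min)
    observations: list[PairObservation] = []
    # qname -> (passes, chrom, pos) for the first primary record seen
    pending: dict[str, tuple[bool, Optional[str], Optional[int]]] = {}
    closed: set[str] = set()

    for rec in stream:
        if not _is_primary(rec) or rec.is_duplicate:
            # secondary/supplementary alignments and duplicate-flagged
            # copies never participate in pair reconstitution
            continue
        if not rec.is_paired:
            counts.skipped += 1
            continue
        qname = rec.query_name
        if qname is None:
            counts.skipped += 1
            continue

        chrom: Optional[str] = None
        pos: Optional[int] = None
        ok = passes_unique_filter(rec, mapq_min)
        if not rec.is_unmapped:
            chrom = rec.reference_name
            pos = rec.reference_start
            if chrom not in chroms:
                logger.warning("record %s maps to unknown reference %r", qname, chrom)
                counts.skipped += 1
                ok = False
                chrom = pos = None
            elif not 0 <= pos < chroms.length_of(chrom):
                logger.warning(
                    "record %s position %d out of range on %s", qname, pos, chrom
                )
                counts.skipped += 1
                ok = False
                chrom = pos = None

        if qname in closed:
            raise ScanInputError(
                f"query name {qname!r} has more than two primary records"
            )
        if qname not in pending:
            pending[qname] = (ok, chrom, pos)
            continue

        ok1, chrom1, pos1 = pending.pop(qname)
        closed.add(qname)
        counts.pairs_seen += 1
        if not (ok1 and ok):
            continue
        assert chrom1 is not None and pos1 is not None
        assert chrom is not None and pos is not None
        counts.pairs_passing += 1
        subtel = int(submap.contains(chrom1, pos1)) + int(submap.contains(chrom, pos))
        if chrom1 != chrom:
            counts.n_inter += 1
            if subtel >= 1:
                counts.k_subtel += 1
            counts.m_subtel_mates += subtel
            if collect_pairs:
                observations.append(
                    PairObservation(qname, chrom1, pos1, chrom, pos, subtel)
                )
        else:
            counts.n_intra += 1

    if pending:
        logger.warning("%d query names had only one primary record", len(pending))
        counts.skipped += len(pending)
    counts.check_invariants()
    return counts, observations


def check_header(header: pysam.AlignmentHeader, chroms: ChromosomeSet) -> None:
    """Verify the @SQ dictionary matches the chromosome set exactly.

    Raises :class:`HeaderMismatchError` listing every discrepancy
    (missing, extra, or length-mismatched reference).
    """
    header_lengths = {
        sq["SN"]: sq["LN"] for sq in header.to_dict().get("SQ", [])
    }
    problems: list[str] = []
    for name, length in chroms.entries:
        if name not in header_lengths:
            problems.append(f"chromosome {name!r} missing from alignment header")
        elif header_lengths[name] != length:
            problems.append(
                f"length mismatch for {name!r}: header {header_lengths[name]}, "
                f"genome table {length}"
            )
    for name in header_lengths:
        if name not in chroms:
            problems.append(f"header reference {name!r} absent from genome table")
    if problems:
        raise HeaderMismatchError("; ".join(problems))


def scan_file(
    path: str | Path,
    submap: SubtelomereMap,
    mapq_min: int = 20,
    collect_pairs: bool = False,
) -> tuple[ScanCounts, list[PairObservation]]:
    """Scan a SAM or BAM file (any sort order) against ``submap``.

    The file's @SQ header is cross-checked against the chromosome set
    before any record is read.
    """
    path = str(path)
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as handle:
        check_header(handle.header, submap.chromosomes)
        return scan_alignments(
            handle, submap, mapq_min=mapq_min, collect_pairs=collect_pairs
        )


def write_pairs_tsv(pairs: Iterable[PairObservation], path: str | Path) -> None:
    """Write interchromosomal pair observations as TSV."""
    with open(path, "w") as handle:
        handle.write("qname\tchromA\tposA\tchromB\tposB\tsubtel_mates\n")
        for pair in pairs:
            handle.write(
                f"{pair.qname}\t{pair.chrom_a}\t{pair.pos_a}\t"
                f"{pair.chrom_b}\t{pair.pos_b}\t{pair.subtel_mates}\n"
            )
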