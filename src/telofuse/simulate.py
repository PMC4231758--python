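"""Synthetic paired-end libraries with known fusion-junction truth.

The generator targets the alignment level directly: it emits SAM records
(coordinates, flags, MAPQ, mate fields) rather than basecalls, since the
analysis begins at the SAM stage. A library mixes:

* concordant background pairs, placed uniformly along the genome with a
  truncated-normal insert model and proper-pair flags;
* discordant junction-spanning pairs, whose two mates flank a fusion
  junction on two different chromosomes.

Junctions come in two kinds. "Telomeric" junctions emulate end-to-end
chromosome fusions: both partner positions lie within ``fusion_zone`` bp
of a chromosome terminus (a uniform offset from the end, echoing
telomere erosion before fusion). "Uniform" junctions are background
rearrangements with both positions uniform over the genome. The mixture
weight ``theta`` is the fraction of telomeric junctions: theta near 0.8
emulates a fusion-rich mutant library, theta = 0 a uniform background.

Every pair is recorded in a truth table so scanner output can be checked
against exact tallies, and ``theta`` can be re-estimated from scan
counts for parameter-recovery checks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .genome import ChromosomeSet, SubtelomereMap, build_subtelomere_map


class SimulationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic library.

    Attributes
    ----------
    chrom_lengths
        Lengths (bp) of the toy chromosomes; names are chr1..chrN.
    fusion_zone
        D, bp: how close to a chromosome end a telomeric junction
        partner lies. Defaults to the 100 kb analysis window so truth
        and annotation align, but the two knobs are independent.
    theta
        Fraction of interchromosomal junctions that are telomeric-type.
    n_pairs
        Total read pairs in the library.
    delta
        Fraction of pairs that are junction-spanning (discordant).
    insert_mean, insert_sd
        Fragment-size model, bp (normal, truncated at 2x read length).
    read_length
        bp per read.
    mapq_high, low_mapq, low_mapq_fraction
        MAPQ assignment: ``mapq_high`` except a ``low_mapq_fraction`` of
        records assigned ``low_mapq`` (below the default filter
        threshold of 20).
    seed
        RNG seed recorded in the truth-file header.
    """

    chrom_lengths: tuple[int, ...]
    fusion_zone: int = 100_000
    theta: float = 0.8
    n_pairs: int = 10_000
    delta: float = 0.1
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    read_length: int = 100
    mapq_high: int = 60
    low_mapq: int = 3
    low_mapq_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom_lengths", tuple(self.chrom_lengths))
        for name, value in (
            ("theta", self.theta),
            ("delta", self.delta),
            ("low_mapq_fraction", self.low_mapq_fraction),
        ):
            if not 0.0 <= value <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {value}")
        if self.n_pairs < 0:
            raise SimulationError("n_pairs must be >= 0")
        if self.fusion_zone < self.read_length:
            raise SimulationError("fusion_zone must be >= read_length")
        if self.insert_mean <= 2 * self.read_length:
            raise SimulationError("insert_mean must exceed 2x read_length")
        if any(length <= 0 for length in self.chrom_lengths):
            raise SimulationError("chromosome lengths must be positive")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(len(self.chrom_lengths)))

    def chromosome_set(self) -> ChromosomeSet:
        return ChromosomeSet(tuple(zip(self.chrom_names, self.chrom_lengths)))

    @property
    def n_discordant(self) -> int:
        return round(self.delta * self.n_pairs)

    @property
    def n_concordant(self) -> int:
        return self.n_pairs - self.n_discordant


@dataclass(frozen=True)
class FusionJunction:
    """A simulated breakpoint joining positions on two chromosomes."""

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    kind: str  # "telomeric" | "uniform"

    def __post_init__(self) -> None:
        if self.chrom_a == self.chrom_b:
            raise SimulationError("junction partners must be on different chromosomes")
        if self.kind not in ("telomeric", "uniform"):
            raise SimulationError(f"unknown junction kind {self.kind!r}")


def simulate_junctions(
    config: SimConfig, count: int, rng: Optional[np.random.Generator] = None
) -> list[FusionJunction]:
    """Draw ``count`` interchromosomal fusion junctions.

    Each junction is telomeric with probability ``config.theta``: an end
    is picked uniformly among all 2C chromosome ends, the partner end
    uniformly among the ends of the other chromosomes, and each position
    offset uniformly in [0, D) from its end. Otherwise both positions
    are uniform over the genome, with distinct chromosomes enforced by
    redraw.
    """
    if count < 0:
        raise SimulationError("count must be >= 0")
    lengths = np.asarray(config.chrom_lengths, dtype=np.int64)
    n_chrom = len(lengths)
    if n_chrom < 2:
        raise SimulationError("need at least 2 chromosomes to form junctions")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if count == 0:
        return []
    names = config.chrom_names
    D = config.fusion_zone
    cumulative = np.cumsum(lengths)
    total = int(cumulative[-1])

    is_telo = rng.random(count) < config.theta
    n_t = int(is_telo.sum())
    n_u = count - n_t

    # telomeric: pick an end uniformly among the 2C chromosome ends,
    # partner end among the other chromosomes' ends (redraw collisions),
    # positions offset uniformly in [0, D) from the chosen terminus
    end_a = rng.integers(0, 2 * n_chrom, n_t)
    end_b = rng.integers(0, 2 * n_chrom, n_t)
    collide = end_b // 2 == end_a // 2
    while collide.any():
        end_b[collide] = rng.integers(0, 2 * n_chrom, int(collide.sum()))
        collide = end_b // 2 == end_a // 2

    def end_positions(ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ci = ends // 2
        offsets = rng.integers(0, D, len(ends))
        length = lengths[ci]
        pos = np.where(
            ends % 2 == 0,
            np.minimum(offsets, length - 1),
            np.maximum(length - 1 - offsets, 0),
        )
        return ci, pos

    t_ci_a, t_pos_a = end_positions(end_a)
    t_ci_b, t_pos_b = end_positions(end_b)

    # uniform: both positions uniform over the genome, distinct
    # chromosomes enforced by redraw of the partner
    def global_to_local(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ci = np.searchsorted(cumulative, g, side="right")
        starts = np.concatenate(([0], cumulative[:-1]))
        return ci, g - starts[ci]

    u_ci_a, u_pos_a = global_to_local(rng.integers(0, total, n_u))
    g_b = rng.integers(0, total, n_u)
    u_ci_b, u_pos_b = global_to_local(g_b)
    collide = u_ci_b == u_ci_a
    while collide.any():
        g_b[collide] = rng.integers(0, total, int(collide.sum()))
        u_ci_b, u_pos_b = global_to_local(g_b)
        collide = u_ci_b == u_ci_a

    junctions: list[FusionJunction] = []
    ti = ui = 0
    for telo in is_telo:
        if telo:
            junctions.append(
                FusionJunction(
                    names[t_ci_a[ti]], int(t_pos_a[ti]),
                    names[t_ci_b[ti]], int(t_pos_b[ti]), "telomeric",
                )
            )
            ti += 1
        else:
            junctions.append(
                FusionJunction(
                    names[u_ci_a[ui]], int(u_pos_a[ui]),
                    names[u_ci_b[ui]], int(u_pos_b[ui]), "uniform",
                )
            )
            ui += 1
    return junctions


TRUTH_COLUMNS = [
    "pair_id",
    "class",
    "junction_id",
    "junction_type",
    "chromA",
    "posA",
    "chromB",
    "posB",
    "read1_chrom",
    "read1_pos",
    "read2_chrom",
    "read2_pos",
]


def _draw_insert(config: SimConfig, rng: np.random.Generator, upper: int) -> int:
    """Insert size ~ Normal(mean, sd) truncated at >= 2x read length,
    clamped to the available span."""
    floor = 2 * config.read_length
    for _ in range(1000):
        insert = int(round(rng.normal(config.insert_mean, config.insert_sd)))
        if insert >= floor:
            return min(insert, upper)
    return min(floor, upper)


def _draw_mapq(config: SimConfig, rng: np.random.Generator) -> int:
    if config.low_mapq_fraction > 0 and rng.random() < config.low_mapq_fraction:
        return config.low_mapq
    return config.mapq_high


def sam_header(config: SimConfig) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": name, "LN": length}
                for name, length in zip(config.chrom_names, config.chrom_lengths)
            ],
        }
    )


def _make_record(
    header: pysam.AlignmentHeader,
    qname: str,
    read1: bool,
    chrom: str,
    pos: int,
    mate_chrom: str,
    mate_pos: int,
    mapq: int,
    proper: bool,
    reverse: bool,
    tlen: int,
    read_length: int,
) -> pysam.AlignedSegment:
    rec = pysam.AlignedSegment(header)
    rec.query_name = qname
    rec.flag = 0x1  # paired
    if proper:
        rec.flag |= 0x2
    rec.flag |= 0x40 if read1 else 0x80
    if reverse:
        rec.flag |= 0x10
    else:
        rec.flag |= 0x20  # mate reverse (FR orientation)
    rec.reference_name = chrom
    rec.reference_start = pos
    rec.mapping_quality = mapq
    rec.cigarstring = f"{read_length}M"
    rec.next_reference_name = mate_chrom
    rec.next_reference_start = mate_pos
    rec.template_length = tlen
    return rec


def simulate_library(
    config: SimConfig,
    junctions: Optional[Sequence[FusionJunction]] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pysam.AlignmentHeader, list[pysam.AlignedSegment], pd.DataFrame]:
    """Generate one synthetic library.

    Returns the SAM header, the alignment records (concordant background
    pairs followed by discordant junction-spanning pairs; two records
    per pair) and the truth table, one row per pair, recording the class,
    the junction (for discordant pairs) and the realized mate positions.

    If ``junctions`` is None, ``config.n_discordant`` junctions are drawn
    from the same RNG and each discordant pair spans its own junction
    (one-to-one), so junction subtelomere status is sampled independently
    across pairs. If an explicit junction list is supplied, each pair is
    assigned a junction uniformly at random from it (several pairs may
    then share a junction). Mates are placed flanking the junction on
    the two partner chromosomes at offsets within the insert size.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    one_to_one = junctions is None
    chroms = config.chromosome_set()
    lengths = np.asarray(config.chrom_lengths, dtype=np.int64)
    names = config.chrom_names
    rl = config.read_length

    min_len = int(lengths.min())
    if min_len < 2 * rl:
        raise SimulationError(
            f"chromosome of length {min_len} is shorter than 2x read length"
        )
    if min_len < config.insert_mean + 3 * config.insert_sd:
        warnings.warn(
            f"chromosome of length {min_len} is shorter than insert mean + 3 sd; "
            "inserts will be clamped",
            stacklevel=2,
        )

    if junctions is None:
        if config.n_discordant > 0:
            junctions = simulate_junctions(config, config.n_discordant, rng)
        else:
            junctions = []
    if config.n_discordant > 0 and not junctions:
        raise SimulationError("non-empty junction list required when delta > 0")

    header = sam_header(config)
    records: list[pysam.AlignedSegment] = []
    truth_rows: list[tuple] = []
    cumulative = np.cumsum(lengths)
    total = int(cumulative[-1])
    pair_width = len(str(max(config.n_pairs, 1)))

    for i in range(config.n_concordant):
        qname = f"pair{i:0{pair_width}d}"
        g = int(rng.integers(0, total))
        ci = int(np.searchsorted(cumulative, g, side="right"))
        length = int(lengths[ci])
        chrom = names[ci]
        insert = _draw_insert(config, rng, upper=length)
        start = int(rng.integers(0, length - insert + 1))
        pos1 = start
        pos2 = start + insert - rl
        mapq1 = _draw_mapq(config, rng)
        mapq2 = _draw_mapq(config, rng)
        records.append(
            _make_record(header, qname, True, chrom, pos1, chrom, pos2,
                         mapq1, True, False, insert, rl)
        )
        records.append(
            _make_record(header, qname, False, chrom, pos2, chrom, pos1,
                         mapq2, True, True, -insert, rl)
        )
        truth_rows.append(
            (qname, "concordant", -1, "NA", chrom, pos1, chrom, pos2,
             chrom, pos1, chrom, pos2)
        )

    for i in range(config.n_discordant):
        qname = f"pair{config.n_concordant + i:0{pair_width}d}"
        jid = i if one_to_one else int(rng.integers(0, len(junctions)))
        junction = junctions[jid]
        insert = _draw_insert(config, rng, upper=2 * min_len)
        positions: list[int] = []
        for chrom, jpos in (
            (junction.chrom_a, junction.pos_a),
            (junction.chrom_b, junction.pos_b),
        ):
            length = chroms.length_of(chrom)
            gap = int(rng.integers(0, max(insert - rl, 1)))
            positions.append(int(np.clip(jpos - gap, 0, length - rl)))
        pos1, pos2 = positions
        mapq1 = _draw_mapq(config, rng)
        mapq2 = _draw_mapq(config, rng)
        records.append(
            _make_record(header, qname, True, junction.chrom_a, pos1,
                         junction.chrom_b, pos2, mapq1, False, False, 0, rl)
        )
        records.append(
            _make_record(header, qname, False, junction.chrom_b, pos2,
                         junction.chrom_a, pos1, mapq2, False, True, 0, rl)
        )
        truth_rows.append(
            (qname, "discordant", jid, junction.kind,
             junction.chrom_a, junction.pos_a, junction.chrom_b, junction.pos_b,
             junction.chrom_a, pos1, junction.chrom_b, pos2)
        )

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return header, records, truth


def write_library(
    config: SimConfig, out_prefix: str | Path, rng: Optional[np.random.Generator] = None
) -> tuple[Path, Path, Path]:
    """Simulate a library and write ``<prefix>.sam``, ``<prefix>.truth.tsv``
    and ``<prefix>.chrom.sizes``. Byte-identical for identical config."""
    header, records, truth = simulate_library(config, rng=rng)
    sam_path = Path(f"{out_prefix}.sam")
    truth_path = Path(f"{out_prefix}.truth.tsv")
    sizes_path = Path(f"{out_prefix}.chrom.sizes")
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as handle:
        for rec in records:
            handle.write(rec)
    with open(truth_path, "w") as handle:
        handle.write(f"# telofuse truth table; seed={config.seed} "
                     f"theta={config.theta} delta={config.delta} "
                     f"fusion_zone={config.fusion_zone}\n")
        truth.to_csv(handle, sep="\t", index=False)
    with open(sizes_path, "w") as handle:
        for name, length in zip(config.chrom_names, config.chrom_lengths):
            handle.write(f"{name}\t{length}\n")
    return sam_path, truth_path, sizes_path


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def truth_tally(truth: pd.DataFrame, submap: SubtelomereMap) -> tuple[int, int, int]:
    """Exact (n, k, m) implied by a truth table's discordant mate positions.

    n = discordant pairs, k = discordant pairs with >=1 subtelomeric mate,
    m = subtelomeric mates among discordant pairs. This is the oracle the
    scanner is checked against when no record fails the MAPQ filter.
    """
    disc = truth[truth["class"] == "discordant"]
    n = len(disc)
    k = 0
    m = 0
    for row in disc.itertuples(index=False):
        s1 = submap.contains(row.read1_chrom, int(row.read1_pos))
        s2 = submap.contains(row.read2_chrom, int(row.read2_pos))
        k += int(s1 or s2)
        m += int(s1) + int(s2)
    return n, k, m


def write_fastq(
    config: SimConfig,
    records: Sequence[pysam.AlignedSegment],
    r1_path: str | Path,
    r2_path: str | Path,
    rng: Optional[np.random.Generator] = None,
) -> None:
    """Interoperability demo only: emit the library as FASTQ with random
    bases (no error model; not validated against any aligner)."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    bases = np.array(list("ACGT"))
    qual = "I" * config.read_length
    with open(r1_path, "w") as h1, open(r2_path, "w") as h2:
        for rec in records:
            seq = "".join(bases[rng.integers(0, 4, config.read_length)])
            handle = h1 if rec.is_read1 else h2
            handle.write(f"@{rec.query_name}\n{seq}\n+\n{qual}\n")
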