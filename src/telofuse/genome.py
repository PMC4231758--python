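"""Reference geometry: chromosome sets and subtelomeric windows.

Coordinates are 0-based, half-open throughout the package; SAM's 1-based
POS is converted at parse time (pysam already exposes 0-based starts).
A "telomere" is operationalized as the assembly end of each chromosome
sequence — no telomeric-repeat masking is attempted — so a subtelomere
is simply the window of ``W`` bp adjacent to either sequence terminus.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class GenomeInputError(ValueError):
    """Raised for malformed chromosome tables or out-of-range queries."""


@dataclass(frozen=True)
class ChromosomeSet:
    """Ordered chromosome names and lengths defining the reference geometry.

    Parameters
    ----------
    entries
        Sequence of ``(name, length)`` pairs in reference order. Names must
        be unique and lengths positive.

    Attributes
    ----------
    total_length
        Genome size ``G`` in bp, the sum of all chromosome lengths.
    """

    entries: tuple[tuple[str, int], ...]
    lengths: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        names = [name for name, _ in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise GenomeInputError(f"duplicate chromosome name(s): {dupes}")
        for name, length in self.entries:
            if not isinstance(length, int) or length <= 0:
                raise GenomeInputError(
                    f"chromosome {name!r} has non-positive length {length!r}"
                )
        object.__setattr__(self, "lengths", dict(self.entries))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.entries)

    @property
    def total_length(self) -> int:
        """Genome size G in bp."""
        return sum(length for _, length in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def length_of(self, name: str) -> int:
        try:
            return self.lengths[name]
        except KeyError:
            raise GenomeInputError(f"unknown chromosome {name!r}") from None


def load_chromosome_set(source: str | Path) -> ChromosomeSet:
    """Read a chromosome-size table into a :class:`ChromosomeSet`.

    Accepts UCSC ``chrom.sizes`` (whitespace-separated name, length) and
    samtools ``.fai`` files (only the first two columns are used). Entries
    are returned in file order.
    """
    path = Path(source)
    entries: list[tuple[str, int]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise GenomeInputError(
                    f"{path}:{lineno}: expected at least two columns, got {line!r}"
                )
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise GenomeInputError(
                    f"{path}:{lineno}: length {fields[1]!r} is not an integer"
                ) from None
            if length <= 0:
                raise GenomeInputError(
                    f"{path}:{lineno}: chromosome {name!r} has non-positive "
                    f"length {length}"
                )
            entries.append((name, length))
    if not entries:
        raise GenomeInputError(f"{path}: empty chromosome table")
    names = [n for n, _ in entries]
    if len(set(names)) != len(names):
        seen: set[str] = set()
        for lineno, (name, _) in enumerate(entries, start=1):
            if name in seen:
                raise GenomeInputError(
                    f"{path}: duplicate chromosome name {name!r}"
                )
            seen.add(name)
    return ChromosomeSet(tuple(entries))


def tair10_chromosomes() -> ChromosomeSet:
    """The packaged TAIR10 nuclear chromosome lengths (Arabidopsis thaliana).

    Ships with the package so the uniform-recombination null for the
    Arabidopsis genome can be built without downloads.
    """
    ref = importlib.resources.files("telofuse.data") / "tair10.chrom.sizes"
    with importlib.resources.as_file(ref) as path:
        return load_chromosome_set(path)


@dataclass(frozen=True)
class SubtelomereMap:
    """Per-chromosome terminal windows of width ``W``.

    For a chromosome of length L the subtelomeric intervals are
    ``[0, min(W, L))`` and ``[max(0, L-W), L)``, merged into a single
    interval when ``L < 2W``. The total span is ``S = sum(min(2W, L))``
    and the genome fraction ``f = S / G``.
    """

    chromosomes: ChromosomeSet
    window: int
    intervals: dict[str, tuple[tuple[int, int], ...]] = field(
        init=False, repr=False
    )

    def __post_init__(self) -> None:
        if self.window < 0:
            raise GenomeInputError(f"window must be >= 0, got {self.window}")
        ivals: dict[str, tuple[tuple[int, int], ...]] = {}
        for name, length in self.chromosomes.entries:
            W = self.window
            if W == 0:
                ivals[name] = ()
            elif length < 2 * W:
                ivals[name] = ((0, length),)
            else:
                ivals[name] = ((0, W), (length - W, length))
        object.__setattr__(self, "intervals", ivals)

    @property
    def total_subtelomeric(self) -> int:
        """Total subtelomeric span S in bp."""
        return sum(
            end - start
            for spans in self.intervals.values()
            for start, end in spans
        )

    @property
    def fraction(self) -> float:
        """Subtelomeric genome fraction f = S / G."""
        return self.total_subtelomeric / self.chromosomes.total_length

    def __contains__(self, item: tuple[str, int]) -> bool:
        return self.contains(*item)

    def contains(self, chrom: str, pos: int) -> bool:
        """True iff 0-based ``pos`` on ``chrom`` lies in a subtelomeric window.

        Half-open test: for window W the positions 0..W-1 and L-W..L-1 are
        subtelomeric; position W is not.
        """
        length = self.chromosomes.length_of(chrom)
        if not 0 <= pos < length:
            raise GenomeInputError(
                f"position {pos} out of range [0, {length}) on {chrom!r}"
            )
        W = self.window
        return pos < W or pos >= length - W

    def to_bed(self, handle) -> None:
        """Write the subtelomeric intervals as 3-column BED (0-based, half-open)."""
        for name in self.chromosomes.names:
            for start, end in self.intervals[name]:
                handle.write(f"{name}\t{start}\t{end}\n")


def build_subtelomere_map(
    chromosomes: ChromosomeSet, window: int = 100_000
) -> SubtelomereMap:
    """Build the subtelomere annotation for ``chromosomes`` at width ``window``.

    The default of 100 kb matches the window used to define subtelomeric
    involvement of fusion junctions in Arabidopsis.
    """
    return SubtelomereMap(chromosomes, window)


def in_subtelomere(submap: SubtelomereMap, chrom: str, pos: int) -> bool:
    """Functional alias for :meth:`SubtelomereMap.contains`."""
    return submap.contains(chrom, pos)


def subtelomeric_fraction(
    chromosomes: ChromosomeSet, window: int
) -> float:
    """Convenience: f = S/G for ``chromosomes`` at ``window`` bp."""
    return build_subtelomere_map(chromosomes, window).fraction
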