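"""Collapse aligned transposon-junction reads into unique insertions.

A unique insertion is a distinct transposon integration event identified by
genomic position and transposon orientation (strand): the 5' end of each
supporting read marks the transposon-chromosome junction, and reads in
opposite orientations at the same coordinate represent distinct insertions.
This module turns a stream of accepted alignments into a per-library catalog
of unique insertions with read counts, and characterizes the (typically
heavy-tailed) reads-per-insertion distribution.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Dict, Iterable, Iterator, List, Mapping, Tuple

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from .formats_io import AlignedRead

#: CIGAR operations that consume reference bases.
_REF_CONSUMING = frozenset("MDN=X")

InsertionKey = Tuple[str, int, str]  # (contig, 1-based position, strand)


@dataclass(frozen=True, order=True)
class UniqueInsertion:
    """A transposon junction: contig, 1-based position, orientation, read support."""

    contig: str
    position: int
    strand: str
    read_count: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"insertion position must be >= 1, got {self.position}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.read_count < 1:
            raise ValueError(f"read_count must be >= 1, got {self.read_count}")

    @property
    def key(self) -> InsertionKey:
        return (self.contig, self.position, self.strand)


class InsertionLibrary:
    """Catalog of unique insertions for one mutant library.

    Iteration yields :class:`UniqueInsertion` sorted by (contig, position,
    strand); ``total_reads`` is the sum of read counts, i.e. the number of
    accepted alignments that produced the catalog.
    """

    def __init__(
        self,
        name: str,
        counts: Mapping[InsertionKey, int] | Iterable[UniqueInsertion] = (),
        source: str = "",
    ) -> None:
        self.name = name
        self.source = source
        if isinstance(counts, Mapping):
            items = counts.items()
        else:
            items = ((ins.key, ins.read_count) for ins in counts)
        self._counts: Dict[InsertionKey, int] = {}
        for key, n in items:
            if n < 1:
                raise ValueError(f"read_count must be >= 1 for {key}, got {n}")
            if key in self._counts:
                raise ValueError(f"duplicate insertion key {key}")
            self._counts[key] = int(n)
        self._counts = dict(sorted(self._counts.items()))
        self._arrays: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._counts)

    def __iter__(self) -> Iterator[UniqueInsertion]:
        for (contig, pos, strand), n in self._counts.items():
            yield UniqueInsertion(contig, pos, strand, n)

    def __contains__(self, key: InsertionKey) -> bool:
        return key in self._counts

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InsertionLibrary):
            return NotImplemented
        return self._counts == other._counts

    def __repr__(self) -> str:
        return (
            f"InsertionLibrary(name={self.name!r}, unique={len(self)}, "
            f"total_reads={self.total_reads})"
        )

    # -- accessors ----------------------------------------------------------

    @property
    def insertions(self) -> List[UniqueInsertion]:
        return list(self)

    @property
    def total_reads(self) -> int:
        return sum(self._counts.values())

    def read_count(self, key: InsertionKey) -> int:
        return self._counts.get(key, 0)

    def contigs(self) -> List[str]:
        return sorted({c for c, _, _ in self._counts})

    def contig_arrays(self, contig: str) -> Tuple[np.ndarray, np.ndarray]:
        """Sorted position array and aligned read-count array for one contig.

        Positions repeat when insertions in both orientations share a
        coordinate; both strands are pooled, which is what every downstream
        window/interval count wants.
        """
        if contig not in self._arrays:
            pairs = [
                (pos, n)
                for (c, pos, _), n in self._counts.items()
                if c == contig
            ]
            pairs.sort()
            if pairs:
                positions = np.array([p for p, _ in pairs], dtype=np.int64)
                counts = np.array([n for _, n in pairs], dtype=np.int64)
            else:
                positions = np.empty(0, dtype=np.int64)
                counts = np.empty(0, dtype=np.int64)
            self._arrays[contig] = (positions, counts)
        return self._arrays[contig]


@dataclass
class CountHistogram:
    """Integer-valued histogram: ``bins[value] -> frequency``."""

    bins: Dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for value, freq in self.bins.items():
            if freq < 0:
                raise ValueError(f"negative frequency {freq} for value {value}")

    @property
    def total(self) -> int:
        return sum(self.bins.values())

    def to_rows(self) -> List[Tuple[int, int]]:
        return sorted(self.bins.items())


@dataclass(frozen=True)
class LibrarySummary:
    """Headline statistics of a library's reads-per-insertion distribution."""

    name: str
    unique_insertions: int
    total_reads: int
    mean_reads_per_insertion: float
    mean_reads_rounded: int
    singletons: int
    singleton_pct: int
    at_most_3_reads: int
    at_most_3_pct: int
    above_threshold: Dict[int, int]


def reference_span(cigar: Iterable[Tuple[str, int]]) -> int:
    """Number of reference bases covered by a CIGAR (M, D, N, =, X consume)."""
    return sum(length for op, length in cigar if op in _REF_CONSUMING)


def junction_position(read: "AlignedRead") -> InsertionKey:
    """Transposon junction coordinate implied by a read: its 5' end.

    Forward reads start at the junction, so the leftmost mapped base is used;
    reverse reads end at it, so the rightmost aligned reference column
    (leftmost position + reference span - 1) is used.
    """
    span = reference_span(read.cigar)
    if span < 1:
        raise ValueError(
            f"read {read.query_name!r} has a CIGAR with zero reference span"
        )
    if read.strand == "+":
        return (read.contig, read.pos, "+")
    return (read.contig, read.pos + span - 1, "-")


def call_unique_insertions(
    reads: Iterable["AlignedRead"], name: str, source: str = ""
) -> InsertionLibrary:
    """Collapse accepted alignments into an :class:`InsertionLibrary`.

    Each distinct (contig, junction position, strand) becomes one unique
    insertion whose read_count is the number of supporting reads; the
    library's total_reads equals the number of reads consumed.
    """
    counter: Counter[InsertionKey] = Counter()
    for read in reads:
        counter[junction_position(read)] += 1
    return InsertionLibrary(name, dict(counter), source=source)


def filter_low_read_insertions(
    library: InsertionLibrary, min_reads: int
) -> InsertionLibrary:
    """Drop unique insertions supported by fewer than ``min_reads`` reads.

    Insertions represented by a single read (or a small number of reads) may
    be false observations arising from misaligned reads; this optional filter
    removes them. Totals are recomputed over the survivors; the input library
    is left unchanged.
    """
    if min_reads < 1:
        raise ValueError(f"min_reads must be >= 1, got {min_reads}")
    kept = {ins.key: ins.read_count for ins in library if ins.read_count >= min_reads}
    return InsertionLibrary(
        library.name, kept, source=f"{library.source} [min_reads={min_reads}]"
    )


def reads_per_insertion_histogram(library: InsertionLibrary) -> CountHistogram:
    """Histogram of read counts per unique insertion."""
    bins: Counter[int] = Counter(ins.read_count for ins in library)
    return CountHistogram(dict(bins))


def library_summary(
    library: InsertionLibrary, read_thresholds: Iterable[int] = (1000, 5000)
) -> LibrarySummary:
    """Summarize library depth and the reads-per-insertion bias.

    Reports mean reads per unique insertion (and the nearest integer), the
    count and integer percentage of singleton insertions and of insertions
    with at most three reads, and the number of insertions above each
    requested read-count threshold.
    """
    n = len(library)
    total = library.total_reads
    counts = [ins.read_count for ins in library]
    singles = sum(1 for c in counts if c == 1)
    le3 = sum(1 for c in counts if c <= 3)
    mean = total / n if n else 0.0
    pct = lambda k: int(round(100.0 * k / n)) if n else 0  # noqa: E731
    return LibrarySummary(
        name=library.name,
        unique_insertions=n,
        total_reads=total,
        mean_reads_per_insertion=mean,
        mean_reads_rounded=int(round(mean)),
        singletons=singles,
        singleton_pct=pct(singles),
        at_most_3_reads=le3,
        at_most_3_pct=pct(le3),
        above_threshold={int(t): sum(1 for c in counts if c > t) for t in read_thresholds},
    )
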