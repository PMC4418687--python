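"""Independent brute-force oracles and small builders shared by the tests.

Everything here recomputes quantities by direct enumeration (per-window
loops, per-position membership checks), deliberately sharing no code with
the library's vectorized implementations.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from tnscan.formats_io import AlignedRead, GeneAnnotation
from tnscan.insertion_calling import InsertionLibrary


def make_read(
    pos: int,
    strand: str = "+",
    cigar: Sequence[Tuple[str, int]] = (("M", 50),),
    contig: str = "c1",
    name: str = "r",
    mapq: int = 60,
) -> AlignedRead:
    flags = 16 if strand == "-" else 0
    return AlignedRead(name, contig, pos, strand, tuple(cigar), mapq, flags)


def make_library(
    entries: Iterable[Tuple[str, int, str, int]], name: str = "test"
) -> InsertionLibrary:
    """Library from (contig, position, strand, read_count) tuples."""
    return InsertionLibrary(name, {(c, p, s): n for c, p, s, n in entries})


def random_library(
    rng: np.random.Generator,
    length: int,
    n: int,
    contig: str = "c1",
    max_count: int = 50,
    name: str = "random",
) -> InsertionLibrary:
    counts: Dict[Tuple[str, int, str], int] = {}
    while len(counts) < n:
        pos = int(rng.integers(1, length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        counts.setdefault((contig, pos, strand), int(rng.integers(1, max_count + 1)))
    return InsertionLibrary(name, counts)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def oracle_rightmost_ref_column(pos: int, cigar: Sequence[Tuple[str, int]]) -> int:
    """Rightmost aligned reference column, by explicit column enumeration."""
    columns = []
    ref = pos
    for op, length in cigar:
        if op in ("M", "=", "X", "D", "N"):
            columns.extend(range(ref, ref + length))
            ref += length
    return max(columns)


def oracle_interval_count(
    library: InsertionLibrary, contig: str, start: int, end: int, mode: str
) -> int:
    total = 0
    for ins in library:
        if ins.contig == contig and start <= ins.position <= end:
            total += ins.read_count if mode == "reads" else 1
    return total


def oracle_window_counts(
    library: InsertionLibrary,
    contig: str,
    length: int,
    window: int,
    step: int,
    mode: str = "unique_insertions",
) -> List[Tuple[int, int]]:
    out = []
    start = 1
    while start + window - 1 <= length:
        out.append(
            (start, oracle_interval_count(library, contig, start,
                                          start + window - 1, mode))
        )
        start += step
    return out


def oracle_effective_interval(
    gene: GeneAnnotation,
    pct5: float = 5.0,
    pct3: float = 20.0,
    nt5: int = 0,
    nt3: int = 0,
) -> Optional[Tuple[int, int]]:
    L = gene.end - gene.start + 1
    r5 = max(nt5, math.floor(pct5 * L / 100))
    r3 = max(nt3, math.floor(pct3 * L / 100))
    if r5 + r3 >= L:
        return None
    if gene.strand == "+":
        return gene.start + r5, gene.end - r3
    return gene.start + r3, gene.end - r5


def oracle_ei(
    gene: GeneAnnotation,
    library: InsertionLibrary,
    length: int,
    window: int,
    pct5: float = 5.0,
    pct3: float = 20.0,
) -> Optional[int]:
    """Essentiality index by exhaustive step-1 window enumeration."""
    interval = oracle_effective_interval(gene, pct5, pct3)
    if interval is None:
        return None
    a, b = interval
    le = b - a + 1
    mode = "unique_insertions"
    if le >= window:
        return max(
            oracle_interval_count(library, gene.contig, w, w + window - 1, mode)
            for w in range(a, b - window + 2)
        )
    starts = [
        w for w in range(1, length - window + 2)
        if w <= a and w + window - 1 >= b
    ]
    if starts:
        return min(
            oracle_interval_count(library, gene.contig, w, w + window - 1, mode)
            for w in starts
        )
    w0 = max(1, min(a, length - window + 1))
    return oracle_interval_count(
        library, gene.contig, w0, min(length, w0 + window - 1), mode
    )


def oracle_regions(
    window_counts: Sequence[Tuple[int, int]], window: int, cutoff: int
) -> List[Tuple[int, int, int, int]]:
    """Merge low-count windows: (start, end, n_windows, max_count) tuples."""
    marked = [(s, s + window - 1, c) for s, c in window_counts if c <= cutoff]
    regions: List[Tuple[int, int, int, int]] = []
    for s, e, c in marked:
        if regions and s <= regions[-1][1] + 1:
            ps, pe, n, mx = regions[-1]
            regions[-1] = (ps, max(pe, e), n + 1, max(mx, c))
        else:
            regions.append((s, e, 1, c))
    return regions
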