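"""Per-gene essentiality scoring and essential-region calling.

Each annotated gene is first reduced to an "effective interval" by
strand-aware truncation: insertions near the 3' end often fail to disrupt
function, and 5' starts may be mis-annotated, so by default 20% of the gene
is trimmed at the 3' end and 5% at the 5' end. Scores are then accumulated
over that interval:

* essentiality index (EI) — for a gene longer than the window, the largest
  unique-insertion count among windows fully embedded in the gene; for a
  shorter gene, the smallest count among windows fully covering it. Low EI
  suggests essentiality.
* insertion density — unique insertions (or reads) per bp.
* reads per TA site — read count divided by the number of TA dinucleotides,
  the appropriate normalization for Mariner-family transposons that insert
  only at TA sites.

A bimodal-valley cutoff on any of these metrics yields a binary
essential/non-essential call, and merging runs of low-count windows yields
candidate essential regions independent of the annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .formats_io import GENE_TABLE_COLUMNS, GeneAnnotation, GenomeRef
from .insertion_calling import InsertionLibrary
from .window_scan import WindowProfile, _interval_sum, _weights

logger = logging.getLogger("tnscan")

FLAG_EMPTY = "empty_after_truncation"
FLAG_BOUNDARY = "boundary_affected"
FLAG_EXCLUDED = "low_insertion_excluded"


@dataclass(frozen=True)
class TruncationPolicy:
    """Strand-aware trimming of gene ends before scoring.

    Each end can be trimmed by a percentage of gene length, a fixed number
    of nucleotides, or both (the larger of the two applies).
    """

    pct_5prime: float = 5.0
    pct_3prime: float = 20.0
    nt_5prime: int = 0
    nt_3prime: int = 0

    def __post_init__(self) -> None:
        if min(self.pct_5prime, self.pct_3prime, self.nt_5prime, self.nt_3prime) < 0:
            raise ValueError("truncation amounts must be non-negative")
        if self.pct_5prime >= 100 or self.pct_3prime >= 100:
            raise ValueError("percentage trims must be < 100")


#: The default 5% 5' / 20% 3' policy.
DEFAULT_POLICY = TruncationPolicy()
#: No trimming.
NO_TRUNCATION = TruncationPolicy(0.0, 0.0, 0, 0)
#: Central-80% variant: 10% trimmed at each end.
CENTRAL_80 = TruncationPolicy(10.0, 10.0, 0, 0)


class EffectiveInterval(NamedTuple):
    start: Optional[int]
    end: Optional[int]
    flags: FrozenSet[str]

    @property
    def empty(self) -> bool:
        return self.start is None

    @property
    def length(self) -> int:
        return 0 if self.empty else self.end - self.start + 1


class ScoreResult(NamedTuple):
    value: Optional[float]
    flags: FrozenSet[str]


@dataclass(frozen=True)
class EssentialRegion:
    """A run of merged overlapping low-count windows."""

    contig: str
    start: int
    end: int
    window_count: int
    max_count: int


@dataclass
class GeneRecord:
    """A gene plus its effective interval and accumulated scores."""

    annotation: GeneAnnotation
    effective_start: Optional[int]
    effective_end: Optional[int]
    flags: set = field(default_factory=set)
    scores: Dict[str, Optional[float]] = field(default_factory=dict)


def effective_interval(
    gene: GeneAnnotation, policy: TruncationPolicy = DEFAULT_POLICY
) -> EffectiveInterval:
    """Apply the truncation policy to a gene, strand-aware.

    The trim at each end is max(fixed nt, floor(pct/100 * length)). On the
    plus strand the 5' trim raises the start and the 3' trim lowers the end;
    on the minus strand the roles swap. An interval consumed entirely by the
    trims is returned empty and flagged, not an error.
    """
    L = gene.length
    removed_5 = max(policy.nt_5prime, int(policy.pct_5prime * L // 100))
    removed_3 = max(policy.nt_3prime, int(policy.pct_3prime * L // 100))
    if removed_5 + removed_3 >= L:
        return EffectiveInterval(None, None, frozenset({FLAG_EMPTY}))
    if gene.strand == "+":
        return EffectiveInterval(
            gene.start + removed_5, gene.end - removed_3, frozenset()
        )
    return EffectiveInterval(
        gene.start + removed_3, gene.end - removed_5, frozenset()
    )


def count_in_interval(
    library: InsertionLibrary,
    contig: str,
    start: int,
    end: int,
    mode: str = "unique_insertions",
) -> int:
    """Unique insertions (or summed reads) with start <= position <= end,
    both strands pooled."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    positions, prefix = _weights(library, contig, mode)
    return int(
        _interval_sum(
            positions, prefix,
            np.array([start], dtype=np.int64),
            np.array([end], dtype=np.int64),
        )[0]
    )


def essentiality_index(
    gene: GeneAnnotation,
    library: InsertionLibrary,
    genome: GenomeRef,
    window_size: int,
    policy: TruncationPolicy = DEFAULT_POLICY,
    mode: str = "unique_insertions",
) -> ScoreResult:
    """Essentiality index of one gene at the given window size.

    Windows are enumerated exhaustively at step 1 so the index does not
    depend on genome phase. With [a, b] the effective interval of length Le:

    * Le >= W: EI = max count over windows fully embedded in [a, b]
      (at Le == W the single embedded window makes both rules coincide).
    * 0 < Le < W: EI = min count over windows that fully encompass [a, b]
      and lie on the contig. If no such window fits, the count of the
      largest available window containing the gene is used and the result
      flagged boundary-affected.
    * empty interval: EI undefined, flagged.
    """
    L = genome.length
    W = int(window_size)
    if W < 1:
        raise ValueError("window_size must be >= 1")
    if W > L:
        raise ValueError(f"window size {W} exceeds contig length {L}")
    interval = effective_interval(gene, policy)
    if interval.empty:
        return ScoreResult(None, interval.flags)
    a, b = interval.start, interval.end
    positions, prefix = _weights(library, genome.contig, mode)
    if interval.length >= W:
        starts = np.arange(a, b - W + 2, dtype=np.int64)
        counts = _interval_sum(positions, prefix, starts, starts + W - 1)
        return ScoreResult(int(counts.max()), frozenset())
    lo = max(1, b - W + 1)
    hi = min(a, L - W + 1)
    if lo <= hi:
        starts = np.arange(lo, hi + 1, dtype=np.int64)
        counts = _interval_sum(positions, prefix, starts, starts + W - 1)
        return ScoreResult(int(counts.min()), frozenset())
    # No window of size W both covers the gene and fits on the contig
    # (only possible for annotations running past the contig end): fall back
    # to the largest on-contig window containing as much of the gene as fits.
    w0 = max(1, min(a, L - W + 1))
    w1 = min(L, w0 + W - 1)
    count = _interval_sum(
        positions, prefix,
        np.array([w0], dtype=np.int64), np.array([w1], dtype=np.int64),
    )[0]
    return ScoreResult(int(count), frozenset({FLAG_BOUNDARY}))


def insertion_density(
    gene: GeneAnnotation,
    library: InsertionLibrary,
    mode: str = "unique_insertions",
    policy: TruncationPolicy = DEFAULT_POLICY,
    denominator: str = "effective_length",
) -> ScoreResult:
    """Insertions (or reads) in the effective interval per bp of gene.

    ``denominator`` selects the effective (post-truncation) length or the
    full annotated length.
    """
    if denominator not in ("effective_length", "annotated_length"):
        raise ValueError(f"unknown denominator {denominator!r}")
    interval = effective_interval(gene, policy)
    if interval.empty:
        return ScoreResult(None, interval.flags)
    count = count_in_interval(
        library, gene.contig, interval.start, interval.end, mode
    )
    length = interval.length if denominator == "effective_length" else gene.length
    return ScoreResult(count / length, frozenset())


def count_ta_sites(genome: GenomeRef, contig: str, start: int, end: int) -> int:
    """TA dinucleotides starting within [start, end-1] on the forward strand.

    TA is its own reverse complement, so counting one strand suffices.
    """
    if genome.sequence is None:
        raise ValueError("TA normalization requires a FASTA genome sequence")
    if genome.contig != contig:
        raise ValueError(f"contig {contig!r} is not {genome.contig!r}")
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    return genome.sequence[start - 1 : end].count("TA")


def reads_per_ta(
    gene: GeneAnnotation,
    library: InsertionLibrary,
    genome: GenomeRef,
    policy: TruncationPolicy = DEFAULT_POLICY,
) -> ScoreResult:
    """Read density per TA site over the effective interval (Mariner mode)."""
    interval = effective_interval(gene, policy)
    if interval.empty:
        return ScoreResult(None, interval.flags)
    n_ta = count_ta_sites(genome, gene.contig, interval.start, interval.end)
    if n_ta == 0:
        return ScoreResult(None, frozenset({"no_ta_sites"}))
    reads = count_in_interval(
        library, gene.contig, interval.start, interval.end, mode="reads"
    )
    return ScoreResult(reads / n_ta, frozenset())


@dataclass
class Classification:
    """Binary essential/non-essential calls at a metric cutoff."""

    metric: str
    cutoff: float
    rule: str
    essential: FrozenSet[str]
    non_essential: FrozenSet[str]
    excluded: FrozenSet[str]

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def classify_genes(
    values: Mapping[str, Optional[float]],
    cutoff: float,
    rule: str = "lt",
    metric: str = "metric",
) -> Classification:
    """Call genes essential when their metric falls below the cutoff.

    ``rule='le'`` uses metric <= cutoff, ``rule='lt'`` uses metric < cutoff
    (so a histogram-valley value with 'lt' calls everything strictly below
    the valley essential). Genes whose metric is undefined are excluded and
    counted.
    """
    if rule not in ("le", "lt"):
        raise ValueError(f"rule must be 'le' or 'lt', got {rule!r}")
    essential, non_essential, excluded = set(), set(), set()
    for locus, value in values.items():
        if value is None or (isinstance(value, float) and np.isnan(value)):
            excluded.add(locus)
        elif (value <= cutoff) if rule == "le" else (value < cutoff):
            essential.add(locus)
        else:
            non_essential.add(locus)
    if excluded:
        logger.info("classify_genes: %d genes excluded (metric undefined)",
                    len(excluded))
    return Classification(
        metric=metric, cutoff=cutoff, rule=rule,
        essential=frozenset(essential),
        non_essential=frozenset(non_essential),
        excluded=frozenset(excluded),
    )


def call_essential_regions(
    profile: WindowProfile, cutoff: int
) -> List[EssentialRegion]:
    """Merge overlapping/abutting low-count windows into essential regions.

    Windows with count <= cutoff are marked; runs of marked windows whose
    [start, start+W-1] intervals overlap or abut are merged into one region
    spanning from the first window's start to the last window's end.
    """
    W = profile.window_size
    regions: List[EssentialRegion] = []
    cur: Optional[List[int]] = None  # [start, end, n_windows, max_count]
    for start, count in profile.items():
        if count > cutoff:
            continue
        end = start + W - 1
        if cur is not None and start <= cur[1] + 1:
            cur[1] = max(cur[1], end)
            cur[2] += 1
            cur[3] = max(cur[3], count)
        else:
            if cur is not None:
                regions.append(EssentialRegion(profile.contig, *cur))
            cur = [start, end, 1, count]
    if cur is not None:
        regions.append(EssentialRegion(profile.contig, *cur))
    return regions


def write_regions_table(regions: Sequence[EssentialRegion], path: str) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("contig\tstart\tend\twindow_count\tmax_count\n")
        for r in regions:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.window_count}\t{r.max_count}\n")


def write_regions_bed(regions: Sequence[EssentialRegion], path: str) -> None:
    """BED export; the 0-based half-open conversion happens only here."""
    with open(path, "w", newline="\n") as fh:
        for i, r in enumerate(regions, 1):
            fh.write(
                f"{r.contig}\t{r.start - 1}\t{r.end}\t"
                f"essential_region_{i}\t{r.max_count}\t.\n"
            )


# ---------------------------------------------------------------------------
# Gene score table
# ---------------------------------------------------------------------------

class GeneTable:
    """Append-only per-gene score table backed by a DataFrame.

    Every analysis adds a new named column; existing columns are never
    mutated, and a name collision is resolved by suffixing a running index
    (with a warning), mirroring how repeated spreadsheet analyses pile up.
    """

    def __init__(self, genes: Sequence[GeneAnnotation]):
        self.genes = list(genes)
        self._frame = pd.DataFrame(
            [
                (g.contig, g.locus_tag, g.symbol, g.description,
                 g.start, g.end, g.strand)
                for g in self.genes
            ],
            columns=list(GENE_TABLE_COLUMNS),
        )

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def columns(self) -> List[str]:
        return list(self._frame.columns)

    def add_column(self, name: str, values_by_locus: Mapping[str, object]) -> str:
        """Append one column; returns the (possibly suffixed) name used."""
        final = name
        i = 1
        while final in self._frame.columns:
            i += 1
            final = f"{name}.{i}"
        if final != name:
            logger.warning(
                "column %r already present; using %r", name, final
            )
        self._frame[final] = [
            values_by_locus.get(g.locus_tag) for g in self.genes
        ]
        return final

    def column(self, name: str) -> Dict[str, object]:
        return dict(zip(self._frame["locus_tag"], self._frame[name]))

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()


def build_gene_table(
    genes: Sequence[GeneAnnotation],
    libraries: Mapping[str, InsertionLibrary],
    analyses: Sequence[Mapping[str, object]],
    genomes: Optional[Mapping[str, GenomeRef]] = None,
    table: Optional[GeneTable] = None,
) -> GeneTable:
    """Run a list of analyses over all genes, one appended column each.

    Each analysis is a mapping with keys ``metric`` (one of ``ei``,
    ``density``, ``reads_per_ta``, ``count``), ``library`` (a key of
    ``libraries``) and metric-specific parameters (``window_size``,
    ``policy``, ``mode``, ``denominator``). Column order follows the
    analysis list; column names are ``<library>.<metric>`` plus the window
    size for EI.
    """
    table = table if table is not None else GeneTable(genes)
    genomes = genomes or {}

    def genome_for(contig: str) -> GenomeRef:
        if contig not in genomes:
            raise ValueError(f"no genome provided for contig {contig!r}")
        return genomes[contig]

    for spec in analyses:
        metric = spec["metric"]
        lib_name = spec["library"]
        if lib_name not in libraries:
            raise ValueError(f"unknown library {lib_name!r}")
        library = libraries[lib_name]
        policy = spec.get("policy", DEFAULT_POLICY)
        mode = spec.get("mode", "unique_insertions")
        values: Dict[str, object] = {}
        if metric == "ei":
            W = int(spec["window_size"])
            name = f"{lib_name}.EI.W{W}"
            for g in table.genes:
                values[g.locus_tag] = essentiality_index(
                    g, library, genome_for(g.contig), W, policy=policy, mode=mode
                ).value
        elif metric == "density":
            name = f"{lib_name}.density"
            denominator = spec.get("denominator", "effective_length")
            for g in table.genes:
                values[g.locus_tag] = insertion_density(
                    g, library, mode=mode, policy=policy, denominator=denominator
                ).value
        elif metric == "reads_per_ta":
            name = f"{lib_name}.reads_per_ta"
            for g in table.genes:
                values[g.locus_tag] = reads_per_ta(
                    g, library, genome_for(g.contig), policy=policy
                ).value
        elif metric == "count":
            name = f"{lib_name}.count"
            for g in table.genes:
                interval = effective_interval(g, policy)
                values[g.locus_tag] = (
                    None if interval.empty else count_in_interval(
                        library, g.contig, interval.start, interval.end, mode
                    )
                )
        else:
            raise ValueError(f"unknown metric {metric!r}")
        table.add_column(name, values)
    return table
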