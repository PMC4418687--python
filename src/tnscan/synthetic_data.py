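"""Synthetic genomes and transposon mutant libraries with known ground truth.

The simulator emulates the salient features of a real Tn-seq experiment:

* a bacterial-scale genome densely packed with non-overlapping genes whose
  lengths follow a log-normal distribution (median ~900 bp);
* a planted essential-gene subset depleted of insertions — mutants with
  insertions in essential genes are not viable, except for a small "leak"
  probability modeling insertions that fail to disrupt function;
  depletion applies to the gene's default effective interval (5% 5' / 20%
  3' trims), since 3'-end insertions often do not abolish function;
* insertion sites drawn uniformly over the genome (Tn5-like) or uniformly
  over TA dinucleotides (Mariner-like), each with a random orientation;
* a heavy-tailed reads-per-unique-insertion distribution, drawn from a
  truncated discrete power law — real libraries show a few insertions with
  thousands of reads while a quarter are singletons.

Every output is reproducible from the seed, and the library can be emitted
as a SAM file of perfect-match single-end reads whose 5' ends sit exactly
on the simulated junctions, so the whole read-in/collapse pipeline can be
round-tripped against the simulated truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np

from .essentiality import DEFAULT_POLICY, TruncationPolicy, effective_interval
from .formats_io import GeneAnnotation, GenomeRef
from .insertion_calling import InsertionKey, InsertionLibrary


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulated experiment."""

    genome_length: int = 2_000_000
    n_genes: int = 1_800
    essential_fraction: float = 0.10
    n_unique_insertions: int = 25_000
    insertion_model: str = "uniform"  # or "ta_only"
    essential_leak: float = 0.02
    read_bias_alpha: float = 1.8
    max_reads_per_insertion: int = 5_000
    seed: int = 0
    gene_length_median: float = 900.0
    gene_length_sigma: float = 0.4

    def __post_init__(self) -> None:
        if min(self.genome_length, self.n_genes, self.n_unique_insertions,
               self.max_reads_per_insertion) < 1:
            raise ValueError("all counts must be positive")
        if not (0.0 <= self.essential_fraction <= 1.0):
            raise ValueError("essential_fraction must be in [0, 1]")
        if not (0.0 <= self.essential_leak <= 1.0):
            raise ValueError("essential_leak must be in [0, 1]")
        if self.read_bias_alpha <= 1.0:
            raise ValueError("read_bias_alpha must be > 1")
        if self.insertion_model not in ("uniform", "ta_only"):
            raise ValueError(f"unknown insertion_model {self.insertion_model!r}")


@dataclass
class SimTruth:
    """Ground truth of a simulation, for recovery tests."""

    essential_locus_tags: FrozenSet[str]
    gene_status: Dict[str, bool]  # locus_tag -> is_essential
    library: Optional[InsertionLibrary] = None


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int,
                     ta_enriched: bool) -> str:
    if not ta_enriched:
        return rng.choice(_BASES, size=length).tobytes().decode("ascii")
    # Dinucleotide units with a boosted chance of "TA" so Mariner-style
    # simulations have plenty of target sites (~1 TA per 8 bp).
    n_units = (length + 1) // 2
    ta_mask = rng.random(n_units) < 0.15
    units = rng.choice(_BASES, size=(n_units, 2))
    units[ta_mask, 0] = ord("T")
    units[ta_mask, 1] = ord("A")
    return units.tobytes().decode("ascii")[:length]


def simulate_genome(
    params: SimParams,
) -> Tuple[GenomeRef, List[GeneAnnotation], SimTruth]:
    """Generate a genome, a non-overlapping gene annotation, and truth labels.

    Gene lengths are log-normal (median ``gene_length_median``); genes are
    laid out left to right with intergenic gaps splitting the leftover
    sequence at sorted uniform breakpoints, strands assigned at random, and
    exactly round(n_genes * essential_fraction) genes labeled essential,
    drawn without replacement. Fully reproducible from the seed.
    """
    rng = np.random.default_rng([params.seed, 0])
    mu = math.log(params.gene_length_median)
    lengths = np.round(
        rng.lognormal(mean=mu, sigma=params.gene_length_sigma,
                      size=params.n_genes)
    ).astype(np.int64)
    lengths = np.clip(lengths, 150, None)
    total_genic = int(lengths.sum())
    if total_genic > params.genome_length:
        raise ValueError(
            f"cannot pack {params.n_genes} genes totaling {total_genic} bp "
            f"into {params.genome_length} bp"
        )
    slack = params.genome_length - total_genic
    cuts = np.sort(rng.integers(0, slack + 1, size=params.n_genes + 1))
    gaps = np.diff(np.concatenate(([0], cuts)))  # n_genes+1 gaps summing <= slack
    strands = rng.choice(np.array(["+", "-"]), size=params.n_genes)

    genes: List[GeneAnnotation] = []
    width = max(4, len(str(params.n_genes)))
    pos = 1
    for i in range(params.n_genes):
        pos += int(gaps[i])
        start = pos
        end = start + int(lengths[i]) - 1
        genes.append(
            GeneAnnotation(
                contig="simchr",
                locus_tag=f"SIM{i + 1:0{width}d}",
                symbol="",
                description="simulated gene",
                start=start,
                end=end,
                strand=str(strands[i]),
            )
        )
        pos = end + 1

    n_essential = int(round(params.n_genes * params.essential_fraction))
    essential_idx = rng.choice(params.n_genes, size=n_essential, replace=False)
    essential = frozenset(genes[i].locus_tag for i in essential_idx)

    sequence = _random_sequence(
        rng, params.genome_length,
        ta_enriched=(params.insertion_model == "ta_only"),
    )
    genome = GenomeRef("simchr", params.genome_length, sequence, circular=False)
    truth = SimTruth(
        essential_locus_tags=essential,
        gene_status={g.locus_tag: g.locus_tag in essential for g in genes},
    )
    return genome, genes, truth


def _power_law_counts(
    rng: np.random.Generator, n: int, alpha: float, k_max: int
) -> np.ndarray:
    """Inverse-CDF sampling of P(k) proportional to k^-alpha on 1..k_max."""
    k = np.arange(1, k_max + 1, dtype=float)
    cdf = np.cumsum(k**-alpha)
    cdf /= cdf[-1]
    return np.searchsorted(cdf, rng.random(n), side="left") + 1


def simulate_library(
    genome: GenomeRef,
    annotation: List[GeneAnnotation],
    truth: SimTruth,
    params: SimParams,
    sam_path: Optional[str] = None,
    depletion_policy: TruncationPolicy = DEFAULT_POLICY,
) -> InsertionLibrary:
    """Place unique insertions with essential-gene depletion and read bias.

    Candidate sites are drawn uniformly over the genome (or over TA
    positions in ``ta_only`` mode) with a random strand; a candidate inside
    an essential gene's effective interval is retained with probability
    ``essential_leak``, otherwise discarded and redrawn, until
    ``n_unique_insertions`` distinct (position, strand) keys are placed.
    Read counts follow the truncated power law. When ``sam_path`` is given,
    the library is also written as SAM (see :func:`write_simulated_sam`).
    """
    rng = np.random.default_rng([params.seed, 1])
    L = genome.length

    # Effective spans of essential genes, as sorted arrays for fast lookup.
    ess_starts, ess_ends = [], []
    for gene in annotation:
        if truth.gene_status.get(gene.locus_tag):
            interval = effective_interval(gene, depletion_policy)
            if not interval.empty:
                ess_starts.append(interval.start)
                ess_ends.append(interval.end)
    order = np.argsort(ess_starts) if ess_starts else np.empty(0, int)
    ess_starts = np.asarray(ess_starts, dtype=np.int64)[order]
    ess_ends = np.asarray(ess_ends, dtype=np.int64)[order]

    if params.insertion_model == "ta_only":
        seq = np.frombuffer((genome.sequence or "").encode("ascii"), dtype=np.uint8)
        ta_pos = np.flatnonzero((seq[:-1] == ord("T")) & (seq[1:] == ord("A"))) + 1
        if ta_pos.size == 0:
            raise ValueError("ta_only insertion model but the genome has no TA sites")

    def in_essential(pos: np.ndarray) -> np.ndarray:
        if ess_starts.size == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(ess_starts, pos, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(pos.shape, dtype=bool)
        hit[ok] = pos[ok] <= ess_ends[idx[ok]]
        return hit

    chosen: Dict[InsertionKey, None] = {}
    max_rounds = 1000
    for _ in range(max_rounds):
        need = params.n_unique_insertions - len(chosen)
        if need <= 0:
            break
        batch = max(need * 2, 1024)
        if params.insertion_model == "ta_only":
            pos = rng.choice(ta_pos, size=batch)
        else:
            pos = rng.integers(1, L + 1, size=batch)
        strand = np.where(rng.random(batch) < 0.5, "+", "-")
        reject = in_essential(pos) & (rng.random(batch) >= params.essential_leak)
        for p, s, r in zip(pos, strand, reject):
            if r:
                continue
            key = ("simchr", int(p), str(s))
            if key not in chosen:
                chosen[key] = None
                if len(chosen) == params.n_unique_insertions:
                    break
    else:
        raise RuntimeError(
            "could not place the requested number of unique insertions; "
            "the genome or TA-site pool is too small for the request"
        )

    keys = sorted(chosen)
    counts = _power_law_counts(
        rng, len(keys), params.read_bias_alpha, params.max_reads_per_insertion
    )
    library = InsertionLibrary(
        name=f"sim-seed{params.seed}",
        counts=dict(zip(keys, (int(c) for c in counts))),
        source=f"simulated (seed={params.seed}, model={params.insertion_model})",
    )
    truth.library = library
    if sam_path is not None:
        write_simulated_sam(library, genome, sam_path)
    return library


def write_simulated_sam(
    library: InsertionLibrary,
    genome: GenomeRef,
    path: str,
    read_length: int = 50,
    mapq: int = 60,
) -> None:
    """Emit the library as perfect-match single-end SAM records.

    Each insertion yields ``read_count`` identical records whose 5' end is
    the junction: forward reads start at the insertion position; reverse
    reads end there (leftmost position shifted back by the read length).
    Reads are clipped at contig edges so the junction geometry is preserved
    even within one read length of an end.
    """
    L = genome.length
    seq = genome.sequence
    with open(path, "w", newline="\n") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{genome.contig}\tLN:{L}\n")
        fh.write("@PG\tID:tnscan\tPN:tnscan\n")
        serial = 0
        for ins in library:
            if ins.strand == "+":
                start = ins.position
                rl = min(read_length, L - start + 1)
                flag = 0
            else:
                start = max(1, ins.position - read_length + 1)
                rl = ins.position - start + 1
                flag = 16
            bases = seq[start - 1 : start - 1 + rl] if seq else "N" * rl
            qual = "I" * rl
            for _ in range(ins.read_count):
                serial += 1
                fh.write(
                    f"r{serial:09d}\t{flag}\t{ins.contig}\t{start}\t{mapq}\t"
                    f"{rl}M\t*\t0\t0\t{bases}\t{qual}\n"
                )


def write_truth_table(truth: SimTruth, path: str) -> None:
    """Tab-delimited per-gene ground-truth labels for test harnesses."""
    with open(path, "w", newline="\n") as fh:
        fh.write("locus_tag\tessential\n")
        for locus, status in sorted(truth.gene_status.items()):
            fh.write(f"{locus}\t{'yes' if status else 'no'}\n")
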