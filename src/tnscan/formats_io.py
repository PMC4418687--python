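"""Input/output: SAM alignments, gene annotations, FASTA genomes, result tables.

SAM is read through pysam, FASTA through Biopython, GFF3 through gffutils.
The durable outputs of the toolkit — the per-library unique-insertion catalog
and the per-gene score table — are plain tab-delimited text with a header
row, so they can be inspected and edited in a spreadsheet. The 7-column
``gene_table`` annotation dialect (contig, locus_tag, symbol, description,
start, end, strand; ``#`` comments allowed) exists for the same reason:
annotations stay editable by the user.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple

import pandas as pd
import pysam
from Bio import SeqIO

from .insertion_calling import InsertionLibrary

logger = logging.getLogger("tnscan")

_CIGAR_OPS = "MIDNSHP=X"
_IUPAC = set("ACGTNRYSWKMBDHV")
_AMBIGUOUS = str.maketrans({c: "N" for c in "RYSWKMBDHV"})

GENE_TABLE_COLUMNS = (
    "contig", "locus_tag", "symbol", "description", "start", "end", "strand",
)


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedRead:
    """A mapped, primary, non-supplementary SAM record (post accept-filter)."""

    query_name: str
    contig: str
    pos: int  # 1-based leftmost mapped reference coordinate
    strand: str  # '+' or '-', from SAM flag 0x10
    cigar: Tuple[Tuple[str, int], ...]
    mapq: int
    flags: int


@dataclass(frozen=True)
class GeneAnnotation:
    """An annotated gene with 1-based inclusive coordinates."""

    contig: str
    locus_tag: str
    symbol: str
    description: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.locus_tag}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.locus_tag}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRef:
    """A reference contig; sequence is optional (needed only for TA counting)."""

    contig: str
    length: int
    sequence: Optional[str] = None
    circular: bool = False

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.length:
            raise FormatError(
                f"contig {self.contig}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


# ---------------------------------------------------------------------------
# SAM alignments
# ---------------------------------------------------------------------------

def _synthesize_header(path: str) -> str:
    """Build a temp SAM with an @SQ header for a headerless single-contig file.

    pysam's text SAM reader requires @SQ lines; a headerless file is accepted
    only when every record names the same contig.
    """
    contigs: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                raise FormatError(
                    f"{path}: malformed SAM line {lineno} ({len(fields)} fields)"
                )
            rname = fields[2]
            if rname == "*":
                continue
            try:
                pos = int(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}: malformed SAM line {lineno}") from exc
            # pos + total CIGAR length over-estimates the reference span,
            # which is all the synthetic @SQ LN needs.
            span = sum(int(tok) for tok in _split_cigar_lengths(fields[5]))
            contigs[rname] = max(contigs.get(rname, 1), pos + span + 1)
    if len(contigs) > 1:
        raise FormatError(
            f"{path}: headerless SAM names multiple contigs "
            f"({', '.join(sorted(contigs))}); a header is required"
        )
    tmp = tempfile.NamedTemporaryFile(
        "w", suffix=".sam", prefix="tnscan_", delete=False
    )
    tmp.write("@HD\tVN:1.6\tSO:unknown\n")
    for rname, ln in contigs.items():
        tmp.write(f"@SQ\tSN:{rname}\tLN:{ln}\n")
    with open(path) as fh:
        for line in fh:
            tmp.write(line)
    tmp.close()
    return tmp.name


def _split_cigar_lengths(cigar: str) -> Iterator[str]:
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if num:
                yield num
            num = ""
    if num:
        yield num


def read_alignments(
    path: str, min_mapq: int = 0, keep_duplicates: bool = True
) -> Iterator[AlignedRead]:
    """Stream accepted alignments from a SAM file.

    Yields only mapped, primary, non-supplementary records with
    ``mapq >= min_mapq``, in file order. Duplicate-flagged (0x400) records
    are kept by default: in Tn-seq many independent junction fragments map
    to the same coordinates, so "duplicates" are signal. The number of
    yielded records is logged when the stream is exhausted.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.readline()
    tmp_path = None
    use_path = path
    if first and not first.startswith("@"):
        tmp_path = _synthesize_header(path)
        use_path = tmp_path
    n_yielded = 0
    n_seen = 0
    try:
        with pysam.AlignmentFile(use_path, "r", check_sq=True) as sam:
            try:
                for rec in sam:
                    n_seen += 1
                    if rec.is_unmapped:
                        # pysam silently unmaps records whose RNAME is not in
                        # the header (flag forced to 0x4, reference dropped,
                        # position kept); surface that as the error it is.
                        if rec.reference_id < 0 and rec.reference_start >= 0:
                            raise FormatError(
                                f"{path}: record {rec.query_name!r} names a "
                                "contig absent from the SAM header"
                            )
                        continue
                    if rec.is_secondary or rec.is_supplementary:
                        continue
                    if not keep_duplicates and rec.is_duplicate:
                        continue
                    if rec.mapping_quality < min_mapq:
                        continue
                    cigar = tuple(
                        (_CIGAR_OPS[op], length)
                        for op, length in (rec.cigartuples or ())
                    )
                    n_yielded += 1
                    yield AlignedRead(
                        query_name=rec.query_name or "",
                        contig=rec.reference_name,
                        pos=rec.reference_start + 1,
                        strand="-" if rec.is_reverse else "+",
                        cigar=cigar,
                        mapq=rec.mapping_quality,
                        flags=rec.flag,
                    )
            except FormatError:
                raise
            except (ValueError, OSError) as exc:
                n_header = sum(
                    1 for line in str(sam.header).splitlines() if line.strip()
                )
                raise FormatError(
                    f"{path}: cannot parse SAM record at line "
                    f"{n_header + n_seen + 1}: {exc}"
                ) from exc
    finally:
        if tmp_path is not None:
            os.unlink(tmp_path)
    logger.info("read_alignments(%s): %d records accepted", path, n_yielded)


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

def _detect_annotation_format(path: str) -> str:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##gff-version"):
                return "gff3"
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 9 and fields[3].isdigit() and fields[4].isdigit():
                return "gff3"
            if len(fields) == 7 and fields[4].isdigit() and fields[5].isdigit():
                return "gene_table"
            break
    raise FormatError(f"{path}: cannot detect annotation format")


def _read_gene_table(path: str) -> List[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise FormatError(
                    f"{path}:{lineno}: expected 7 tab-separated columns, "
                    f"got {len(fields)}"
                )
            contig, locus_tag, symbol, description, start, end, strand = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric coordinates"
                ) from exc
            genes.append(
                GeneAnnotation(contig, locus_tag, symbol, description,
                               start_i, end_i, strand)
            )
    return genes


def _read_gff3(path: str) -> List[GeneAnnotation]:
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: List[GeneAnnotation] = []
    feature_types = [t for t in ("gene", "CDS") if t in set(db.featuretypes())]
    seen_from_gene = set()
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            locus = (
                feat.attributes.get("locus_tag", [None])[0]
                or feat.attributes.get("ID", [None])[0]
                or feat.attributes.get("Name", [None])[0]
            )
            if locus is None:
                raise FormatError(
                    f"{path}: {ftype} feature at {feat.seqid}:{feat.start} "
                    "lacks locus_tag/ID/Name"
                )
            if ftype == "CDS" and locus in seen_from_gene:
                continue  # CDS child of an already-collected gene row
            symbol = (
                feat.attributes.get("gene", [None])[0]
                or feat.attributes.get("Name", [""])[0]
                or ""
            )
            if symbol == locus:
                symbol = ""
            description = (
                feat.attributes.get("product", [None])[0]
                or feat.attributes.get("description", [""])[0]
                or ""
            )
            strand = feat.strand if feat.strand in ("+", "-") else "+"
            genes.append(
                GeneAnnotation(feat.seqid, locus, symbol, description,
                               feat.start, feat.end, strand)
            )
            if ftype == "gene":
                seen_from_gene.add(locus)
    return genes


def read_gene_annotation(
    path: str, format: Optional[str] = None
) -> List[GeneAnnotation]:
    """Read gene annotations from GFF3 or the 7-column gene_table dialect.

    Returns genes sorted by (contig, start). Raises on duplicate locus tags
    or start > end.
    """
    fmt = format or _detect_annotation_format(path)
    if fmt == "gene_table":
        genes = _read_gene_table(path)
    elif fmt == "gff3":
        genes = _read_gff3(path)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    seen = set()
    for gene in genes:
        if gene.locus_tag in seen:
            raise FormatError(f"{path}: duplicate locus_tag {gene.locus_tag}")
        seen.add(gene.locus_tag)
    genes.sort(key=lambda g: (g.contig, g.start, g.end, g.locus_tag))
    return genes


def write_gene_annotation(genes: Sequence[GeneAnnotation], path: str) -> None:
    """Write the editable 7-column gene_table dialect."""
    with open(path, "w", newline="\n") as fh:
        fh.write("# " + "\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                f"{g.contig}\t{g.locus_tag}\t{g.symbol}\t{g.description}\t"
                f"{g.start}\t{g.end}\t{g.strand}\n"
            )


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------

def read_genome_fasta(path: str, circular: bool = False) -> List[GenomeRef]:
    """Read a FASTA genome; sequences are uppercased and IUPAC-validated.

    Ambiguity codes other than N are mapped to N (they carry no information
    for TA counting); anything outside the IUPAC DNA alphabet is an error.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    refs: List[GenomeRef] = []
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate contig name {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC
        if bad:
            raise FormatError(
                f"{path}: contig {rec.id} contains non-IUPAC characters "
                f"{sorted(bad)}"
            )
        seq = seq.translate(_AMBIGUOUS)
        refs.append(GenomeRef(rec.id, len(seq), seq, circular=circular))
    return refs


def write_genome_fasta(refs: Sequence[GenomeRef], path: str, width: int = 70) -> None:
    with open(path, "w", newline="\n") as fh:
        for ref in refs:
            if ref.sequence is None:
                raise ValueError(f"contig {ref.contig} has no sequence to write")
            fh.write(f">{ref.contig}\n")
            for i in range(0, len(ref.sequence), width):
                fh.write(ref.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Insertion tables
# ---------------------------------------------------------------------------

_INSERTION_HEADER = "contig\tposition\tstrand\tread_count"


def write_insertion_table(library: InsertionLibrary, path: str) -> None:
    """Write the complete unique-insertion catalog as tab-delimited text."""
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# library: {library.name}\n")
        if library.source:
            fh.write(f"# source: {library.source}\n")
        fh.write(f"# unique_insertions: {len(library)}\n")
        fh.write(f"# total_reads: {library.total_reads}\n")
        fh.write(_INSERTION_HEADER + "\n")
        for ins in library:
            fh.write(f"{ins.contig}\t{ins.position}\t{ins.strand}\t{ins.read_count}\n")


def read_insertion_table(path: str) -> InsertionLibrary:
    """Read an insertion table written by :func:`write_insertion_table`."""
    name = os.path.splitext(os.path.basename(path))[0]
    source = f"insertion table {path}"
    counts = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# library:"):
                    name = line.split(":", 1)[1].strip()
                elif line.startswith("# source:"):
                    source = line.split(":", 1)[1].strip()
                continue
            if line == _INSERTION_HEADER:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 columns, got {len(fields)}"
                )
            contig, pos_s, strand, count_s = fields
            try:
                pos, count = int(pos_s), int(count_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from exc
            if pos < 1:
                raise FormatError(f"{path}:{lineno}: position {pos} < 1")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            if count < 1:
                raise FormatError(f"{path}:{lineno}: read_count {count} < 1")
            key = (contig, pos, strand)
            if key in counts:
                raise FormatError(f"{path}:{lineno}: duplicate insertion {key}")
            counts[key] = count
    return InsertionLibrary(name, counts, source=source)


# ---------------------------------------------------------------------------
# Gene score tables
# ---------------------------------------------------------------------------

def write_gene_table(table, path: str) -> None:
    """Write a per-gene score table (tab-delimited, UTF-8, LF, 4-decimal floats).

    ``table`` is a pandas DataFrame or any object with a ``to_frame()``
    method returning one (e.g. :class:`tnscan.essentiality.GeneTable`).
    """
    frame = table if isinstance(table, pd.DataFrame) else table.to_frame()
    frame.to_csv(
        path, sep="\t", index=False, float_format="%.4f",
        lineterminator="\n", encoding="utf-8",
    )


def read_gene_table(path: str) -> pd.DataFrame:
    """Read back a gene score table as a DataFrame."""
    return pd.read_csv(path, sep="\t")


def write_histogram(histogram, path: str) -> None:
    """Export a CountHistogram as two-column (value, frequency) text."""
    with open(path, "w", newline="\n") as fh:
        fh.write("count\tfrequency\n")
        for value, freq in histogram.to_rows():
            fh.write(f"{value}\t{freq}\n")
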