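"""Transcript models, spliced sequences, read QC and RPKM.

Consumes assembler output (Cufflinks-style GTF) and a reference genome;
read alignment and assembly themselves are external.  Coordinates are
0-based half-open internally and converted at the GTF boundary
(1-based inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import (
    ConfigurationError,
    CoordinateError,
    ParseError,
    UndefinedResultError,
)


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded multi-exon transcript on genomic coordinates."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple  # ((start, end), ...) 0-based half-open, sorted by start
    source_tag: str = "assembled"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        exons = tuple((int(a), int(b)) for a, b in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for a, b in exons:
            if b <= a:
                raise ValueError(f"empty exon [{a}, {b})")
            if prev_end is not None and a < prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = b
        if not exons:
            raise ValueError("transcript needs at least one exon")

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def span(self) -> tuple:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class ExpressionRecord:
    """Uniquely-mapped read count and RPKM for one transcript."""

    transcript_id: str
    read_count: int
    rpkm: float


def read_gtf(path, source_tag: str = "assembled") -> List[TranscriptModel]:
    """Parse exon features of a GTF into transcript models.

    Exons are grouped by ``transcript_id``; each exon must also carry a
    ``gene_id``.  Mixed strands or chromosomes within one transcript, or
    overlapping exons, are rejected.
    """
    per_tx: Dict[str, dict] = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:
                raise ParseError(f"unparseable GTF line: {exc}", path, lineno)
            if feat.featuretype != "exon":
                continue
            attrs = feat.attributes
            if "transcript_id" not in attrs or not attrs["transcript_id"]:
                raise ParseError("exon missing transcript_id", path, lineno)
            if "gene_id" not in attrs or not attrs["gene_id"]:
                raise ParseError("exon missing gene_id", path, lineno)
            tid = attrs["transcript_id"][0]
            gid = attrs["gene_id"][0]
            if feat.strand not in ("+", "-"):
                raise ParseError(
                    f"exon of {tid} lacks a +/- strand", path, lineno
                )
            rec = per_tx.get(tid)
            if rec is None:
                per_tx[tid] = rec = {
                    "gene_id": gid,
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "exons": [],
                }
                order.append(tid)
            else:
                if rec["strand"] != feat.strand:
                    raise ParseError(
                        f"mixed strands within transcript {tid}", path, lineno
                    )
                if rec["chrom"] != feat.seqid:
                    raise ParseError(
                        f"mixed chromosomes within transcript {tid}", path, lineno
                    )
            rec["exons"].append((feat.start - 1, feat.end))

    models = []
    for tid in order:
        rec = per_tx[tid]
        exons = sorted(rec["exons"])
        try:
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=rec["gene_id"],
                    chrom=rec["chrom"],
                    strand=rec["strand"],
                    exons=tuple(exons),
                    source_tag=source_tag,
                )
            )
        except ValueError as exc:
            raise ParseError(f"transcript {tid}: {exc}", path)
    return models


def write_gtf(models: Sequence[TranscriptModel], path, source: str = "epilinc") -> None:
    """Write exon features, inverse of :func:`read_gtf`."""
    with open(path, "w") as fh:
        for m in models:
            for a, b in m.exons:
                fh.write(
                    f"{m.chrom}\t{source}\texon\t{a + 1}\t{b}\t.\t{m.strand}\t.\t"
                    f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";\n'
                )


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    try:
        contig = genome[chrom]
    except KeyError:
        raise CoordinateError(f"chromosome {chrom!r} not in genome") from None
    if start < 0 or end > len(contig):
        raise CoordinateError(
            f"interval [{start}, {end}) outside {chrom} (length {len(contig)})"
        )
    return str(contig[start:end])


def spliced_sequence(model: TranscriptModel, genome) -> str:
    """The transcript's mature sequence: exons concatenated in genomic
    order, reverse-complemented as a whole for minus-strand models.

    ``genome`` is any mapping of chromosome name to a sliceable sequence
    (a plain dict of strings or a ``pyfaidx.Fasta``).  Soft-masked bases
    are uppercased; coding-potential features are case-insensitive.
    """
    parts = [_fetch(genome, model.chrom, a, b) for a, b in model.exons]
    seq = "".join(parts).upper()
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def fastq_quality_filter(
    sequence: str,
    quality,
    max_n_fraction: float = 0.10,
    min_quality: int = 20,
    min_good_fraction: float = 0.85,
) -> bool:
    """Keep/discard decision for one read.

    A read is kept iff its N fraction is strictly below ``max_n_fraction``
    and the fraction of bases with Phred quality strictly above
    ``min_quality`` is strictly above ``min_good_fraction``.  ``quality``
    is a Phred+33 string or a sequence of integer scores.  Empty reads
    are discarded.
    """
    if isinstance(quality, str):
        scores = [ord(ch) - 33 for ch in quality]
    else:
        scores = list(quality)
    if len(scores) != len(sequence):
        raise ParseError(
            f"sequence length {len(sequence)} != quality length {len(scores)}"
        )
    n = len(sequence)
    if n == 0:
        return False
    n_frac = sequence.upper().count("N") / n
    good_frac = sum(1 for q in scores if q > min_quality) / n
    return n_frac < max_n_fraction and good_frac > min_good_fraction


def filter_fastq(in_path, out_path=None, **thresholds) -> tuple:
    """Apply :func:`fastq_quality_filter` to a Phred+33 FASTQ file.

    Returns (n_total, n_kept); kept reads are written to ``out_path``
    when given.
    """
    n_total = n_kept = 0
    kept = []
    for rec in SeqIO.parse(str(in_path), "fastq"):
        n_total += 1
        if fastq_quality_filter(
            str(rec.seq), rec.letter_annotations["phred_quality"], **thresholds
        ):
            n_kept += 1
            kept.append(rec)
    if out_path is not None:
        with open(out_path, "w") as fh:
            SeqIO.write(kept, fh, "fastq")
    return n_total, n_kept


def rpkm(read_count: int, exon_length_nt: int, total_mapped: int) -> float:
    """Reads per kilobase of exon model per million mapped reads:
    ``1e9 * read_count / (total_mapped * exon_length_nt)``."""
    if exon_length_nt < 1:
        raise ConfigurationError("exon_length_nt must be >= 1")
    if total_mapped < 1:
        raise UndefinedResultError("total_mapped must be >= 1")
    if read_count < 0:
        raise ConfigurationError("read_count must be non-negative")
    return 1e9 * read_count / (total_mapped * exon_length_nt)


def read_counts_table(path) -> pd.DataFrame:
    """Read a 3-column TSV (transcript_id, read_count, library_size)."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"transcript_id": str, "read_count": int, "library_size": int},
    )
    missing = {"transcript_id", "read_count", "library_size"} - set(df.columns)
    if missing:
        raise ParseError(f"counts table missing columns {sorted(missing)}", path)
    return df


def compute_expression(
    models: Sequence[TranscriptModel], counts: pd.DataFrame
) -> List[ExpressionRecord]:
    """RPKM for every model present in the counts table."""
    by_id = {m.transcript_id: m for m in models}
    records = []
    for row in counts.itertuples(index=False):
        model = by_id.get(row.transcript_id)
        if model is None:
            continue
        records.append(
            ExpressionRecord(
                transcript_id=row.transcript_id,
                read_count=int(row.read_count),
                rpkm=rpkm(int(row.read_count), model.length, int(row.library_size)),
            )
        )
    return records
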