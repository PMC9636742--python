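"""Anchor assembled transcripts at epimutation sites and place them
relative to the annotation.

An assembled transcript is a candidate only if one of the called CpG
sites falls inside (or within a configurable window of) its genomic
span.  Retained candidates are then screened positionally: transcripts
inside the 1-kb flanks of annotated genes are removed, except — by
default — purely antisense overlaps, so that an antisense lncRNA
transcribed opposite an annotated gene survives the cascade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence

from intervaltree import IntervalTree

from .epimutation import EpimutationCall
from .transcriptome import TranscriptModel


@dataclass(frozen=True)
class AnchorResult:
    """One (transcript, call) anchoring with its positional relation."""

    transcript: TranscriptModel
    anchor: EpimutationCall
    anchor_relation: str  # exonic | intronic | within_window
    distance_nt: int


@dataclass(frozen=True)
class GeneSpan:
    """Union span of one annotated gene's transcripts."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int


@dataclass(frozen=True)
class PositionClass:
    """Positional class of a candidate relative to the annotation."""

    transcript_id: str
    klass: str  # intergenic | antisense_overlap | sense_overlap | flank_proximal
    nearest_gene_id: str | None
    nearest_distance_nt: float  # 0 when overlapping; inf when no annotation


def anchor_transcripts(
    transcripts: Sequence[TranscriptModel],
    calls: Sequence[EpimutationCall],
    window_nt: int = 0,
) -> List[AnchorResult]:
    """All (transcript, call) pairs where the call lies within the
    transcript span or within ``window_nt`` of it.

    Inside the span the relation is ``exonic`` or ``intronic`` and the
    distance 0; outside it is ``within_window`` with the gap in nt
    (1 for the base immediately past the span's half-open end).
    """
    if window_nt < 0:
        raise ValueError("window_nt must be >= 0")
    results = []
    for tx in transcripts:
        start, end = tx.span
        for call in sorted(calls, key=lambda c: c.rank):
            if call.site.chrom != tx.chrom:
                continue
            pos = call.site.pos
            if start <= pos < end:
                relation = "intronic"
                for a, b in tx.exons:
                    if a <= pos < b:
                        relation = "exonic"
                        break
                results.append(AnchorResult(tx, call, relation, 0))
            else:
                dist = start - pos if pos < start else pos - end + 1
                if 0 < dist <= window_nt:
                    results.append(AnchorResult(tx, call, "within_window", dist))
    return results


def gene_spans(annotation: Sequence[TranscriptModel]) -> List[GeneSpan]:
    """Per-gene union spans over the annotation's transcripts."""
    acc: Dict[str, dict] = {}
    for tx in annotation:
        s, e = tx.span
        rec = acc.get(tx.gene_id)
        if rec is None:
            acc[tx.gene_id] = {
                "chrom": tx.chrom, "strand": tx.strand, "start": s, "end": e
            }
        else:
            if rec["chrom"] != tx.chrom:
                raise ValueError(
                    f"gene {tx.gene_id} spans multiple chromosomes"
                )
            rec["start"] = min(rec["start"], s)
            rec["end"] = max(rec["end"], e)
    return [
        GeneSpan(gid, r["chrom"], r["strand"], r["start"], r["end"])
        for gid, r in acc.items()
    ]


def _span_trees(spans: Sequence[GeneSpan], pad: int = 0) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for g in spans:
        tree = trees.setdefault(g.chrom, IntervalTree())
        tree.addi(max(0, g.start - pad), g.end + pad, g)
    return trees


def flank_filter(
    candidates: Sequence[TranscriptModel],
    annotation: Sequence[TranscriptModel],
    flank_nt: int = 1000,
    antisense_exemption: bool = True,
) -> List[TranscriptModel]:
    """Remove candidates overlapping annotated gene spans extended by
    ``flank_nt`` on both sides (half-open arithmetic).

    With ``antisense_exemption`` a candidate whose extended-span overlaps
    are *all* on the opposite strand is retained.  Input order is
    preserved.
    """
    if flank_nt < 0:
        raise ValueError("flank_nt must be >= 0")
    trees = _span_trees(gene_spans(annotation), pad=flank_nt)
    kept = []
    for tx in candidates:
        s, e = tx.span
        hits = trees.get(tx.chrom, IntervalTree()).overlap(s, e)
        if not hits:
            kept.append(tx)
            continue
        if antisense_exemption and all(
            iv.data.strand != tx.strand for iv in hits
        ):
            kept.append(tx)
    return kept


def _gap_nt(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Distance in nt between two half-open intervals; 0 when overlapping,
    1 when immediately adjacent."""
    if a_start < b_end and b_start < a_end:
        return 0
    if a_end <= b_start:
        return b_start - a_end + 1
    return a_start - b_end + 1


def classify_position(
    candidate: TranscriptModel,
    annotation: Sequence[TranscriptModel],
    flank_nt: int = 1000,
) -> PositionClass:
    """Classify one candidate against annotated gene spans.

    ``sense_overlap``: a candidate exon overlaps a same-strand gene span;
    ``antisense_overlap``: the candidate span overlaps an opposite-strand
    gene span (and no sense overlap); ``flank_proximal``: no overlap but
    the nearest gene is within ``flank_nt``; otherwise ``intergenic``.
    The nearest gene and distance are always reported (inf sentinel when
    the annotation is empty).
    """
    spans = [g for g in gene_spans(annotation) if g.chrom == candidate.chrom]
    s, e = candidate.span
    if not spans:
        return PositionClass(candidate.transcript_id, "intergenic", None, math.inf)

    nearest = min(
        spans, key=lambda g: (_gap_nt(s, e, g.start, g.end), g.gene_id)
    )
    nearest_d = _gap_nt(s, e, nearest.start, nearest.end)

    sense = any(
        g.strand == candidate.strand
        and any(a < g.end and g.start < b for a, b in candidate.exons)
        for g in spans
    )
    if sense:
        klass = "sense_overlap"
    elif any(
        g.strand != candidate.strand and s < g.end and g.start < e for g in spans
    ):
        klass = "antisense_overlap"
    elif 0 < nearest_d <= flank_nt:
        klass = "flank_proximal"
    else:
        klass = "intergenic"
    return PositionClass(
        candidate.transcript_id, klass, nearest.gene_id, float(nearest_d)
    )
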