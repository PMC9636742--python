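"""End-to-end orchestration: methylation -> epimutation calls -> top-k
-> anchoring -> coding cascade -> RPKM -> report.

Every stage writes a plain-text intermediate artifact into the output
directory so partial runs can be inspected and diffed; the final report
has one row per anchored candidate with every criterion verdict, its
positional class, expression, and the anchoring call.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import pyfaidx

from . import anchoring, coding_potential, epimutation, methylation_io, transcriptome
from .coding_potential import CascadeConfig
from .errors import ConfigurationError, ParseError
from .synthetic_data import _rng, make_training_sets

log = logging.getLogger("epilinc")

# The default thresholds of the discovery cascade, kept in one table so
# they can be asserted against and echoed; any override is logged.
DEFAULT_THRESHOLDS = {
    "cascade.length_min": 200,
    "cascade.orf_max": 400,
    "cascade.pfam_evalue_min": 1e-5,
    "cascade.noncoding_score_min": 0.5,
    "cascade.cpat_threshold": 0.375,
    "anchoring.flank_nt": 1000,
    "top_k": 2,
}


@dataclass
class PipelineConfig:
    seed: int = 0
    top_k: int = 2
    anchor_window_nt: int = 0
    min_cov: int = 5
    min_fraction_samples: float = 0.5
    min_abs_delta: float = 0.3
    alpha: float = 0.05
    flank_nt: int = 1000
    antisense_exemption: bool = True
    merge_strands: bool = False
    cascade: CascadeConfig = field(default_factory=CascadeConfig)

    def validate(self) -> None:
        if self.top_k < 1:
            raise ConfigurationError("top_k must be >= 1")
        if self.anchor_window_nt < 0:
            raise ConfigurationError("anchor_window_nt must be >= 0")
        if self.min_cov < 1:
            raise ConfigurationError("min_cov must be >= 1")
        if not 0 < self.min_fraction_samples <= 1:
            raise ConfigurationError("min_fraction_samples must be in (0, 1]")
        if not 0 <= self.min_abs_delta <= 1:
            raise ConfigurationError("min_abs_delta must be in [0, 1]")
        if not 0 < self.alpha <= 1:
            raise ConfigurationError("alpha must be in (0, 1]")
        if self.flank_nt < 0:
            raise ConfigurationError("flank_nt must be >= 0")

    def echo_overrides(self) -> None:
        current = {
            "cascade.length_min": self.cascade.length_min,
            "cascade.orf_max": self.cascade.orf_max,
            "cascade.pfam_evalue_min": self.cascade.pfam_evalue_min,
            "cascade.noncoding_score_min": self.cascade.noncoding_score_min,
            "cascade.cpat_threshold": self.cascade.cpat_threshold,
            "anchoring.flank_nt": self.flank_nt,
            "top_k": self.top_k,
        }
        for key, default in DEFAULT_THRESHOLDS.items():
            if current[key] != default:
                log.warning("threshold override: %s = %s (default %s)",
                            key, current[key], default)
        if self.cascade.cpat_direction == "literal":
            log.warning(
                "coding-probability criterion read literally (keep > %s); "
                "the default keeps transcripts below the cutoff, consistent "
                "with screening FOR noncoding transcripts",
                self.cascade.cpat_threshold,
            )


@dataclass
class PipelineInputs:
    samples_tsv: Path
    assembled_gtf: Path
    annotation_gtf: Path
    genome_fasta: Path
    counts_tsv: Optional[Path] = None
    pfam_tsv: Optional[Path] = None
    noncoding_scores_tsv: Optional[Path] = None


@dataclass
class PipelineResult:
    calls: list
    top_calls: list
    anchors: list
    report: pd.DataFrame
    final_candidates: List[str]
    outdir: Path


def read_samples_table(path) -> Dict[str, tuple]:
    """sample_id -> (coverage path resolved next to the table, group)."""
    base = Path(path).parent
    out: Dict[str, tuple] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["sample_id", "group", "path"]:
            raise ParseError(
                "samples table must have columns sample_id, group, path", path, 1
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError("expected 3 columns", path, lineno)
            sid, group, p = fields
            if sid in out:
                raise ParseError(f"duplicate sample {sid}", path, lineno)
            out[sid] = (base / p if not Path(p).is_absolute() else Path(p), group)
    return out


def load_matrix(samples_tsv, merge_strands: bool = False):
    samples = read_samples_table(samples_tsv)
    tables = {
        sid: methylation_io.read_methylation_calls(path)
        for sid, (path, _group) in samples.items()
    }
    groups = {sid: group for sid, (_path, group) in samples.items()}
    return methylation_io.build_matrix(tables, groups, merge_strands=merge_strands)


def train_builtin_model(seed: int):
    """Train the built-in hexamer table and logistic coding model on a
    seeded synthetic corpus (disjoint stream from any fixture)."""
    rng = _rng(seed, 101)
    coding, noncoding = make_training_sets(rng, n_coding=120, n_noncoding=120,
                                           length_range=(400, 1200))
    coding_orfs = []
    for seq in coding:
        orf = coding_potential.longest_orf(seq)
        coding_orfs.append(seq[orf.start : orf.end])
    table = coding_potential.train_hexamer_table(coding_orfs, noncoding)
    assessments = [
        coding_potential.compute_assessment(f"train_{i}", seq, table)
        for i, seq in enumerate(coding + noncoding)
    ]
    labels = [1] * len(coding) + [0] * len(noncoding)
    model = coding_potential.train_coding_model(assessments, labels)
    return table, model


def _stage(name):
    log.info("stage %s ...", name)
    return time.perf_counter()


def _done(name, t0):
    log.info("stage %s done in %.2f s", name, time.perf_counter() - t0)


def run_pipeline(
    config: PipelineConfig, inputs: PipelineInputs, outdir
) -> PipelineResult:
    """Execute the full discovery pipeline and write its artifacts."""
    config.validate()
    config.echo_overrides()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    t0 = _stage("methylation")
    matrix = load_matrix(inputs.samples_tsv, merge_strands=config.merge_strands)
    matrix = methylation_io.filter_by_coverage(
        matrix, config.min_cov, config.min_fraction_samples
    )
    _done("methylation", t0)

    t0 = _stage("epimutation")
    calls = epimutation.call_epimutations(
        matrix,
        min_cov=config.min_cov,
        min_abs_delta=config.min_abs_delta,
        alpha=config.alpha,
    )
    epimutation.write_calls_bed(calls, outdir / "calls.bed")
    top = epimutation.top_candidates(calls, config.top_k) if calls else []
    epimutation.write_calls_bed(top, outdir / "top_calls.bed")
    _done("epimutation", t0)

    t0 = _stage("anchoring")
    assembled = transcriptome.read_gtf(inputs.assembled_gtf, source_tag="assembled")
    annotation = transcriptome.read_gtf(inputs.annotation_gtf, source_tag="annotated")
    anchors = anchoring.anchor_transcripts(assembled, top, config.anchor_window_nt)
    with open(outdir / "anchors.tsv", "w") as fh:
        fh.write("transcript_id\tanchor_chrom\tanchor_pos\tanchor_rank\t"
                 "relation\tdistance_nt\n")
        for a in anchors:
            fh.write(
                f"{a.transcript.transcript_id}\t{a.anchor.site.chrom}\t"
                f"{a.anchor.site.pos}\t{a.anchor.rank}\t{a.anchor_relation}\t"
                f"{a.distance_nt}\n"
            )
    # one candidate per transcript; first (best-ranked) anchor wins
    candidates: List = []
    anchor_of: Dict[str, anchoring.AnchorResult] = {}
    for a in anchors:
        tid = a.transcript.transcript_id
        if tid not in anchor_of:
            anchor_of[tid] = a
            candidates.append(a.transcript)
    flank_kept = {
        tx.transcript_id
        for tx in anchoring.flank_filter(
            candidates, annotation, config.flank_nt, config.antisense_exemption
        )
    }
    position = {
        tx.transcript_id: anchoring.classify_position(tx, annotation, config.flank_nt)
        for tx in candidates
    }
    _done("anchoring", t0)

    t0 = _stage("coding_potential")
    hexamer_table, model = train_builtin_model(config.seed)
    hexamer_table.save(outdir / "hexamer_table.tsv")
    model.save(outdir / "coding_model.json")
    genome = pyfaidx.Fasta(str(inputs.genome_fasta))
    pfam = (
        coding_potential.read_score_table(inputs.pfam_tsv, "best_evalue")
        if inputs.pfam_tsv
        else None
    )
    ncs = (
        coding_potential.read_score_table(inputs.noncoding_scores_tsv, "score")
        if inputs.noncoding_scores_tsv
        else None
    )
    assessments = {}
    decisions = {}
    for tx in candidates:
        seq = transcriptome.spliced_sequence(tx, genome)
        assessment = coding_potential.compute_assessment(
            tx.transcript_id,
            seq,
            hexamer_table,
            model=model,
            pfam_best_evalue=(
                pfam.get(tx.transcript_id, float("inf")) if pfam is not None else None
            ),
            external_noncoding_score=(
                ncs.get(tx.transcript_id) if ncs is not None else None
            ),
        )
        assessments[tx.transcript_id] = assessment
        decisions[tx.transcript_id] = coding_potential.apply_filter_cascade(
            tx.length,
            assessment,
            config.cascade,
            flank_pass=tx.transcript_id in flank_kept,
        )
    _done("coding_potential", t0)

    t0 = _stage("expression")
    expression = {}
    if inputs.counts_tsv is not None:
        counts = transcriptome.read_counts_table(inputs.counts_tsv)
        for rec in transcriptome.compute_expression(assembled, counts):
            expression[rec.transcript_id] = rec
    _done("expression", t0)

    t0 = _stage("report")
    rows = []
    for tx in sorted(candidates, key=lambda t: t.transcript_id):
        tid = tx.transcript_id
        a = anchor_of[tid]
        assessment = assessments[tid]
        decision = decisions[tid]
        pos = position[tid]
        rec = expression.get(tid)
        orf = assessment.longest_orf
        rows.append(
            {
                "transcript_id": tid,
                "gene_id": tx.gene_id,
                "chrom": tx.chrom,
                "start": tx.span[0],
                "end": tx.span[1],
                "strand": tx.strand,
                "n_exons": tx.n_exons,
                "length_nt": tx.length,
                "anchor_pos": a.anchor.site.pos,
                "anchor_rank": a.anchor.rank,
                "anchor_delta": a.anchor.delta,
                "anchor_q": a.anchor.q_value,
                "anchor_relation": a.anchor_relation,
                "anchor_distance_nt": a.distance_nt,
                "position_class": pos.klass,
                "nearest_gene": pos.nearest_gene_id or "",
                "nearest_distance_nt": pos.nearest_distance_nt,
                "longest_orf_nt": orf.nt_length if orf else 0,
                "orf_coverage": assessment.orf_coverage,
                "fickett": assessment.fickett,
                "hexamer": assessment.hexamer,
                "coding_probability": assessment.coding_probability,
                **{f"verdict_{k}": v for k, v in decision.verdicts.items()},
                "overall": "pass" if decision.overall else "fail",
                "first_failed": decision.first_failed or "",
                "read_count": rec.read_count if rec else "",
                "rpkm": f"{rec.rpkm:.6g}" if rec else "",
            }
        )
    report = pd.DataFrame(rows)
    report.to_csv(outdir / "report.tsv", sep="\t", index=False,
                  float_format="%.6g")
    final = [r["transcript_id"] for r in rows if r["overall"] == "pass"]
    with open(outdir / "candidates.txt", "w") as fh:
        for tid in final:
            fh.write(tid + "\n")
    _done("report", t0)
    log.info("%d call(s), %d anchored candidate(s), %d final lncRNA candidate(s)",
             len(calls), len(candidates), len(final))
    return PipelineResult(
        calls=calls,
        top_calls=top,
        anchors=anchors,
        report=report,
        final_candidates=final,
        outdir=outdir,
    )
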