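"""Seeded synthetic fixtures for every pipeline stage.

The default configuration emulates the study design the pipeline is
built for: two groups of six bisulfite-sequenced individuals, beta-
binomial methylation counts at ~1000 CpG sites with two planted
differential epimutations (case methylation ~Beta(9,1), control
~Beta(1,9), i.e. a planted |delta| of 0.8), a random genome carrying a
small protein-coding annotation, and assembled transcripts planted on
top of the first epimutation: one antisense lncRNA (the object the
pipeline should recover), mRNA-like decoys with long biased-codon ORFs,
and distant decoys that are never anchored.  The second planted site
has no transcript over it.

One global seed fans out to fixed per-component streams so that partial
config changes do not reshuffle unrelated components.  Identical
configurations produce byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coding_potential import STOP_CODONS, find_orfs
from .errors import ConfigurationError
from .methylation_io import (
    CpGSite,
    MethylationMatrix,
    SampleCounts,
    write_methylation_calls,
)
from .transcriptome import TranscriptModel, write_gtf

# fixed per-component sub-seeds derived from the global seed
_RNG_GENOME, _RNG_TRANSCRIPTS, _RNG_METHYLATION, _RNG_FASTQ, _RNG_COUNTS = range(5)

BASES = np.array(list("ACGT"))

# one human-preferred (mostly GC-ending) codon per amino acid; no stops
PREFERRED_CODONS = (
    "GCC", "CGG", "AAC", "GAC", "TGC", "CAG", "GAG", "GGC", "CAC", "ATC",
    "CTG", "AAG", "ATG", "TTC", "CCC", "AGC", "ACC", "TGG", "TAC", "GTG",
)
ALL_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


def _rng(seed: int, component: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), component]))


def random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def make_coding_sequence(
    rng: np.random.Generator,
    length: int,
    orf_fraction: float = 0.7,
    codon_bias_strength: float = 0.8,
) -> str:
    """An mRNA-like sequence: one long ORF of biased codons inside UTRs.

    The ORF occupies roughly ``orf_fraction`` of the length; each
    internal codon is drawn from the preferred-codon set with
    probability ``codon_bias_strength``, otherwise uniformly from all
    sense codons.
    """
    orf_nt = 3 * int(orf_fraction * length // 3)
    if orf_nt < 9:
        raise ConfigurationError(
            f"length {length} too short for an ORF of fraction {orf_fraction}"
        )
    if orf_nt > length:
        raise ConfigurationError("ORF longer than transcript")
    n_internal = orf_nt // 3 - 2
    codons = []
    for _ in range(n_internal):
        if rng.random() < codon_bias_strength:
            codons.append(PREFERRED_CODONS[rng.integers(len(PREFERRED_CODONS))])
        else:
            codons.append(ALL_SENSE_CODONS[rng.integers(len(ALL_SENSE_CODONS))])
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    utr5 = (length - orf_nt) // 2
    utr3 = length - orf_nt - utr5
    return (
        random_bases(rng, utr5) + "ATG" + "".join(codons) + stop
        + random_bases(rng, utr3)
    )


def make_noncoding_sequence(
    rng: np.random.Generator, length: int, max_orf_nt: int = 300
) -> str:
    """A lncRNA-like sequence: uniform random bases with stop codons
    inserted until no ORF (including open-ended ones) reaches
    ``max_orf_nt``."""
    seq = list(random_bases(rng, length))
    for _ in range(100):
        long_orfs = [o for o in find_orfs("".join(seq)) if o.nt_length >= max_orf_nt]
        if not long_orfs:
            return "".join(seq)
        for orf in long_orfs:
            n_codons = orf.nt_length // 3
            j = int(rng.integers(1, max(2, n_codons - 1)))
            at = orf.start + 3 * j
            seq[at : at + 3] = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    raise ConfigurationError("could not cap ORFs below the requested length")


def make_training_sets(
    rng: np.random.Generator,
    n_coding: int = 150,
    n_noncoding: int = 150,
    length_range: Tuple[int, int] = (400, 1500),
    codon_bias_strength: float = 0.8,
) -> Tuple[List[str], List[str]]:
    """Labelled sequence sets for training the coding-potential model."""
    lo, hi = length_range
    coding = [
        make_coding_sequence(
            rng, int(rng.integers(lo, hi + 1)),
            codon_bias_strength=codon_bias_strength,
        )
        for _ in range(n_coding)
    ]
    noncoding = [
        make_noncoding_sequence(rng, int(rng.integers(lo, hi + 1)))
        for _ in range(n_noncoding)
    ]
    return coding, noncoding


# ---------------------------------------------------------------------------
# Methylation count simulation


def betabinomial_counts(
    rng: np.random.Generator,
    n_sites: int,
    n_samples: int,
    coverage_mean: float,
    beta: Tuple[float, float],
) -> Tuple[np.ndarray, np.ndarray]:
    """(meth, coverage) arrays of shape (n_sites, n_samples): coverage is
    Poisson(coverage_mean), per-cell methylation fraction Beta(a, b)."""
    a, b = beta
    cov = rng.poisson(coverage_mean, size=(n_sites, n_samples))
    p = rng.beta(a, b, size=(n_sites, n_samples))
    meth = rng.binomial(cov, p)
    return meth, cov


def null_pooled_counts(
    rng: np.random.Generator,
    n_sites: int,
    n_case: int,
    n_control: int,
    coverage_mean: float,
    beta: Tuple[float, float] = (5.0, 5.0),
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Group-pooled (meth, cov) counts under the exchangeable global null.

    Each site draws one methylation level p ~ Beta(a, b) shared by every
    sample of both groups, so the two groups genuinely share a binomial
    rate and the pooled exact test's null holds.  (Contrast
    :func:`betabinomial_counts`, which draws p per individual and models
    biological overdispersion — under that process the pooled test's
    null is intentionally violated.)  Returns pooled
    (meth_case, cov_case, meth_control, cov_control) arrays of length
    ``n_sites``.
    """
    a, b = beta
    p = rng.beta(a, b, size=n_sites)
    cov_case = rng.poisson(coverage_mean, size=(n_sites, n_case))
    cov_ctrl = rng.poisson(coverage_mean, size=(n_sites, n_control))
    meth_case = rng.binomial(cov_case, p[:, None])
    meth_ctrl = rng.binomial(cov_ctrl, p[:, None])
    return (
        meth_case.sum(axis=1),
        cov_case.sum(axis=1),
        meth_ctrl.sum(axis=1),
        cov_ctrl.sum(axis=1),
    )


def simulate_matrix(
    rng: np.random.Generator,
    n_sites: int,
    n_case: int,
    n_control: int,
    coverage_mean: float,
    null_beta: Tuple[float, float] = (5.0, 5.0),
    planted: Optional[Dict[int, Tuple[Tuple[float, float], Tuple[float, float]]]] = None,
    chrom: str = "chrS",
) -> MethylationMatrix:
    """An in-memory matrix of null sites with optional planted
    differential sites (``planted[site_index] = (case_beta, control_beta)``)."""
    meth_case, cov_case = betabinomial_counts(
        rng, n_sites, n_case, coverage_mean, null_beta
    )
    meth_ctrl, cov_ctrl = betabinomial_counts(
        rng, n_sites, n_control, coverage_mean, null_beta
    )
    for i, (case_beta, control_beta) in (planted or {}).items():
        pc = rng.beta(*case_beta, size=n_case)
        meth_case[i] = rng.binomial(cov_case[i], pc)
        pk = rng.beta(*control_beta, size=n_control)
        meth_ctrl[i] = rng.binomial(cov_ctrl[i], pk)
    samples = [f"case_{j + 1}" for j in range(n_case)] + [
        f"control_{j + 1}" for j in range(n_control)
    ]
    group = {s: ("case" if s.startswith("case") else "control") for s in samples}
    meth = np.hstack([meth_case, meth_ctrl])
    cov = np.hstack([cov_case, cov_ctrl])
    sites = [CpGSite(chrom, 100 + 3 * i) for i in range(n_sites)]
    return MethylationMatrix(
        sites=sites, samples=samples, group=group, meth=meth, unmeth=cov - meth
    )


# ---------------------------------------------------------------------------
# Full file-bundle fixture


@dataclass(frozen=True)
class PlantedSite:
    """A differential CpG between groups; pos None = assigned by layout."""

    pos: Optional[int] = None
    case_beta: Tuple[float, float] = (9.0, 1.0)
    control_beta: Tuple[float, float] = (1.0, 9.0)


@dataclass(frozen=True)
class PlantedTranscript:
    name: str
    kind: str  # mrna | lncrna | antisense_lncrna
    length: int
    n_exons: int
    strand: str
    anchored: bool


def _default_planted_transcripts() -> Tuple[PlantedTranscript, ...]:
    return (
        PlantedTranscript("planted_lnc_1", "antisense_lncrna", 600, 4, "-", True),
        PlantedTranscript("decoy_mrna_anch_1", "mrna", 900, 3, "-", True),
        PlantedTranscript("decoy_mrna_anch_2", "mrna", 900, 2, "+", True),
        PlantedTranscript("decoy_lnc_far_1", "lncrna", 500, 2, "+", False),
        PlantedTranscript("decoy_mrna_far_1", "mrna", 800, 2, "+", False),
    )


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom: str = "chrS"
    genome_size_nt: int = 60_000
    n_genes: int = 6
    gene_length: int = 2000
    n_case: int = 6
    n_control: int = 6
    coverage_mean: float = 30.0
    n_null_sites: int = 998
    null_beta: Tuple[float, float] = (5.0, 5.0)
    planted_sites: Tuple[PlantedSite, ...] = (PlantedSite(), PlantedSite())
    planted_transcripts: Tuple[PlantedTranscript, ...] = field(
        default_factory=_default_planted_transcripts
    )
    codon_bias_strength: float = 0.8
    n_reads_fastq: int = 300
    read_length: int = 100
    library_size: int = 20_000_000
    lnc_read_count: int = 250

    def validate(self) -> None:
        if self.genome_size_nt < 4000 + self.n_genes * 8000:
            raise ConfigurationError(
                "genome too small for the requested number of genes"
            )
        if self.n_case < 1 or self.n_control < 1:
            raise ConfigurationError("need at least one sample per group")
        if self.coverage_mean <= 0:
            raise ConfigurationError("coverage_mean must be positive")
        if self.n_genes < 2:
            raise ConfigurationError("need at least two annotated genes")
        for t in self.planted_transcripts:
            if t.anchored and t.n_exons < 2:
                raise ConfigurationError(
                    f"anchored transcript {t.name} needs >= 2 exons to span "
                    "the anchor site"
                )
            if t.length < 3 * t.n_exons:
                raise ConfigurationError(f"{t.name}: exons would be empty")
            if t.kind not in ("mrna", "lncrna", "antisense_lncrna"):
                raise ConfigurationError(f"unknown transcript kind {t.kind!r}")
        for s in self.planted_sites:
            if s.pos is not None and not 0 <= s.pos < self.genome_size_nt - 1:
                raise ConfigurationError("planted site outside the genome")


@dataclass
class FixtureBundle:
    outdir: Path
    genome_fasta: Path
    annotation_gtf: Path
    assembled_gtf: Path
    samples_tsv: Path
    coverage_files: Dict[str, Path]
    counts_tsv: Path
    fastq: Path
    truth_tsv: Path
    truth: pd.DataFrame
    planted_site_positions: List[int]
    config: SimulationConfig


def _split_exons(length: int, n: int) -> List[int]:
    base, rem = divmod(length, n)
    return [base + 1] * rem + [base] * (n - rem)


def _layout_anchored(
    planted: Sequence[PlantedTranscript], locus_start: int, gap: int = 30
) -> Tuple[Dict[str, List[Tuple[int, int]]], int]:
    """Round-robin exon placement so every transcript spans one shared
    anchor slot reserved after the first round."""
    queues = {t.name: list(reversed(_split_exons(t.length, t.n_exons))) for t in planted}
    placed: Dict[str, List[Tuple[int, int]]] = {t.name: [] for t in planted}
    cur = locus_start
    anchor_pos = None
    round_index = 0
    while any(queues.values()):
        for t in planted:
            q = queues[t.name]
            if q:
                size = q.pop()
                placed[t.name].append((cur, cur + size))
                cur += size + gap
        round_index += 1
        if round_index == 1:
            anchor_pos = cur
            cur += 2 + gap
    return placed, anchor_pos


def _layout_unanchored(
    planted: Sequence[PlantedTranscript], start: int, intron: int = 50, gap: int = 300
) -> Tuple[Dict[str, List[Tuple[int, int]]], int]:
    placed: Dict[str, List[Tuple[int, int]]] = {}
    cur = start
    for t in planted:
        exons = []
        for size in _split_exons(t.length, t.n_exons):
            exons.append((cur, cur + size))
            cur += size + intron
        placed[t.name] = exons
        cur += gap - intron
    return placed, cur


def _transcript_sequence(
    rng: np.random.Generator, t: PlantedTranscript, codon_bias_strength: float
) -> str:
    if t.kind == "mrna":
        return make_coding_sequence(
            rng, t.length, orf_fraction=0.7, codon_bias_strength=codon_bias_strength
        )
    return make_noncoding_sequence(rng, t.length, max_orf_nt=300)


def _paste(genome: list, model_exons, strand: str, spliced: str) -> None:
    genomic = spliced if strand == "+" else str(Seq(spliced).reverse_complement())
    offset = 0
    for a, b in model_exons:
        genome[a:b] = list(genomic[offset : offset + (b - a)])
        offset += b - a


def generate_fixture(config: SimulationConfig, outdir) -> FixtureBundle:
    """Write the full synthetic file bundle and its truth table."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = config.genome_size_nt

    rng_genome = _rng(config.seed, _RNG_GENOME)
    rng_tx = _rng(config.seed, _RNG_TRANSCRIPTS)
    rng_meth = _rng(config.seed, _RNG_METHYLATION)
    rng_fastq = _rng(config.seed, _RNG_FASTQ)
    rng_counts = _rng(config.seed, _RNG_COUNTS)

    genome = list(random_bases(rng_genome, g))

    # --- annotation: evenly spaced plus-strand genes of three exons
    gene_models = []
    gene_spans_list = []
    for i in range(config.n_genes):
        s = 4000 + i * 8000
        e = s + config.gene_length
        third = config.gene_length // 4
        exons = ((s, s + third), (s + third + 250, s + 2 * third + 250), (e - third, e))
        gene_models.append(
            TranscriptModel(
                transcript_id=f"G{i + 1}.1",
                gene_id=f"G{i + 1}",
                chrom=config.chrom,
                strand="+",
                exons=exons,
                source_tag="annotated",
            )
        )
        gene_spans_list.append((s, e))

    # --- planted transcripts: anchored ones interleaved inside gene 2's
    # span around the shared anchor slot, distant ones after the last gene
    anchored = [t for t in config.planted_transcripts if t.anchored]
    unanchored = [t for t in config.planted_transcripts if not t.anchored]
    anchor_gene_start = 4000 + 1 * 8000
    placed, anchor_pos = ({}, None)
    if anchored:
        placed, anchor_pos = _layout_anchored(anchored, anchor_gene_start + 50)
    far_start = gene_spans_list[-1][1] + 1500
    far_placed, far_end = _layout_unanchored(unanchored, far_start)
    placed.update(far_placed)
    if far_end + 200 > g:
        raise ConfigurationError("genome too small for the planted transcripts")

    tx_models = []
    for t in config.planted_transcripts:
        tx_models.append(
            TranscriptModel(
                transcript_id=t.name,
                gene_id=t.name,
                chrom=config.chrom,
                strand=t.strand,
                exons=tuple(placed[t.name]),
                source_tag="assembled",
            )
        )
        spliced = _transcript_sequence(rng_tx, t, config.codon_bias_strength)
        _paste(genome, placed[t.name], t.strand, spliced)

    # --- methylation site positions
    site_positions: List[int] = []
    site_params: List[PlantedSite] = []
    auto_candidates = []
    for i in range(config.n_genes - 1):
        mid = (gene_spans_list[i][1] + gene_spans_list[i + 1][0]) // 2
        auto_candidates.append(mid)
    exon_intervals = [iv for name in placed for iv in placed[name]]

    def _clear(pos: int) -> bool:
        if not 200 <= pos < g - 200:
            return False
        for a, b in exon_intervals:
            if a - 2 <= pos < b + 2:
                return False
        return all(abs(pos - q) > 50 for q in site_positions)

    for k, site in enumerate(config.planted_sites):
        if site.pos is not None:
            pos = site.pos
        elif k == 0 and anchor_pos is not None:
            pos = anchor_pos
        else:
            pos = next((c for c in auto_candidates if _clear(c)), None)
            if pos is None:
                raise ConfigurationError("no intergenic slot left for a planted site")
            auto_candidates.remove(pos)
        site_positions.append(pos)
        site_params.append(replace(site, pos=pos))

    forbidden = np.zeros(g, dtype=bool)
    forbidden[:200] = True
    forbidden[g - 200:] = True
    for a, b in exon_intervals:
        forbidden[max(0, a - 2) : min(g, b + 2)] = True
    for pos in site_positions:
        forbidden[max(0, pos - 50) : min(g, pos + 51)] = True
    allowed = np.flatnonzero(~forbidden)
    draw = min(allowed.size, 4 * config.n_null_sites)
    chosen = np.sort(rng_meth.choice(allowed, size=draw, replace=False))
    null_positions: List[int] = []
    last = -10
    for pos in chosen:
        if pos - last >= 3:
            null_positions.append(int(pos))
            last = int(pos)
        if len(null_positions) == config.n_null_sites:
            break
    if len(null_positions) < config.n_null_sites:
        raise ConfigurationError("genome too small for the requested null sites")

    for pos in site_positions + null_positions:
        genome[pos] = "C"
        genome[pos + 1] = "G"

    # --- write genome (after all edits)
    genome_str = "".join(genome)
    genome_fasta = outdir / "genome.fa"
    SeqIO.write(
        [SeqRecord(Seq(genome_str), id=config.chrom, description="")],
        str(genome_fasta),
        "fasta",
    )
    annotation_gtf = outdir / "annotation.gtf"
    write_gtf(gene_models, annotation_gtf, source="simulated_annotation")
    assembled_gtf = outdir / "assembled.gtf"
    write_gtf(tx_models, assembled_gtf, source="simulated_assembly")

    # --- methylation counts per sample
    all_sites = sorted(
        [(p, s.case_beta, s.control_beta) for p, s in zip(site_positions, site_params)]
        + [(p, config.null_beta, config.null_beta) for p in null_positions]
    )
    samples = [f"case_{j + 1}" for j in range(config.n_case)] + [
        f"control_{j + 1}" for j in range(config.n_control)
    ]
    group = {s: ("case" if s.startswith("case") else "control") for s in samples}
    coverage_files: Dict[str, Path] = {}
    for s in samples:
        is_case = group[s] == "case"
        table = {}
        for pos, case_beta, control_beta in all_sites:
            a, b = case_beta if is_case else control_beta
            cov = int(rng_meth.poisson(config.coverage_mean))
            meth = int(rng_meth.binomial(cov, rng_meth.beta(a, b))) if cov else 0
            table[CpGSite(config.chrom, pos)] = SampleCounts(meth, cov - meth)
        path = outdir / f"{s}.cov"
        write_methylation_calls(table, path, dialect="bismark_cov")
        coverage_files[s] = path
    samples_tsv = outdir / "samples.tsv"
    with open(samples_tsv, "w") as fh:
        fh.write("sample_id\tgroup\tpath\n")
        for s in samples:
            fh.write(f"{s}\t{group[s]}\t{coverage_files[s].name}\n")

    # --- expression counts
    counts_tsv = outdir / "counts.tsv"
    with open(counts_tsv, "w") as fh:
        fh.write("transcript_id\tread_count\tlibrary_size\n")
        for t in config.planted_transcripts:
            if t.kind == "antisense_lncrna":
                count = config.lnc_read_count
            else:
                count = int(rng_counts.integers(50, 501))
            fh.write(f"{t.name}\t{count}\t{config.library_size}\n")

    # --- FASTQ reads exercising the QC rule
    fastq = outdir / "reads.fastq"
    n_bad_n = config.n_reads_fastq * 15 // 100
    n_bad_q = config.n_reads_fastq * 15 // 100
    records = []
    for r in range(config.n_reads_fastq):
        length = config.read_length
        seq = list(random_bases(rng_fastq, length))
        quals = list(rng_fastq.integers(25, 41, size=length))
        if r < n_bad_n:
            n_n = math.ceil(0.12 * length)
            where = rng_fastq.choice(length, size=n_n, replace=False)
            for w in where:
                seq[w] = "N"
        elif r < n_bad_n + n_bad_q:
            n_low = math.ceil(0.40 * length)
            where = rng_fastq.choice(length, size=n_low, replace=False)
            low = rng_fastq.integers(2, 16, size=n_low)
            for w, q in zip(where, low):
                quals[w] = int(q)
        rec = SeqRecord(Seq("".join(seq)), id=f"read_{r + 1}", description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in quals]
        records.append(rec)
    with open(fastq, "w") as fh:
        SeqIO.write(records, fh, "fastq")

    # --- truth table
    rows = []
    for k, (pos, s) in enumerate(zip(site_positions, site_params)):
        rows.append(
            {
                "record_type": "epimutation_site",
                "name": f"site_{k + 1}",
                "chrom": config.chrom,
                "start": pos,
                "end": pos + 2,
                "strand": ".",
                "detail": (
                    f"case_beta={s.case_beta[0]:g},{s.case_beta[1]:g};"
                    f"control_beta={s.control_beta[0]:g},{s.control_beta[1]:g}"
                ),
            }
        )
    for t, model in zip(config.planted_transcripts, tx_models):
        s, e = model.span
        rows.append(
            {
                "record_type": "transcript",
                "name": t.name,
                "chrom": config.chrom,
                "start": s,
                "end": e,
                "strand": t.strand,
                "detail": f"kind={t.kind};anchored={int(t.anchored)}",
            }
        )
    truth = pd.DataFrame(rows)
    truth_tsv = outdir / "truth.tsv"
    truth.to_csv(truth_tsv, sep="\t", index=False)

    return FixtureBundle(
        outdir=outdir,
        genome_fasta=genome_fasta,
        annotation_gtf=annotation_gtf,
        assembled_gtf=assembled_gtf,
        samples_tsv=samples_tsv,
        coverage_files=coverage_files,
        counts_tsv=counts_tsv,
        fastq=fastq,
        truth_tsv=truth_tsv,
        truth=truth,
        planted_site_positions=site_positions,
        config=config,
    )


# ---------------------------------------------------------------------------
# Printed-structure fixture


@dataclass
class PaperFixture:
    """Three antisense multi-exon transcripts (888/603/382 nt mature
    length with 7/5/3 exons, minus strand) over one plus-strand
    annotated gene, on a synthetic toy chromosome.  Mirrors the exon
    structure reported for a RACE-resolved antisense lncRNA locus;
    internal exon boundaries are arbitrary but deterministic and the
    genome sequence is synthetic background."""

    genome: Dict[str, str]
    transcripts: List[TranscriptModel]
    annotation: List[TranscriptModel]


def paper_fixture() -> PaperFixture:
    rng = np.random.default_rng(2892)
    chrom = "chr21_toy"
    genome = {chrom: random_bases(rng, 8000)}
    specs = [("LINC_T1", 888, 7), ("LINC_T2", 603, 5), ("LINC_T3", 382, 3)]
    transcripts = []
    for i, (tid, length, n_exons) in enumerate(specs):
        cur = 1000 + i * 150
        exons = []
        for size in _split_exons(length, n_exons):
            exons.append((cur, cur + size))
            cur += size + 80
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id="LINC_TOY",
                chrom=chrom,
                strand="-",
                exons=tuple(exons),
                source_tag="assembled",
            )
        )
    annotation = [
        TranscriptModel(
            transcript_id="TOYGENE1.1",
            gene_id="TOYGENE1",
            chrom=chrom,
            strand="+",
            exons=((900, 1200), (2600, 2900)),
            source_tag="annotated",
        )
    ]
    return PaperFixture(genome=genome, transcripts=transcripts, annotation=annotation)
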