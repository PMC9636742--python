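"""Coding-potential assessment and the six-criterion noncoding filter
cascade.

The cascade screens assembled transcripts for lncRNA character:

1. mature length > 200 nt;
2. longest ORF < 400 nt;
3. no PFAM protein-family match (best E-value > 1e-5), ingested as an
   external score table;
4. external noncoding score (e.g. an iSeeRNA-style SVM) > 0.5, ingested
   as an external score table;
5. coding probability from the built-in model below the 0.375 cutoff
   (the classic CPAT human cutoff; the comparison direction is
   configurable, see ``CascadeConfig``);
6. removal within 1 kb of annotated genes — that verdict is computed by
   the anchoring module and supplied to the cascade.

The built-in coding-probability model is CPAT-style: a logistic
regression on [longest ORF length, ORF coverage, Fickett TESTCODE
score, hexamer usage bias], trained on labelled sequences.  Fickett's
position/content lookup tables and weights follow the published
TESTCODE parameterization; hexamer bias is the mean in-frame
log-likelihood ratio of 6-mer frequencies between coding and noncoding
training sets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .errors import ConfigurationError, TrainingError, UndefinedResultError

STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"


# ---------------------------------------------------------------------------
# ORF finding


@dataclass(frozen=True)
class OpenReadingFrame:
    """An ATG-initiated reading frame on the (already oriented) transcript.

    ``end`` is half-open and includes the stop codon for stop-terminated
    ORFs; ``open_ended`` marks ORFs that run off the 3' end without a
    stop.
    """

    start: int
    end: int
    frame: int
    open_ended: bool = False

    @property
    def nt_length(self) -> int:
        return self.end - self.start

    @property
    def peptide_length_aa(self) -> int:
        n_codons = self.nt_length // 3
        return n_codons - 1 if not self.open_ended else n_codons


def find_orfs(seq: str) -> List[OpenReadingFrame]:
    """All ATG-to-stop ORFs in the three forward frames.

    Nested ORFs sharing a stop keep only the longest (most 5' ATG);
    after the last stop of a frame, a remaining ATG yields an open-ended
    ORF truncated to a codon boundary.  Codons containing N never match
    ATG or a stop.  Output sorted by length descending, ties by start.
    """
    seq = seq.upper()
    orfs: List[OpenReadingFrame] = []
    n = len(seq)
    for frame in range(3):
        start: Optional[int] = None
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if start is None and codon == START_CODON:
                start = i
            elif start is not None and codon in STOP_CODONS:
                orfs.append(OpenReadingFrame(start, i + 3, frame, False))
                start = None
            i += 3
        if start is not None:
            end = start + 3 * ((n - start) // 3)
            if end > start:
                orfs.append(OpenReadingFrame(start, end, frame, True))
    orfs.sort(key=lambda o: (-o.nt_length, o.start))
    return orfs


def longest_orf(seq: str) -> Optional[OpenReadingFrame]:
    orfs = find_orfs(seq)
    return orfs[0] if orfs else None


# ---------------------------------------------------------------------------
# Fickett TESTCODE
#
# Published position/content probability tables and weights of the
# TESTCODE statistic.  "Position" is the asymmetry of each base across
# the three codon positions, max count / (min count + 1); "content" is
# the base's overall frequency.  Each value maps through its lookup
# table to a probability of coding, weighted by the parameter's
# discriminative power, and the eight terms are summed.

_POSITION_PROB = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_EDGES = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1)

_CONTENT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_EDGES = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17)


def _lookup(value: float, edges, probs) -> float:
    for i, edge in enumerate(edges):
        if value >= edge:
            return probs[i]
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic of a nucleotide sequence.

    Non-ACGT characters are ignored in the counts; if they exceed half
    the sequence the score is undefined.
    """
    seq = seq.upper()
    if len(seq) < 2:
        raise UndefinedResultError("sequence too short for a Fickett score")
    n_acgt = sum(seq.count(b) for b in "ACGT")
    if n_acgt < 0.5 * len(seq):
        raise UndefinedResultError("more than 50% non-ACGT bases")
    phase_counts = {b: [0, 0, 0] for b in "ACGT"}
    for i, ch in enumerate(seq):
        if ch in phase_counts:
            phase_counts[ch][i % 3] += 1
    score = 0.0
    for b in "ACGT":
        counts = phase_counts[b]
        position_value = max(counts) / (min(counts) + 1)
        content_value = sum(counts) / n_acgt if n_acgt else 0.0
        score += (
            _lookup(position_value, _POSITION_EDGES, _POSITION_PROB[b])
            * _POSITION_WEIGHT[b]
        )
        score += (
            _lookup(content_value, _CONTENT_EDGES, _CONTENT_PROB[b])
            * _CONTENT_WEIGHT[b]
        )
    return score


# ---------------------------------------------------------------------------
# Hexamer usage bias

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
N_HEXAMERS = 4096


def hexamer_index(hexamer: str) -> Optional[int]:
    """Base-4 index of a 6-mer, or None if it contains non-ACGT bases."""
    idx = 0
    for ch in hexamer:
        b = _BASE_INDEX.get(ch)
        if b is None:
            return None
        idx = idx * 4 + b
    return idx


def _count_hexamers(seqs: Sequence[str], step: int) -> np.ndarray:
    counts = np.zeros(N_HEXAMERS, dtype=np.int64)
    for seq in seqs:
        seq = seq.upper()
        for i in range(0, len(seq) - 5, step):
            idx = hexamer_index(seq[i : i + 6])
            if idx is not None:
                counts[idx] += 1
    return counts


@dataclass
class HexamerTable:
    """Add-one-smoothed log(f_coding / f_noncoding) over all 4096 6-mers."""

    log_ratios: np.ndarray
    f_coding: np.ndarray
    f_noncoding: np.ndarray

    def __getitem__(self, hexamer: str) -> float:
        idx = hexamer_index(hexamer.upper())
        if idx is None:
            raise KeyError(hexamer)
        return float(self.log_ratios[idx])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("hexamer\tlog_ratio\tf_coding\tf_noncoding\n")
            for idx in range(N_HEXAMERS):
                kmer = ""
                v = idx
                for _ in range(6):
                    kmer = "ACGT"[v % 4] + kmer
                    v //= 4
                fh.write(
                    f"{kmer}\t{self.log_ratios[idx]:.12g}\t"
                    f"{self.f_coding[idx]:.12g}\t{self.f_noncoding[idx]:.12g}\n"
                )

    @classmethod
    def load(cls, path) -> "HexamerTable":
        lr = np.zeros(N_HEXAMERS)
        fc = np.zeros(N_HEXAMERS)
        fn = np.zeros(N_HEXAMERS)
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                kmer, ratio, f_c, f_n = line.rstrip("\n").split("\t")
                idx = hexamer_index(kmer)
                lr[idx] = float(ratio)
                fc[idx] = float(f_c)
                fn[idx] = float(f_n)
        return cls(lr, fc, fn)


def train_hexamer_table_from_frequencies(
    f_coding: np.ndarray, f_noncoding: np.ndarray
) -> HexamerTable:
    return HexamerTable(
        log_ratios=np.log(f_coding / f_noncoding),
        f_coding=f_coding,
        f_noncoding=f_noncoding,
    )


def train_hexamer_table(
    coding_seqs: Sequence[str], noncoding_seqs: Sequence[str]
) -> HexamerTable:
    """Train the 6-mer log-ratio table.

    Coding sequences are read in-frame (step 3, so they should be ORF /
    CDS sequences starting at a codon boundary); noncoding sequences in
    every frame (step 1).  Both count vectors are add-one smoothed.
    """
    if not coding_seqs or not noncoding_seqs:
        raise TrainingError("both training sets must be non-empty")
    c = _count_hexamers(coding_seqs, step=3)
    n = _count_hexamers(noncoding_seqs, step=1)
    f_c = (c + 1) / (c.sum() + N_HEXAMERS)
    f_n = (n + 1) / (n.sum() + N_HEXAMERS)
    return train_hexamer_table_from_frequencies(f_c, f_n)


def hexamer_score(seq: str, table: HexamerTable) -> float:
    """Mean log-ratio over the in-frame 6-mers of the longest ORF; 0 when
    there is no ORF or no complete in-frame hexamer."""
    orf = longest_orf(seq)
    if orf is None:
        return 0.0
    seq = seq.upper()
    values = []
    i = orf.start
    while i + 6 <= orf.end:
        idx = hexamer_index(seq[i : i + 6])
        if idx is not None:
            values.append(table.log_ratios[idx])
        i += 3
    if not values:
        return 0.0
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# Logistic coding-probability model

MODEL_FEATURES = ("orf_nt", "orf_coverage", "fickett", "hexamer")
MODEL_FORMAT_VERSION = 1


@dataclass
class CodingModel:
    """Serialized logistic regression on the four CPAT-style features."""

    mean: np.ndarray
    scale: np.ndarray
    coef: np.ndarray
    intercept: float
    feature_names: tuple = MODEL_FEATURES

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        x = (np.atleast_2d(features) - self.mean) / self.scale
        z = x @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def save(self, path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "feature_names": list(self.feature_names),
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "CodingModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ConfigurationError(
                f"unsupported model format {payload.get('format_version')!r}"
            )
        return cls(
            mean=np.array(payload["mean"]),
            scale=np.array(payload["scale"]),
            coef=np.array(payload["coef"]),
            intercept=float(payload["intercept"]),
            feature_names=tuple(payload["feature_names"]),
        )


def feature_vector(assessment: "CodingAssessment") -> np.ndarray:
    orf_nt = assessment.longest_orf.nt_length if assessment.longest_orf else 0
    return np.array(
        [orf_nt, assessment.orf_coverage, assessment.fickett, assessment.hexamer],
        dtype=float,
    )


def train_coding_model(
    assessments: Sequence["CodingAssessment"], labels: Sequence[int]
) -> CodingModel:
    """Fit the logistic model; labels are 1 = coding, 0 = noncoding.

    Features are standardized before the fit; the fitted parameters are
    frozen into a :class:`CodingModel` so that loaded and freshly
    trained models score identically.
    """
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise TrainingError("training input contains a single class")
    x = np.vstack([feature_vector(a) for a in assessments])
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    xs = (x - mean) / scale
    clf = LogisticRegression(C=100.0, solver="lbfgs", max_iter=5000)
    clf.fit(xs, y)
    return CodingModel(
        mean=mean,
        scale=scale,
        coef=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
    )


# ---------------------------------------------------------------------------
# Assessment and cascade


@dataclass
class CodingAssessment:
    """Everything the cascade needs to know about one transcript sequence.

    External scores: ``pfam_best_evalue`` is ``inf`` for "searched, no
    hit", a float for the best hit, and ``None`` when no PFAM table was
    supplied at all (criterion skipped).  ``external_noncoding_score``
    is ``None`` when not supplied.
    """

    transcript_id: str
    longest_orf: Optional[OpenReadingFrame]
    fickett: float
    hexamer: float
    orf_coverage: float
    coding_probability: Optional[float] = None
    pfam_best_evalue: Optional[float] = None
    external_noncoding_score: Optional[float] = None


def compute_assessment(
    transcript_id: str,
    seq: str,
    hexamer_table: HexamerTable,
    model: Optional[CodingModel] = None,
    pfam_best_evalue: Optional[float] = None,
    external_noncoding_score: Optional[float] = None,
) -> CodingAssessment:
    """Score one oriented transcript sequence."""
    orf = longest_orf(seq)
    try:
        fickett = fickett_score(seq)
    except UndefinedResultError:
        fickett = float("nan")
    hexamer = hexamer_score(seq, hexamer_table)
    coverage = (orf.nt_length / len(seq)) if (orf and len(seq) > 0) else 0.0
    assessment = CodingAssessment(
        transcript_id=transcript_id,
        longest_orf=orf,
        fickett=fickett,
        hexamer=hexamer,
        orf_coverage=coverage,
        pfam_best_evalue=pfam_best_evalue,
        external_noncoding_score=external_noncoding_score,
    )
    if model is not None:
        assessment.coding_probability = float(
            model.predict_proba(feature_vector(assessment))[0]
        )
    return assessment


CRITERIA = (
    "length_gt_200",
    "orf_lt_400",
    "pfam_no_match",
    "noncoding_score",
    "coding_probability",
    "flank_removal",
)

PASS, FAIL, SKIPPED = "pass", "fail", "skipped"


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds of the six lncRNA filter criteria.

    ``cpat_direction='noncoding'`` keeps transcripts whose coding
    probability is *below* ``cpat_threshold`` — the reading consistent
    with screening for noncoding transcripts, since under the CPAT
    convention high probability means coding.  ``'literal'`` inverts the
    comparison (keep > threshold) for strict reproduction of a
    published-as-printed filter direction.
    """

    length_min: int = 200
    orf_max: int = 400
    pfam_evalue_min: float = 1e-5
    noncoding_score_min: float = 0.5
    cpat_threshold: float = 0.375
    cpat_direction: str = "noncoding"

    def __post_init__(self):
        if self.length_min < 1:
            raise ConfigurationError("length_min must be >= 1")
        if self.orf_max < 1:
            raise ConfigurationError("orf_max must be >= 1")
        if self.pfam_evalue_min <= 0:
            raise ConfigurationError("pfam_evalue_min must be positive")
        if not 0 <= self.noncoding_score_min <= 1:
            raise ConfigurationError("noncoding_score_min must be in [0, 1]")
        if not 0 <= self.cpat_threshold <= 1:
            raise ConfigurationError("cpat_threshold must be in [0, 1]")
        if self.cpat_direction not in ("noncoding", "literal"):
            raise ConfigurationError(
                "cpat_direction must be 'noncoding' or 'literal'"
            )


@dataclass
class FilterDecision:
    """Per-criterion verdicts for one transcript; all criteria are always
    evaluated and reported, never short-circuited."""

    transcript_id: str
    verdicts: Dict[str, str]
    overall: bool
    first_failed: Optional[str]


def apply_filter_cascade(
    transcript_length_nt: int,
    assessment: CodingAssessment,
    config: CascadeConfig = CascadeConfig(),
    flank_pass: Optional[bool] = None,
) -> FilterDecision:
    """Evaluate all six criteria for one candidate.

    ``flank_pass`` carries the anchoring module's flank-filter verdict
    (None -> criterion skipped).  Missing external score tables yield
    ``skipped`` verdicts, never silent passes; the overall verdict is a
    pass iff no *evaluated* criterion fails.
    """
    v: Dict[str, str] = {}
    v["length_gt_200"] = PASS if transcript_length_nt > config.length_min else FAIL

    orf = assessment.longest_orf
    v["orf_lt_400"] = PASS if (orf is None or orf.nt_length < config.orf_max) else FAIL

    e = assessment.pfam_best_evalue
    if e is None:
        v["pfam_no_match"] = SKIPPED
    else:
        v["pfam_no_match"] = PASS if e > config.pfam_evalue_min else FAIL

    s = assessment.external_noncoding_score
    if s is None:
        v["noncoding_score"] = SKIPPED
    else:
        v["noncoding_score"] = PASS if s > config.noncoding_score_min else FAIL

    p = assessment.coding_probability
    if p is None or (isinstance(p, float) and math.isnan(p)):
        v["coding_probability"] = SKIPPED
    elif config.cpat_direction == "noncoding":
        v["coding_probability"] = PASS if p < config.cpat_threshold else FAIL
    else:
        v["coding_probability"] = PASS if p > config.cpat_threshold else FAIL

    if flank_pass is None:
        v["flank_removal"] = SKIPPED
    else:
        v["flank_removal"] = PASS if flank_pass else FAIL

    first_failed = next((c for c in CRITERIA if v[c] == FAIL), None)
    return FilterDecision(
        transcript_id=assessment.transcript_id,
        verdicts=v,
        overall=first_failed is None,
        first_failed=first_failed,
    )


# ---------------------------------------------------------------------------
# External score tables


def read_score_table(path, value_column: str) -> Dict[str, float]:
    """Read a 2-column TSV of transcript_id -> score (PFAM best E-value
    or external noncoding score)."""
    table: Dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:1] != ["transcript_id"] or len(header) != 2:
            raise ConfigurationError(
                f"score table must have columns (transcript_id, {value_column})"
            )
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            tid, value = line.split("\t")
            table[tid] = float(value)
    return table
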