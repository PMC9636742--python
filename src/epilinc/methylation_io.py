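"""Read, validate and filter per-CpG methylation count files.

Input files are per-sample tables of methylated / unmethylated read
counts at single cytosines, in either the bismark-coverage dialect
(1-based inclusive, six columns) or a bedGraph fraction track with a
companion coverage file (0-based half-open).  Internally everything is
0-based half-open; conversions happen only at the file boundary.

Missing (site, sample) pairs are represented as coverage 0 and never
imputed — the exact test downstream handles empty cells natively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping

import numpy as np

from .errors import ConfigurationError, ParseError

STRANDS = ("+", "-", ".")
GROUPS = ("case", "control")


@dataclass(frozen=True, order=True)
class CpGSite:
    """A single cytosine of a CpG dinucleotide, 0-based."""

    chrom: str
    pos: int
    strand: str = "."

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")


@dataclass(frozen=True)
class SampleCounts:
    """Methylated/unmethylated read counts for one site in one sample."""

    methylated: int
    unmethylated: int

    def __post_init__(self):
        if self.methylated < 0 or self.unmethylated < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def coverage(self) -> int:
        return self.methylated + self.unmethylated


SampleTable = Dict[CpGSite, SampleCounts]


@dataclass
class MethylationMatrix:
    """Site-by-sample grid of methylation counts with case/control labels.

    ``meth`` and ``unmeth`` are (n_sites, n_samples) integer arrays aligned
    with ``sites`` (sorted by chrom, pos, strand) and ``samples``.
    """

    sites: list
    samples: list
    group: Dict[str, str]
    meth: np.ndarray
    unmeth: np.ndarray

    def __post_init__(self):
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.unmeth = np.asarray(self.unmeth, dtype=np.int64)
        if self.meth.shape != (len(self.sites), len(self.samples)):
            raise ValueError("count array shape does not match sites x samples")
        if self.meth.shape != self.unmeth.shape:
            raise ValueError("meth/unmeth shapes differ")
        for s in self.samples:
            if self.group.get(s) not in GROUPS:
                raise ConfigurationError(
                    f"sample {s!r} has no case/control group label"
                )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def coverage(self) -> np.ndarray:
        return self.meth + self.unmeth

    def group_indices(self, label: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if self.group[s] == label],
            dtype=int,
        )

    def counts(self, site_index: int, sample_index: int) -> SampleCounts:
        return SampleCounts(
            int(self.meth[site_index, sample_index]),
            int(self.unmeth[site_index, sample_index]),
        )

    def __eq__(self, other):
        return (
            isinstance(other, MethylationMatrix)
            and self.sites == other.sites
            and self.samples == other.samples
            and self.group == other.group
            and np.array_equal(self.meth, other.meth)
            and np.array_equal(self.unmeth, other.unmeth)
        )


def _parse_int(text: str, what: str, path, lineno) -> int:
    try:
        value = int(text)
    except ValueError:
        raise ParseError(f"non-integer {what}: {text!r}", path, lineno) from None
    if value < 0:
        raise ParseError(f"negative {what}: {value}", path, lineno)
    return value


def _read_bismark_cov(path) -> SampleTable:
    table: SampleTable = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(
                    f"expected 6 tab-separated columns, got {len(fields)}",
                    path, lineno,
                )
            chrom, start, _end, pct, n_meth, n_unmeth = fields
            pos = _parse_int(start, "position", path, lineno) - 1
            if pos < 0:
                raise ParseError("1-based position must be >= 1", path, lineno)
            meth = _parse_int(n_meth, "methylated count", path, lineno)
            unmeth = _parse_int(n_unmeth, "unmethylated count", path, lineno)
            cov = meth + unmeth
            if cov > 0:
                try:
                    stated = float(pct)
                except ValueError:
                    raise ParseError(
                        f"non-numeric methylation percentage: {pct!r}", path, lineno
                    ) from None
                if abs(stated - 100.0 * meth / cov) > 0.5:
                    warnings.warn(
                        f"{path}:{lineno}: stated methylation {stated}% "
                        f"inconsistent with counts {meth}/{cov}; counts win"
                    )
            site = CpGSite(chrom, pos)
            if site in table:
                raise ParseError(f"duplicate site {chrom}:{pos}", path, lineno)
            table[site] = SampleCounts(meth, unmeth)
    return table


def _read_bedgraph(path, coverage_path) -> SampleTable:
    if coverage_path is None:
        raise ConfigurationError(
            "bedGraph methylation fractions carry no read-count evidence; "
            "a companion coverage file is required for calling"
        )
    coverage: Dict[tuple, int] = {}
    with open(coverage_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(
                    f"expected 4 columns in coverage file, got {len(fields)}",
                    coverage_path, lineno,
                )
            chrom, start, _end, cov = fields
            pos = _parse_int(start, "position", coverage_path, lineno)
            coverage[(chrom, pos)] = _parse_int(cov, "coverage", coverage_path, lineno)

    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(
                    f"expected 4 tab-separated columns, got {len(fields)}",
                    path, lineno,
                )
            chrom, start, _end, frac = fields
            pos = _parse_int(start, "position", path, lineno)
            try:
                value = float(frac)
            except ValueError:
                raise ParseError(
                    f"non-numeric methylation value: {frac!r}", path, lineno
                ) from None
            if value < 0:
                raise ParseError(f"negative methylation value {value}", path, lineno)
            rows.append((chrom, pos, value, lineno))

    # a track whose values exceed 1 is read as percentages
    percent = any(v > 1.0 for _, _, v, _ in rows)
    table: SampleTable = {}
    for chrom, pos, value, lineno in rows:
        frac = value / 100.0 if percent else value
        if (chrom, pos) not in coverage:
            raise ParseError(
                f"site {chrom}:{pos} missing from coverage file", path, lineno
            )
        cov = coverage[(chrom, pos)]
        meth = int(round(frac * cov))
        site = CpGSite(chrom, pos)
        if site in table:
            raise ParseError(f"duplicate site {chrom}:{pos}", path, lineno)
        table[site] = SampleCounts(meth, cov - meth)
    return table


def read_methylation_calls(
    path, dialect: str = "bismark_cov", coverage_path=None
) -> SampleTable:
    """Read one sample's per-CpG counts into a site -> counts mapping.

    ``dialect`` is ``bismark_cov`` (6 columns, 1-based inclusive; the
    percentage column is checked against the counts but the counts win)
    or ``bedgraph`` (4 columns, 0-based half-open fractions; requires
    ``coverage_path`` with matching 4-column integer coverages).
    Zero-coverage rows are retained.
    """
    if dialect == "bismark_cov":
        return _read_bismark_cov(path)
    if dialect == "bedgraph":
        return _read_bedgraph(path, coverage_path)
    raise ConfigurationError(f"unknown dialect {dialect!r}")


def write_methylation_calls(
    table: SampleTable, path, dialect: str = "bismark_cov", coverage_path=None
) -> None:
    """Write a per-sample table, inverse of :func:`read_methylation_calls`."""
    sites = sorted(table)
    if dialect == "bismark_cov":
        with open(path, "w") as fh:
            for site in sites:
                c = table[site]
                pct = 0.0 if c.coverage == 0 else 100.0 * c.methylated / c.coverage
                fh.write(
                    f"{site.chrom}\t{site.pos + 1}\t{site.pos + 1}\t"
                    f"{pct:.10g}\t{c.methylated}\t{c.unmethylated}\n"
                )
    elif dialect == "bedgraph":
        if coverage_path is None:
            raise ConfigurationError(
                "bedgraph output requires a companion coverage_path"
            )
        with open(path, "w") as fh, open(coverage_path, "w") as ch:
            for site in sites:
                c = table[site]
                frac = 0.0 if c.coverage == 0 else c.methylated / c.coverage
                fh.write(
                    f"{site.chrom}\t{site.pos}\t{site.pos + 1}\t{frac:.10g}\n"
                )
                ch.write(
                    f"{site.chrom}\t{site.pos}\t{site.pos + 1}\t{c.coverage}\n"
                )
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}")


def merge_strand_counts(table: SampleTable) -> SampleTable:
    """Destrand a table: counts on '-' cytosines are summed onto the '+'
    cytosine one base upstream (the C of the same CpG on the other strand).

    Sites already unstranded ('.') or on '+' keep their coordinate.
    """
    merged: SampleTable = {}
    for site, counts in table.items():
        if site.strand == "-":
            if site.pos == 0:
                key = site  # cannot shift off the contig; keep as-is
            else:
                key = CpGSite(site.chrom, site.pos - 1, "+")
        elif site.strand == "+":
            key = site
        else:
            key = CpGSite(site.chrom, site.pos, ".")
        if key in merged:
            prev = merged[key]
            merged[key] = SampleCounts(
                prev.methylated + counts.methylated,
                prev.unmethylated + counts.unmethylated,
            )
        else:
            merged[key] = counts
    return merged


def build_matrix(
    tables: Mapping[str, SampleTable],
    groups: Mapping[str, str],
    merge_strands: bool = False,
) -> MethylationMatrix:
    """Assemble per-sample tables into one matrix over the union of sites.

    Every sample must carry a group label in ``groups`` and at least one
    case and one control sample are required.  Pairs absent from a
    sample's table get coverage 0.
    """
    samples = list(tables)
    for s in samples:
        if groups.get(s) not in GROUPS:
            raise ConfigurationError(f"sample {s!r} has no case/control group label")
    labels = {groups[s] for s in samples}
    if labels != set(GROUPS):
        raise ConfigurationError(
            "need at least one 'case' and one 'control' sample, "
            f"got groups {sorted(labels)}"
        )
    if merge_strands:
        tables = {s: merge_strand_counts(t) for s, t in tables.items()}
    site_set = set()
    for t in tables.values():
        site_set.update(t)
    sites = sorted(site_set)
    index = {site: i for i, site in enumerate(sites)}
    meth = np.zeros((len(sites), len(samples)), dtype=np.int64)
    unmeth = np.zeros_like(meth)
    for j, s in enumerate(samples):
        for site, c in tables[s].items():
            i = index[site]
            meth[i, j] = c.methylated
            unmeth[i, j] = c.unmethylated
    return MethylationMatrix(
        sites=sites,
        samples=samples,
        group={s: groups[s] for s in samples},
        meth=meth,
        unmeth=unmeth,
    )


def filter_by_coverage(
    matrix: MethylationMatrix, min_cov: int, min_fraction_samples: float
) -> MethylationMatrix:
    """Keep sites covered at >= ``min_cov`` reads in at least
    ``min_fraction_samples`` of the samples of *each* group."""
    if min_cov < 1:
        raise ConfigurationError("min_cov must be >= 1")
    if not 0 < min_fraction_samples <= 1:
        raise ConfigurationError("min_fraction_samples must be in (0, 1]")
    cov = matrix.coverage
    keep = np.ones(matrix.n_sites, dtype=bool)
    for label in GROUPS:
        idx = matrix.group_indices(label)
        frac = (cov[:, idx] >= min_cov).mean(axis=1)
        # nudge for float representation of fractions like 2/3
        keep &= frac >= min_fraction_samples - 1e-12
    kept = np.flatnonzero(keep)
    return MethylationMatrix(
        sites=[matrix.sites[i] for i in kept],
        samples=list(matrix.samples),
        group=dict(matrix.group),
        meth=matrix.meth[kept],
        unmeth=matrix.unmeth[kept],
    )
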