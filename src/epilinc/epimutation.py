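"""Differential single-CpG epimutation calling and primer-region search.

A site's effect size is the coverage-weighted pooled methylation
difference between case and control; its significance is a two-sided
Fisher exact test on the pooled 2x2 table.  Calls are adjusted with
Benjamini-Hochberg across every tested site, thresholded on |delta| and
the adjusted p, and ranked by |delta| (ties: smaller p, then position) —
so rank 1 is the site with the strongest differential methylation rate.

For wet-lab follow-up (MS-HRM melt assays) the module also enumerates
candidate amplicon windows around a call, scored by how many CpGs they
capture: more CpGs inside the amplicon means a larger melting-curve
shift between methylated and unmethylated templates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from ._exact import fisher_exact_two_sided_many
from .errors import ConfigurationError, ParseError, UndefinedResultError
from .methylation_io import CpGSite, MethylationMatrix, SampleCounts


@dataclass(frozen=True)
class EpimutationCall:
    """One differentially methylated CpG site."""

    site: CpGSite
    mean_case: float
    mean_control: float
    delta: float
    p_value: float
    q_value: float
    rank: int
    n_case_covered: int
    n_control_covered: int


@dataclass(frozen=True)
class PrimerRegion:
    """A candidate MS-HRM amplicon window containing an epimutation call."""

    chrom: str
    start: int
    end: int
    n_cpgs: int
    anchor: EpimutationCall

    @property
    def length_nt(self) -> int:
        return self.end - self.start


def site_statistic(
    case: Sequence[SampleCounts], control: Sequence[SampleCounts]
) -> tuple:
    """Pooled effect size and two-sided Fisher exact p for one site.

    delta = (sum meth_case / sum cov_case) - (sum meth_ctrl / sum cov_ctrl);
    the p-value tests the pooled 2x2 table
    [[meth_case, unmeth_case], [meth_ctrl, unmeth_ctrl]].
    """
    m_case = sum(c.methylated for c in case)
    u_case = sum(c.unmethylated for c in case)
    m_ctrl = sum(c.methylated for c in control)
    u_ctrl = sum(c.unmethylated for c in control)
    if m_case + u_case == 0 or m_ctrl + u_ctrl == 0:
        raise UndefinedResultError("zero total coverage in one group")
    delta = m_case / (m_case + u_case) - m_ctrl / (m_ctrl + u_ctrl)
    p = fisher_exact_two_sided_many(
        np.array([m_case]), np.array([u_case]),
        np.array([m_ctrl]), np.array([u_ctrl]),
    )[0]
    return float(delta), float(p)


def pooled_site_pvalues(
    meth_case, unmeth_case, meth_control, unmeth_control
) -> np.ndarray:
    """Vectorized two-sided Fisher exact p-values for pooled per-site tables."""
    return fisher_exact_two_sided_many(
        meth_case, unmeth_case, meth_control, unmeth_control
    )


def call_epimutations(
    matrix: MethylationMatrix,
    min_cov: int = 1,
    min_abs_delta: float = 0.0,
    alpha: float = 0.05,
) -> List[EpimutationCall]:
    """Call, adjust, filter and rank differential single-CpG epimutations.

    Sites with zero pooled coverage in either group are untestable and
    skipped.  BH adjustment runs across all tested sites; a site is kept
    when ``|delta| >= min_abs_delta`` and ``q <= alpha``.  Output order
    is |delta| descending, ties broken by smaller p, then (chrom, pos);
    ranks are 1-based in that order.
    """
    if matrix.n_sites == 0:
        return []
    case_idx = matrix.group_indices("case")
    ctrl_idx = matrix.group_indices("control")
    mc = matrix.meth[:, case_idx].sum(axis=1)
    uc = matrix.unmeth[:, case_idx].sum(axis=1)
    mk = matrix.meth[:, ctrl_idx].sum(axis=1)
    uk = matrix.unmeth[:, ctrl_idx].sum(axis=1)
    testable = (mc + uc > 0) & (mk + uk > 0)
    if not testable.any():
        return []
    idx = np.flatnonzero(testable)
    mean_case = mc[idx] / (mc + uc)[idx]
    mean_ctrl = mk[idx] / (mk + uk)[idx]
    delta = mean_case - mean_ctrl
    p = fisher_exact_two_sided_many(mc[idx], uc[idx], mk[idx], uk[idx])
    q = multipletests(p, method="fdr_bh")[1]

    cov_floor = max(min_cov, 1)
    cov = matrix.coverage
    n_case_cov = (cov[:, case_idx] >= cov_floor).sum(axis=1)
    n_ctrl_cov = (cov[:, ctrl_idx] >= cov_floor).sum(axis=1)

    selected = (np.abs(delta) >= min_abs_delta) & (q <= alpha)
    order = sorted(
        np.flatnonzero(selected),
        key=lambda j: (
            -abs(delta[j]),
            p[j],
            matrix.sites[idx[j]].chrom,
            matrix.sites[idx[j]].pos,
        ),
    )
    calls = []
    for rank, j in enumerate(order, start=1):
        i = int(idx[j])
        calls.append(
            EpimutationCall(
                site=matrix.sites[i],
                mean_case=float(mean_case[j]),
                mean_control=float(mean_ctrl[j]),
                delta=float(delta[j]),
                p_value=float(p[j]),
                q_value=float(q[j]),
                rank=rank,
                n_case_covered=int(n_case_cov[i]),
                n_control_covered=int(n_ctrl_cov[i]),
            )
        )
    return calls


def top_candidates(calls: Sequence[EpimutationCall], k: int) -> List[EpimutationCall]:
    """The first ``min(k, len(calls))`` calls by rank."""
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    ordered = sorted(calls, key=lambda c: c.rank)
    return list(ordered[:k])


def _contig_sequence(genome, chrom: str) -> str:
    try:
        contig = genome[chrom]
    except KeyError:
        raise UndefinedResultError(f"chromosome {chrom!r} not in genome") from None
    return str(contig[:]).upper()


def find_primer_regions(
    call: EpimutationCall,
    genome,
    min_len: int = 80,
    max_len: int = 250,
    min_cpgs: int = 2,
    max_cpgs: int = 25,
    limit: int | None = None,
) -> List[PrimerRegion]:
    """Enumerate amplicon windows around a call for MS-HRM primer design.

    Every half-open window of length in ``[min_len, max_len]`` that fully
    contains the anchor CpG dinucleotide and lies inside the contig is
    scored by the number of plus-strand CG dinucleotides it fully contains.
    Windows with ``min_cpgs <= n <= max_cpgs`` are returned, best first
    (more CpGs, then shorter, then leftmost).  Near a contig end the
    admissible set simply shrinks; it may be empty but never raises.
    """
    if not (1 <= min_len <= max_len):
        raise ConfigurationError("need 1 <= min_len <= max_len")
    if not (0 <= min_cpgs <= max_cpgs):
        raise ConfigurationError("need 0 <= min_cpgs <= max_cpgs")
    chrom = call.site.chrom
    pos = call.site.pos
    seq = _contig_sequence(genome, chrom)
    contig_len = len(seq)
    if pos >= contig_len:
        return []
    lo = max(0, pos - max_len)
    hi = min(contig_len, pos + max_len + 2)
    local = seq[lo:hi]
    # prefix[i] = number of CG starts in local[:i]
    is_cg = np.array(
        [1 if local[i : i + 2] == "CG" else 0 for i in range(len(local))],
        dtype=np.int64,
    )
    prefix = np.concatenate([[0], np.cumsum(is_cg)])

    regions = []
    for length in range(min_len, max_len + 1):
        # window [s, s+length) must contain [pos, pos+2)
        s_lo = max(lo, pos + 2 - length)
        s_hi = min(pos, contig_len - length)
        for s in range(s_lo, s_hi + 1):
            a, b = s - lo, s - lo + length
            # CG starts fully inside the window: start index in [a, b-1)
            n = int(prefix[max(b - 1, a)] - prefix[a])
            if min_cpgs <= n <= max_cpgs:
                regions.append(PrimerRegion(chrom, s, s + length, n, call))
    regions.sort(key=lambda r: (-r.n_cpgs, r.length_nt, r.start))
    if limit is not None:
        regions = regions[:limit]
    return regions


# ---------------------------------------------------------------------------
# BED interchange


def write_calls_bed(calls: Sequence[EpimutationCall], path) -> None:
    """BED6+ export: name=rank, score=round(1000*|delta|), then
    delta, p, q, mean_case, mean_control, n_case_covered, n_control_covered."""
    with open(path, "w") as fh:
        for c in calls:
            score = min(1000, int(round(1000 * abs(c.delta))))
            fh.write(
                f"{c.site.chrom}\t{c.site.pos}\t{c.site.pos + 1}\t{c.rank}\t"
                f"{score}\t{c.site.strand}\t{c.delta!r}\t{c.p_value!r}\t"
                f"{c.q_value!r}\t{c.mean_case!r}\t{c.mean_control!r}\t"
                f"{c.n_case_covered}\t{c.n_control_covered}\n"
            )


def read_calls_bed(path) -> List[EpimutationCall]:
    """Inverse of :func:`write_calls_bed`."""
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 13:
                raise ParseError(f"expected 13 columns, got {len(f)}", path, lineno)
            calls.append(
                EpimutationCall(
                    site=CpGSite(f[0], int(f[1]), f[5]),
                    mean_case=float(f[9]),
                    mean_control=float(f[10]),
                    delta=float(f[6]),
                    p_value=float(f[7]),
                    q_value=float(f[8]),
                    rank=int(f[3]),
                    n_case_covered=int(f[11]),
                    n_control_covered=int(f[12]),
                )
            )
    return calls


def write_primer_regions_bed(regions: Sequence[PrimerRegion], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions, start=1):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\tregion_{i}\t{r.n_cpgs}\t+\t"
                f"{r.anchor.site.pos}\n"
            )
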