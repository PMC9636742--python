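"""Differential epimutation calling, ranking and primer-region search."""

import numpy as np
import pytest

from epilinc.epimutation import (
    EpimutationCall,
    call_epimutations,
    find_primer_regions,
    read_calls_bed,
    site_statistic,
    top_candidates,
    write_calls_bed,
)
from epilinc.errors import ConfigurationError, UndefinedResultError
from epilinc.methylation_io import CpGSite, MethylationMatrix, SampleCounts
from epilinc.synthetic_data import simulate_matrix, _rng

from test_exact import enumeration_p


def matrix_from_pooled(tables):
    """One-sample-per-group matrix from [(m_case, u_case, m_ctrl, u_ctrl)]."""
    tables = np.asarray(tables)
    return MethylationMatrix(
        sites=[CpGSite("chr1", 10 * i) for i in range(len(tables))],
        samples=["case_1", "control_1"],
        group={"case_1": "case", "control_1": "control"},
        meth=tables[:, [0, 2]],
        unmeth=tables[:, [1, 3]],
    )


class TestSiteStatistic:
    def test_identical_groups_give_zero_delta_and_p_one(self):
        counts = [SampleCounts(10, 0)]
        delta, p = site_statistic(counts, counts)
        assert delta == 0.0
        assert p == 1.0

    def test_nine_one_table_matches_hypergeometric_enumeration(self):
        delta, p = site_statistic([SampleCounts(9, 1)], [SampleCounts(1, 9)])
        assert p == pytest.approx(enumeration_p(9, 1, 1, 9), abs=1e-12)
        assert delta == pytest.approx(0.8)

    def test_extreme_table(self):
        delta, p = site_statistic([SampleCounts(0, 20)], [SampleCounts(20, 0)])
        assert delta == -1.0
        assert p == pytest.approx(enumeration_p(0, 20, 20, 0), abs=1e-15)

    def test_coverage_weighted_pooling(self):
        # 9/10 + 0/10 pooled = 9/20, not the per-sample mean of 0.45/0.0
        case = [SampleCounts(9, 1), SampleCounts(0, 10)]
        control = [SampleCounts(0, 20)]
        delta, _ = site_statistic(case, control)
        assert delta == pytest.approx(9 / 20)

    def test_zero_coverage_group_is_undefined(self):
        with pytest.raises(UndefinedResultError):
            site_statistic([SampleCounts(0, 0)], [SampleCounts(5, 5)])


class TestCallEpimutations:
    def test_empty_matrix_gives_empty_list(self):
        m = matrix_from_pooled(np.empty((0, 4), dtype=int))
        assert call_epimutations(m) == []

    def test_unreachable_delta_threshold_gives_empty_list(self):
        m = matrix_from_pooled([[20, 0, 0, 20]])
        assert call_epimutations(m, min_abs_delta=1.01) == []

    def test_equal_delta_ties_break_by_smaller_p(self):
        # same pooled fractions, doubled coverage -> same delta, smaller p
        m = matrix_from_pooled([[8, 2, 2, 8], [16, 4, 4, 16]])
        calls = call_epimutations(m, min_abs_delta=0.0, alpha=1.0)
        assert [c.rank for c in calls] == [1, 2]
        assert calls[0].p_value < calls[1].p_value
        assert abs(calls[0].delta) == abs(calls[1].delta)
        assert calls[0].site.pos == 10  # the deeper-covered site wins

    def test_planted_site_recovers_rank_one(self):
        rng = _rng(123, 0)
        m = simulate_matrix(
            rng, 1000, 6, 6, 30.0, planted={500: ((9, 1), (1, 9))}
        )
        calls = call_epimutations(m, min_cov=1, min_abs_delta=0.0, alpha=1.0)
        assert calls[0].site == m.sites[500]
        assert calls[0].delta > 0.5

    def test_deterministic_reruns_are_byte_identical(self, tmp_path):
        rng = _rng(9, 0)
        m = simulate_matrix(rng, 200, 4, 4, 20.0, planted={7: ((9, 1), (1, 9))})
        calls1 = call_epimutations(m, min_abs_delta=0.2, alpha=0.5)
        calls2 = call_epimutations(m, min_abs_delta=0.2, alpha=0.5)
        write_calls_bed(calls1, tmp_path / "a.bed")
        write_calls_bed(calls2, tmp_path / "b.bed")
        assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()

    def test_bed_round_trip(self, tmp_path):
        rng = _rng(10, 0)
        m = simulate_matrix(rng, 100, 3, 3, 25.0, planted={5: ((9, 1), (1, 9))})
        calls = call_epimutations(m, min_abs_delta=0.0, alpha=1.0)
        write_calls_bed(calls, tmp_path / "c.bed")
        assert read_calls_bed(tmp_path / "c.bed") == calls

    def test_q_values_are_bh_adjusted(self):
        # one strong site among nulls: its q = p * n_tests / rank(le)
        m = matrix_from_pooled([[20, 0, 0, 20], [5, 5, 5, 5], [6, 4, 4, 6]])
        calls = call_epimutations(m, min_abs_delta=0.0, alpha=1.0)
        top = calls[0]
        assert top.q_value == pytest.approx(min(1.0, top.p_value * 3), rel=1e-9)


class TestTopCandidates:
    def make_calls(self, n):
        return [
            EpimutationCall(
                CpGSite("chr1", i), 0.9, 0.1, 0.8, 1e-6, 1e-5, i + 1, 6, 6
            )
            for i in range(n)
        ]

    def test_two_best_of_many_calls(self):
        top = top_candidates(self.make_calls(194), 2)
        assert [c.rank for c in top] == [1, 2]

    def test_empty_and_oversized_k(self):
        assert top_candidates([], 5) == []
        calls = self.make_calls(3)
        assert top_candidates(calls, 10) == calls

    def test_k_below_one_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            top_candidates(self.make_calls(3), 0)


def _call_at(chrom, pos):
    return EpimutationCall(CpGSite(chrom, pos), 0.9, 0.1, 0.8, 1e-8, 1e-7, 1, 6, 6)


def brute_force_windows(seq, pos, min_len, max_len, min_cpgs, max_cpgs):
    hits = set()
    for s in range(len(seq)):
        for length in range(min_len, max_len + 1):
            e = s + length
            if e > len(seq) or not (s <= pos and pos + 2 <= e):
                continue
            n = sum(1 for i in range(s, e - 1) if seq[i : i + 2] == "CG")
            if min_cpgs <= n <= max_cpgs:
                hits.add((s, e, n))
    return hits


class TestPrimerRegions:
    def test_windows_match_brute_force_enumeration(self):
        rng = np.random.default_rng(21)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        pos = 1000
        seq = seq[:pos] + "CG" + seq[pos + 2 :]
        genome = {"chr1": seq}
        regions = find_primer_regions(
            _call_at("chr1", pos), genome, min_len=60, max_len=90,
            min_cpgs=3, max_cpgs=8,
        )
        got = {(r.start, r.end, r.n_cpgs) for r in regions}
        assert got == brute_force_windows(seq, pos, 60, 90, 3, 8)
        # ordering: best CpG capture first, then shortest amplicon
        keys = [(-r.n_cpgs, r.length_nt, r.start) for r in regions]
        assert keys == sorted(keys)

    def test_single_cg_genome_with_min_two_cpgs_is_empty(self):
        genome = {"chr1": "AT" * 500 + "CG" + "TA" * 500}
        assert (
            find_primer_regions(
                _call_at("chr1", 1000), genome, min_cpgs=2, max_cpgs=10
            )
            == []
        )

    def test_degenerate_length_range_returns_fixed_length(self):
        rng = np.random.default_rng(22)
        seq = "".join(rng.choice(list("ACGT"), size=1500))
        seq = seq[:700] + "CG" + seq[702:]
        regions = find_primer_regions(
            _call_at("chr1", 700), {"chr1": seq}, min_len=100, max_len=100,
            min_cpgs=0, max_cpgs=100,
        )
        assert regions and all(r.length_nt == 100 for r in regions)

    def test_anchor_near_contig_end_clips_and_never_raises(self):
        genome = {"chr1": "ACGT" * 10}  # 40 nt contig
        regions = find_primer_regions(
            _call_at("chr1", 1), genome, min_len=30, max_len=60,
            min_cpgs=0, max_cpgs=100,
        )
        assert all(r.start >= 0 and r.end <= 40 for r in regions)
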