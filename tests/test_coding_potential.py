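"""ORF finding, Fickett/hexamer features, the logistic model and the
filter cascade."""

import numpy as np
import pytest

from epilinc.coding_potential import (
    STOP_CODONS,
    CascadeConfig,
    CodingModel,
    apply_filter_cascade,
    compute_assessment,
    fickett_score,
    find_orfs,
    hexamer_score,
    longest_orf,
    train_coding_model,
    train_hexamer_table,
    train_hexamer_table_from_frequencies,
)
from epilinc.errors import (
    ConfigurationError,
    TrainingError,
    UndefinedResultError,
)
from epilinc.synthetic_data import (
    _rng,
    make_coding_sequence,
    make_noncoding_sequence,
    make_training_sets,
)


def orf_oracle(seq):
    """All-pairs forward-scan oracle: for each ATG walk to its stop,
    then keep the most 5' ATG per (stop, frame)."""
    seq = seq.upper()
    n = len(seq)
    best = {}
    for a in range(n - 2):
        if seq[a : a + 3] != "ATG":
            continue
        j = a + 3
        stop = None
        while j + 3 <= n:
            if seq[j : j + 3] in STOP_CODONS:
                stop = j
                break
            j += 3
        if stop is not None:
            key = (stop + 3, a % 3, False)
        else:
            key = (a + 3 * ((n - a) // 3), a % 3, True)
        best[key] = min(best.get(key, a), a)
    return {
        (a, end, open_ended) for (end, _frame, open_ended), a in best.items()
    }


class TestFindOrfs:
    def test_minimal_orf(self):
        (orf,) = find_orfs("ATGAAATAG")
        assert (orf.start, orf.end, orf.nt_length) == (0, 9, 9)
        assert orf.peptide_length_aa == 2
        assert not orf.open_ended

    def test_no_start_codon_gives_empty_list(self):
        assert find_orfs("CCCCCCTAGCCC") == []

    def test_codon_with_n_is_neither_start_nor_stop(self):
        (orf,) = find_orfs("ATGNNATAG")  # NNA is passed through
        assert orf.nt_length == 9
        # TNA is not a stop, so the frame runs off the end
        (orf2,) = find_orfs("ATGAAATNA")
        assert orf2.open_ended and orf2.nt_length == 9

    def test_nested_starts_keep_most_5prime_atg(self):
        (orf,) = [o for o in find_orfs("ATGATGAAATAA") if o.frame == 0]
        assert orf.start == 0 and orf.end == 12

    def test_matches_oracle_on_random_sequences(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGTN"), size=300,
                                     p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            got = {(o.start, o.end, o.open_ended) for o in find_orfs(seq)}
            assert got == orf_oracle(seq)

    def test_peptide_length_identity_for_stop_terminated(self):
        rng = np.random.default_rng(78)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=240))
            for o in find_orfs(seq):
                if not o.open_ended:
                    assert o.peptide_length_aa * 3 + 3 == o.nt_length

    def test_sorted_longest_first(self):
        orfs = find_orfs("ATGAAATAGGATGAAAAAATAGG")
        lengths = [o.nt_length for o in orfs]
        assert lengths == sorted(lengths, reverse=True)


class TestFickett:
    def test_homopolymer_matches_manual_table_walk(self):
        # A*120: position value 40/41 -> lowest bin for every base;
        # content 1.0 for A (top bin), 0.0 for C/G/T (bottom bin):
        # 0.22*0.26 + 0.23*0.18 + 0.08*0.31 + 0.09*0.33
        # + 0.28*0.11 + 0.31*0.12 + 0.29*0.15 + 0.58*0.14 = 0.3458
        assert fickett_score("A" * 120) == pytest.approx(0.3458, abs=1e-9)

    def test_deterministic(self):
        seq = "ACGT" * 30
        assert fickett_score(seq) == fickett_score(seq)

    def test_mostly_ambiguous_sequence_is_undefined(self):
        with pytest.raises(UndefinedResultError):
            fickett_score("N" * 80 + "ACGT" * 5)

    def test_coding_like_scores_above_uniform_random(self):
        rng = _rng(81, 0)
        coding = [make_coding_sequence(rng, 600) for _ in range(200)]
        noncoding = [make_noncoding_sequence(rng, 600) for _ in range(200)]
        mean_c = np.mean([fickett_score(s) for s in coding])
        mean_n = np.mean([fickett_score(s) for s in noncoding])
        assert mean_c > mean_n


class TestHexamer:
    def test_identical_frequency_inputs_give_all_zero_ratios(self):
        f = np.full(4096, 1 / 4096)
        table = train_hexamer_table_from_frequencies(f, f)
        assert np.all(table.log_ratios == 0.0)

    def test_smoothed_coding_distribution_conserves_probability(self):
        rng = _rng(82, 0)
        coding, noncoding = make_training_sets(rng, 30, 30, (300, 600))
        table = train_hexamer_table(coding, noncoding)
        total = np.sum(np.exp(table.log_ratios) * table.f_noncoding)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_planted_codon_bias_tops_the_table(self):
        rng = _rng(83, 0)
        coding = [
            make_coding_sequence(rng, 900, codon_bias_strength=1.0)
            for _ in range(40)
        ]
        noncoding = [make_noncoding_sequence(rng, 900) for _ in range(40)]
        orf_seqs = []
        for s in coding:
            o = longest_orf(s)
            orf_seqs.append(s[o.start : o.end])
        table = train_hexamer_table(orf_seqs, noncoding)
        from epilinc.synthetic_data import PREFERRED_CODONS

        top = set(np.argsort(table.log_ratios)[-100:])
        from epilinc.coding_potential import hexamer_index

        preferred_pairs = {
            hexamer_index(a + b)
            for a in PREFERRED_CODONS
            for b in PREFERRED_CODONS
        }
        # the strongest enrichment must sit on planted-codon pairs
        assert top & preferred_pairs
        assert int(np.argmax(table.log_ratios)) in preferred_pairs

    def test_empty_training_set_raises(self):
        with pytest.raises(TrainingError):
            train_hexamer_table([], ["ACGTGA"])

    def test_no_orf_scores_zero(self, builtin_model):
        table, _model = builtin_model
        assert hexamer_score("CCCCCCCCCCCC", table) == 0.0

    def test_single_hexamer_orf_equals_table_entry(self, builtin_model):
        table, _model = builtin_model
        assert hexamer_score("ATGTAA", table) == pytest.approx(table["ATGTAA"])

    def test_matches_sliding_oracle_on_random_sequences(self, builtin_model):
        table, _model = builtin_model
        rng = np.random.default_rng(84)
        checked = 0
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            orf = longest_orf(seq)
            if orf is None or orf.nt_length < 6:
                assert hexamer_score(seq, table) == 0.0
                continue
            vals = [
                table[seq[i : i + 6]]
                for i in range(orf.start, orf.end - 5, 3)
            ]
            assert hexamer_score(seq, table) == pytest.approx(
                float(np.mean(vals)), rel=1e-12
            )
            checked += 1
        assert checked > 50

    def test_table_save_load_round_trip(self, builtin_model, tmp_path):
        table, _model = builtin_model
        table.save(tmp_path / "hex.tsv")
        back = type(table).load(tmp_path / "hex.tsv")
        assert np.allclose(back.log_ratios, table.log_ratios, rtol=1e-10)


class TestCodingModel:
    def assessments(self, seed, n=60):
        rng = _rng(seed, 0)
        coding, noncoding = make_training_sets(rng, n, n, (400, 900))
        table = train_hexamer_table(
            [s[longest_orf(s).start : longest_orf(s).end] for s in coding],
            noncoding,
        )
        a = [
            compute_assessment(f"t{i}", s, table)
            for i, s in enumerate(coding + noncoding)
        ]
        return a, [1] * n + [0] * n, table

    def test_separable_synthetic_sets_reach_perfect_training_accuracy(self):
        assessments, labels, _ = self.assessments(90)
        model = train_coding_model(assessments, labels)
        from epilinc.coding_potential import feature_vector

        x = np.vstack([feature_vector(a) for a in assessments])
        pred = (model.predict_proba(x) > 0.5).astype(int)
        assert np.array_equal(pred, labels)

    def test_label_shuffle_gives_chance_level_cross_validation(self):
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score
        from epilinc.coding_potential import feature_vector

        assessments, labels, _ = self.assessments(91, n=100)
        rng = np.random.default_rng(92)
        x = np.vstack([feature_vector(a) for a in assessments])
        x = (x - x.mean(0)) / np.where(x.std(0) == 0, 1, x.std(0))
        # single-shuffle CV accuracies are strongly fold-correlated, so
        # average the permutation distribution itself
        accs = []
        for _ in range(30):
            y = np.array(labels)
            rng.shuffle(y)
            accs.append(
                cross_val_score(LogisticRegression(max_iter=2000), x, y, cv=5).mean()
            )
        mean_acc = float(np.mean(accs))
        se = float(np.std(accs, ddof=1) / np.sqrt(len(accs)))
        assert abs(mean_acc - 0.5) <= 3 * max(se, 0.01)

    def test_saved_model_reproduces_probabilities_bit_identically(self, tmp_path):
        assessments, labels, _ = self.assessments(93)
        model = train_coding_model(assessments, labels)
        model.save(tmp_path / "model.json")
        loaded = CodingModel.load(tmp_path / "model.json")
        from epilinc.coding_potential import feature_vector

        x = np.vstack([feature_vector(a) for a in assessments])
        assert np.array_equal(model.predict_proba(x), loaded.predict_proba(x))

    def test_single_class_training_raises(self):
        assessments, _, _ = self.assessments(94, n=10)
        with pytest.raises(TrainingError):
            train_coding_model(assessments, [1] * len(assessments))


class TestFilterCascade:
    def make_assessment(self, tid="t", orf_nt=0, coding_p=0.01, **kw):
        from epilinc.coding_potential import CodingAssessment, OpenReadingFrame

        return CodingAssessment(
            transcript_id=tid,
            longest_orf=OpenReadingFrame(0, orf_nt, 0) if orf_nt else None,
            fickett=0.5,
            hexamer=0.0,
            orf_coverage=0.2,
            coding_probability=coding_p,
            **kw,
        )

    @pytest.mark.parametrize("length", [888, 603, 382])
    def test_printed_transcript_lengths_pass_the_length_criterion(self, length):
        d = apply_filter_cascade(length, self.make_assessment())
        assert d.verdicts["length_gt_200"] == "pass"

    def test_exactly_200_nt_fails_strictly(self):
        d = apply_filter_cascade(200, self.make_assessment())
        assert d.verdicts["length_gt_200"] == "fail"
        assert d.first_failed == "length_gt_200"
        assert not d.overall

    def test_orf_boundary_is_strict(self):
        assert (
            apply_filter_cascade(500, self.make_assessment(orf_nt=399))
            .verdicts["orf_lt_400"]
            == "pass"
        )
        assert (
            apply_filter_cascade(500, self.make_assessment(orf_nt=400))
            .verdicts["orf_lt_400"]
            == "fail"
        )

    def test_no_orf_passes_orf_criterion(self):
        d = apply_filter_cascade(500, self.make_assessment(orf_nt=0))
        assert d.verdicts["orf_lt_400"] == "pass"

    def test_missing_external_scores_are_skipped_not_passed(self):
        d = apply_filter_cascade(500, self.make_assessment())
        assert d.verdicts["pfam_no_match"] == "skipped"
        assert d.verdicts["noncoding_score"] == "skipped"
        assert d.overall  # skipped criteria cannot fail a candidate

    def test_pfam_searched_but_no_hit_passes(self):
        d = apply_filter_cascade(
            500, self.make_assessment(pfam_best_evalue=float("inf"))
        )
        assert d.verdicts["pfam_no_match"] == "pass"
        d2 = apply_filter_cascade(
            500, self.make_assessment(pfam_best_evalue=1e-30)
        )
        assert d2.verdicts["pfam_no_match"] == "fail"

    def test_coding_probability_direction_default_and_literal(self):
        coding_like = self.make_assessment(coding_p=0.9)
        default = apply_filter_cascade(500, coding_like)
        assert default.verdicts["coding_probability"] == "fail"
        literal = apply_filter_cascade(
            500, coding_like, CascadeConfig(cpat_direction="literal")
        )
        assert literal.verdicts["coding_probability"] == "pass"

    def test_flank_verdict_comes_from_caller(self):
        d = apply_filter_cascade(500, self.make_assessment(), flank_pass=False)
        assert d.verdicts["flank_removal"] == "fail"
        assert not d.overall

    def test_all_criteria_reported_even_after_failures(self):
        d = apply_filter_cascade(100, self.make_assessment(orf_nt=402))
        assert set(d.verdicts) == {
            "length_gt_200", "orf_lt_400", "pfam_no_match", "noncoding_score",
            "coding_probability", "flank_removal",
        }
        assert d.first_failed == "length_gt_200"

    def test_insane_threshold_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            CascadeConfig(length_min=-5)

    def test_planted_mrna_fails_orf_and_coding_probability(self, builtin_model):
        table, model = builtin_model
        rng = _rng(95, 0)
        mrna = make_coding_sequence(rng, 900)
        lnc = make_noncoding_sequence(rng, 600)
        d_mrna = apply_filter_cascade(
            len(mrna), compute_assessment("m", mrna, table, model=model),
            flank_pass=True,
        )
        assert d_mrna.verdicts["orf_lt_400"] == "fail"
        assert d_mrna.verdicts["coding_probability"] == "fail"
        d_lnc = apply_filter_cascade(
            len(lnc), compute_assessment("l", lnc, table, model=model),
            flank_pass=True,
        )
        assert d_lnc.overall


class TestCascadeBenchmark:
    def test_sensitivity_and_leakage_on_disjoint_planted_sets(self, builtin_model):
        """Cascade keeps >= 90% of planted lncRNA-like transcripts and
        lets through <= 10% of planted mRNA-like ones, with the model
        trained on a disjoint seeded corpus."""
        table, model = builtin_model
        rng = _rng(96, 0)
        coding, noncoding = make_training_sets(rng, 200, 200, (400, 1500))
        kept_nc = kept_c = 0
        for seqs, counter in ((noncoding, "nc"), (coding, "c")):
            for i, seq in enumerate(seqs):
                a = compute_assessment(f"{counter}{i}", seq, table, model=model)
                d = apply_filter_cascade(len(seq), a, flank_pass=True)
                if d.overall:
                    if counter == "nc":
                        kept_nc += 1
                    else:
                        kept_c += 1
        assert kept_nc / 200 >= 0.9
        assert kept_c / 200 <= 0.1
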