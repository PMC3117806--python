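import itertools
import random
from functools import lru_cache

import pytest

from chemphrase.evaluation import (
    AlignmentScoring,
    AnnotationSpan,
    AnnotatorSet,
    action_name_agreement,
    agreement_matrix,
    align_annotations,
    aligned_agreement,
    dice,
    exact_match,
    filtered_match,
    read_annotations,
    token_dice,
    write_annotations,
)
from chemphrase.samples import ALIGNMENT_ANNOTATOR_A, ALIGNMENT_ANNOTATOR_B


def spans_from(phrases, label="Add", labels=None):
    out, pos = [], 0
    for i, p in enumerate(phrases):
        out.append(
            AnnotationSpan(pos, pos + len(p), p,
                           labels[i] if labels else label)
        )
        pos += len(p) + 1
    return out


def annotator(id_, phrases, **kw):
    return AnnotatorSet(id_, spans_from(phrases, **kw))


class TestDice:
    def test_identical_sets(self):
        x = spans_from(["a b c", "d e"])
        assert dice(x, list(x), exact_match) == 1.0

    def test_disjoint_sets(self):
        x = spans_from(["a b"])
        y = spans_from(["c d"])
        assert dice(x, y, exact_match) == 0.0

    def test_three_vs_two_with_two_matches(self):
        x = spans_from(["heated", "cooled", "stirred"])
        y = spans_from(["heated", "cooled"])
        assert dice(x, y, exact_match) == pytest.approx(0.8)

    def test_both_empty_is_one(self):
        assert dice([], [], exact_match) == 1.0

    def test_one_empty_is_zero(self):
        assert dice(spans_from(["x y"]), [], exact_match) == 0.0

    def test_symmetry_and_range(self):
        rng = random.Random(1)
        vocab = ["stirred", "heated", "cooled", "washed", "dried"]
        for _ in range(50):
            x = spans_from([
                " ".join(rng.choices(vocab, k=rng.randint(1, 3)))
                for _ in range(rng.randint(0, 5))
            ])
            y = spans_from([
                " ".join(rng.choices(vocab, k=rng.randint(1, 3)))
                for _ in range(rng.randint(0, 5))
            ])
            d_xy = dice(x, y, filtered_match)
            d_yx = dice(y, x, filtered_match)
            assert d_xy == pytest.approx(d_yx)
            assert 0.0 <= d_xy <= 1.0


class TestMatchPredicates:
    def test_exact_identity(self):
        a, b = spans_from(["concentrated at 80°C"] * 2)
        assert exact_match(a, b)

    def test_exact_rejects_leading_conjunction(self):
        (a,) = spans_from(["and concentrated at 80°C"])
        (b,) = spans_from(["concentrated at 80°C"])
        assert not exact_match(a, b)

    def test_filtered_accepts_stock_word_differences(self):
        (a,) = spans_from(["and concentrated at 80°C"])
        (b,) = spans_from(["concentrated at 80°C."])
        assert filtered_match(a, b)

    def test_filtered_rejects_different_phrases(self):
        (a,) = spans_from(["heated under reflux"])
        (b,) = spans_from(["cooled to rt"])
        assert not filtered_match(a, b)

    def test_filtered_empty_vs_nonempty(self):
        (a,) = spans_from(["and the"])  # filtered to nothing
        (b,) = spans_from(["heated under reflux"])
        assert not filtered_match(a, b)


def brute_force_best_score(xs, ys, scoring):
    """Exhaustive optimum over all monotone alignments (small instances)."""
    sim = [[scoring.similarity(a, b) for b in ys] for a in xs]

    @lru_cache(maxsize=None)
    def best(i, j):
        if i == len(xs) and j == len(ys):
            return 0.0
        options = []
        if i < len(xs):
            options.append(scoring.gap_penalty + best(i + 1, j))
        if j < len(ys):
            options.append(scoring.gap_penalty + best(i, j + 1))
        if i < len(xs) and j < len(ys):
            options.append(sim[i][j] + best(i + 1, j + 1))
        return max(options)

    return best(0, 0)


class TestAlignment:
    def test_flask_assembly_example(self):
        a = annotator("A", ALIGNMENT_ANNOTATOR_A)
        b = annotator("B", ALIGNMENT_ANNOTATOR_B)
        result = align_annotations(a, b)
        assert result.index_map_a == [1, 2, 3, 4, 5]
        assert result.index_map_b == [1, 2, 3, -1, 4]

    def test_identical_sequences_identity_mapping(self):
        a = annotator("A", ALIGNMENT_ANNOTATOR_B)
        b = annotator("B", ALIGNMENT_ANNOTATOR_B)
        result = align_annotations(a, b)
        n = len(ALIGNMENT_ANNOTATOR_B)
        assert result.index_map_a == list(range(1, n + 1))
        assert result.index_map_b == list(range(1, n + 1))

    def test_empty_side_aligns_to_gaps(self):
        a = annotator("A", ALIGNMENT_ANNOTATOR_A)
        b = AnnotatorSet("B", [])
        result = align_annotations(a, b)
        assert result.index_map_b == [-1] * len(a.spans)
        assert result.pairs == []

    def test_matched_pairs_are_monotone(self):
        rng = random.Random(9)
        vocab = "the was mixture stirred heated cooled washed brine water".split()
        for _ in range(40):
            a = annotator("A", [
                " ".join(rng.choices(vocab, k=rng.randint(2, 6)))
                for _ in range(rng.randint(0, 6))
            ])
            b = annotator("B", [
                " ".join(rng.choices(vocab, k=rng.randint(2, 6)))
                for _ in range(rng.randint(0, 6))
            ])
            result = align_annotations(a, b)
            for (i1, j1, _), (i2, j2, _) in itertools.pairwise(result.pairs):
                assert i1 < i2 and j1 < j2

    def test_optimal_against_brute_force(self):
        rng = random.Random(17)
        vocab = "the was mixture stirred heated cooled washed brine water".split()
        scoring = AlignmentScoring()
        for _ in range(60):
            a = annotator("A", [
                " ".join(rng.choices(vocab, k=rng.randint(2, 6)))
                for _ in range(rng.randint(0, 6))
            ])
            b = annotator("B", [
                " ".join(rng.choices(vocab, k=rng.randint(2, 6)))
                for _ in range(rng.randint(0, 6))
            ])
            result = align_annotations(a, b, scoring)
            expect = brute_force_best_score(
                tuple(a.spans), tuple(b.spans), scoring
            )
            assert result.score == pytest.approx(expect)


class TestAlignedAgreement:
    def test_identical_annotators(self):
        a = annotator("A", ALIGNMENT_ANNOTATOR_A)
        assert aligned_agreement(a, a) == 100.0

    def test_flask_assembly_fragment(self):
        a = annotator("A", ALIGNMENT_ANNOTATOR_A)
        b = annotator("B", ALIGNMENT_ANNOTATOR_B)
        assert aligned_agreement(a, b) == pytest.approx(2 * 4 / 9 * 100)

    def test_one_empty_side(self):
        a = annotator("A", ALIGNMENT_ANNOTATOR_A)
        assert aligned_agreement(a, AnnotatorSet("B", [])) == 0.0


class TestActionNameAgreement:
    def test_all_labels_identical(self):
        a = annotator("A", ALIGNMENT_ANNOTATOR_B, label="Stir")
        b = annotator("B", ALIGNMENT_ANNOTATOR_B, label="Stir")
        assert action_name_agreement(a, b) == 100.0

    def test_half_the_labels_differ(self):
        phrases = ["heated under reflux", "cooled to rt",
                   "washed with brine", "dried under vacuum"]
        a = annotator("A", phrases, labels=["Heat", "Cool", "Wash", "Dry"])
        b = annotator("B", phrases, labels=["Heat", "Cool", "Stir", "Remove"])
        assert action_name_agreement(a, b) == pytest.approx(50.0)

    def test_no_aligned_pairs(self):
        a = annotator("A", ["heated under reflux"])
        b = annotator("B", ["completely unrelated words entirely"])
        assert action_name_agreement(a, b) == 0.0


class TestAgreementMatrix:
    def test_identical_annotators_all_100(self):
        sets = [annotator(f"a{i}", ALIGNMENT_ANNOTATOR_B) for i in range(4)]
        machine = annotator("machine", ALIGNMENT_ANNOTATOR_B)
        report = agreement_matrix(sets, machine, aligned_agreement)
        assert report.machine_annotator_mean == 100.0
        assert report.inter_annotator_mean == 100.0

    def test_matrix_symmetry(self):
        a = annotator("a1", ALIGNMENT_ANNOTATOR_A)
        b = annotator("a2", ALIGNMENT_ANNOTATOR_B)
        machine = annotator("machine", ALIGNMENT_ANNOTATOR_B[:3])
        report = agreement_matrix([a, b], machine, aligned_agreement)
        for i in range(3):
            for j in range(3):
                assert report.matrix[i][j] == report.matrix[j][i]

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            agreement_matrix([annotator("a", ["x y"])], None, aligned_agreement)


class TestAnnotationFiles:
    @pytest.mark.parametrize("suffix", ["tsv", "json"])
    def test_write_read_round_trip(self, tmp_path, suffix):
        original = annotator("A", ALIGNMENT_ANNOTATOR_A)
        path = tmp_path / f"spans.{suffix}"
        write_annotations(original, path)
        loaded = read_annotations(path, "A")
        assert loaded.spans == original.spans


def test_token_dice_on_identical_and_disjoint():
    assert token_dice("heated under reflux", "heated under reflux") == 1.0
    assert token_dice("heated under reflux", "completely different") == 0.0
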