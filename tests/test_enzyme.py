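"""EC parsing/matching, hierarchical scoring, and the association contract."""

import numpy as np
import pytest

from crxnfp.enzyme import (
    AnnotatedReaction,
    AssociationResult,
    ECNumber,
    ECReference,
    EnzymeAssociator,
    Neighbor,
    ec_match,
    load_fluorinated_benchmark,
    score_benchmark_table,
    score_ec_predictions,
)


class TestECNumber:
    @pytest.mark.parametrize(
        "text, depth", [("6.2.1.-", 3), ("3.8.1.3", 4), ("6.2.1", 3), ("1", 1)]
    )
    def test_parse_depth(self, text, depth):
        assert ECNumber.parse(text).depth == depth

    def test_round_trip(self):
        for text in ("6.2.1.-", "3.8.1.3", "1.14.13.25"):
            assert str(ECNumber.parse(text)) == text

    def test_wildcard_then_field_rejected(self):
        with pytest.raises(ValueError):
            ECNumber(fields=(6, None, 1))

    def test_composite_reference_parses_alternatives(self):
        ref = ECReference.parse("3.8.1.3 AND 3.8.1.2")
        assert len(ref.alternatives) == 2
        assert str(ref) == "3.8.1.3 AND 3.8.1.2"


class TestECMatch:
    def test_sibling_serial_matches_to_level_three_only(self):
        pred = ECNumber.parse("3.8.1.3")
        assert ec_match(pred, "3.8.1.2", level=3)
        assert not ec_match(pred, "3.8.1.2", level=4)

    def test_truncated_reference_sets_comparison_depth(self):
        assert ec_match(ECNumber.parse("6.2.1.40"), "6.2.1", level=3)
        assert ec_match(ECNumber.parse("6.2.1.-"), "6.2.1", level=3)

    def test_missing_prediction_never_matches(self):
        for level in (1, 2, 3, 4):
            assert not ec_match(None, "3.5.1", level)

    def test_composite_matches_any_alternative(self):
        pred = ECNumber.parse("3.8.1.3")
        assert ec_match(pred, ECReference.parse("3.8.1.2 AND 3.8.1.3"), level=4)

    def test_shallow_prediction_fails_deeper_levels(self):
        assert ec_match(ECNumber.parse("3.5"), "3.5.1.6", level=2)
        assert not ec_match(ECNumber.parse("3.5"), "3.5.1.6", level=3)

    def test_level_out_of_range(self):
        with pytest.raises(ValueError):
            ec_match(ECNumber.parse("1.1.1.1"), "1.1.1.1", level=5)


class TestScoring:
    def test_all_correct_is_hundred(self):
        rows = [("1.1.1.1", ECNumber.parse("1.1.1.1"))] * 4
        assert score_ec_predictions(rows, level=3) == 100.0

    def test_missing_predictions_count_in_denominator(self):
        rows = [("1.1.1.1", ECNumber.parse("1.1.1.1")), ("2.1.1.1", None)]
        assert score_ec_predictions(rows, level=1) == 50.0

    def test_score_non_increasing_in_level(self):
        df = load_fluorinated_benchmark()
        for column in ("crxnfp", "theia", "claire"):
            accs = [score_benchmark_table(df, column=column, level=l) for l in (1, 2, 3)]
            assert accs[0] >= accs[1] >= accs[2]

    def test_benchmark_has_23_rows_with_two_no_predictions(self):
        df = load_fluorinated_benchmark()
        assert len(df) == 23
        assert int(df["crxnfp"].isna().sum()) == 2  # the two no-analog amides
        assert int(df["theia"].isna().sum()) == 3


def _unit(v):
    return np.asarray(v, dtype=float)


class TestAssociator:
    @pytest.fixture()
    def fitted(self):
        from crxnfp.chem_io import canonicalize_reaction

        embeddings = np.array(
            [[1.0, 0.0, 0.0], [0.8, 0.6, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
        )
        annotations = [
            AnnotatedReaction(
                reaction=canonicalize_reaction("CCO>>CC=O", id=f"REF{i}"),
                ec=ECNumber.parse(ec),
                source_id=f"REF{i}",
            )
            for i, ec in enumerate(("1.1.1.1", "1.1.1.2", "2.3.1.5", "3.5.1.4"))
        ]
        return EnzymeAssociator(k=5, threshold=0.5).fit(embeddings, annotations)

    def test_self_query_ranked_first_with_cosine_one(self, fitted):
        result = fitted.associate_one(_unit([0.0, 1.0, 0.0]), "q")
        assert result.status == "predicted"
        assert result.neighbors[0].source_id == "REF2"
        assert result.neighbors[0].cosine == pytest.approx(1.0)

    def test_threshold_monotonicity(self, fitted):
        q = _unit([0.7, 0.7, 0.1])
        counts = []
        for thr in (0.0, 0.3, 0.5, 0.7, 0.9):
            fitted.set_params(threshold=thr)
            counts.append(len(fitted.associate_one(q).neighbors))
        fitted.set_params(threshold=0.5)
        assert counts == sorted(counts, reverse=True)

    def test_all_below_threshold_gives_no_analog_status(self, fitted):
        result = fitted.associate_one(_unit([-1.0, -0.5, -0.2]), "deet-like")
        assert result.status == "no_analogous_reaction"
        assert EnzymeAssociator.predict_ec(result) is None

    def test_neighbors_sorted_and_above_threshold(self, fitted):
        result = fitted.associate_one(_unit([0.9, 0.5, 0.05]))
        cosines = [n.cosine for n in result.neighbors]
        assert cosines == sorted(cosines, reverse=True)
        assert all(c > 0.5 for c in cosines)

    def test_determinism(self, fitted):
        q = _unit([0.5, 0.5, 0.5])
        r1 = fitted.associate_one(q)
        r2 = fitted.associate_one(q)
        assert [n.source_id for n in r1.neighbors] == [n.source_id for n in r2.neighbors]

    def test_predict_ec_top_hit_and_majority(self):
        neighbors = (
            Neighbor("a", 0.9, ECNumber.parse("1.1.1.1")),
            Neighbor("b", 0.8, ECNumber.parse("2.3.1.5")),
            Neighbor("c", 0.7, ECNumber.parse("2.3.1.6")),
        )
        result = AssociationResult(query_id="q", neighbors=neighbors)
        assert str(EnzymeAssociator.predict_ec(result)) == "1.1.1.1"
        assert str(EnzymeAssociator.predict_ec(result, rule="majority")) == "2.3.1.5"

    def test_empty_reference_is_error(self):
        with pytest.raises(ValueError):
            EnzymeAssociator().fit(np.empty((0, 3)), [])

    def test_unsorted_neighbors_rejected(self):
        with pytest.raises(ValueError):
            AssociationResult(
                query_id="q",
                neighbors=(
                    Neighbor("a", 0.5, ECNumber.parse("1.1")),
                    Neighbor("b", 0.9, ECNumber.parse("1.2")),
                ),
            )
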