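"""Fuzzy cognitive-interaction patterns: degrees, age-banded classification,
calibration curves and the legacy 0-100 convenience score."""

import pytest
from hypothesis import given, strategies as st

from slm import (
    AgeBand,
    AnswerSheet,
    PatternMembership,
    classify_pattern,
    default_interval_table,
    evaluate_differentiation,
    legacy_bowen_score,
    pattern_degree,
    pattern_radar,
)
from slm.bank import PATTERNS

from conftest import answer_all, best_answers, worst_answers


class TestPatternDegree:
    def test_all_best_gives_zero(self, mini_bank):
        sheet = AnswerSheet("r", 30, likert_answers=best_answers(mini_bank))
        for pattern in PATTERNS:
            assert pattern_degree(mini_bank, sheet, pattern) == 0.0

    def test_all_worst_gives_one(self, mini_bank):
        sheet = AnswerSheet("r", 30, likert_answers=worst_answers(mini_bank))
        for pattern in PATTERNS:
            assert pattern_degree(mini_bank, sheet, pattern) == 1.0

    def test_midpoint_answers_give_half(self, mini_bank):
        # Mini bank differentiation questions are negative-keyed: option 2 -> 2/4.
        sheet = AnswerSheet("r", 30, likert_answers=answer_all(mini_bank, 2))
        for pattern in PATTERNS:
            assert pattern_degree(mini_bank, sheet, pattern) == pytest.approx(0.5)

    def test_incomplete_subscale_raises(self, mini_bank):
        answers = answer_all(mini_bank, 2)
        del answers["dif_reaction_01"]
        sheet = AnswerSheet("r", 30, likert_answers=answers)
        with pytest.raises(ValueError) as err:
            pattern_degree(mini_bank, sheet, "reaction")
        assert "dif_reaction_01" in str(err.value)

    def test_unknown_pattern_rejected(self, mini_bank):
        sheet = AnswerSheet("r", 30, likert_answers=answer_all(mini_bank, 2))
        with pytest.raises(ValueError):
            pattern_degree(mini_bank, sheet, "obstinacy")

    def test_calibration_curve_applied(self, mini_bank):
        sheet = AnswerSheet("r", 30, likert_answers=answer_all(mini_bank, 2))
        # Piecewise-linear curve mapping 0.5 -> 0.8.
        curve = [(0.0, 0.0), (0.5, 0.8), (1.0, 1.0)]
        assert pattern_degree(mini_bank, sheet, "adaptation", curve) == pytest.approx(0.8)

    def test_worsening_answer_never_decreases_degree(self, mini_bank):
        base = AnswerSheet("r", 30, likert_answers=answer_all(mini_bank, 1))
        d0 = pattern_degree(mini_bank, base, "creativity")
        worse = dict(base.likert_answers)
        worse["dif_creativity_02"] = 4
        d1 = pattern_degree(mini_bank, AnswerSheet("r", 30, likert_answers=worse), "creativity")
        assert d1 >= d0

    def test_no_normalisation_across_patterns(self, mini_bank):
        """Degrees are simultaneous, not exclusive: all three can be 1."""
        sheet = AnswerSheet("r", 30, likert_answers=worst_answers(mini_bank))
        degrees = [pattern_degree(mini_bank, sheet, p) for p in PATTERNS]
        assert degrees == [1.0, 1.0, 1.0]


class TestClassification:
    @pytest.mark.parametrize(
        "degree,interval,expected",
        [
            (0.9, (0.2, 0.6), "above"),
            (0.4, (0.2, 0.6), "inside"),
            (0.2, (0.2, 0.6), "inside"),
            (0.6, (0.2, 0.6), "inside"),
            (0.1, (0.2, 0.6), "below"),
        ],
    )
    def test_interval_classification(self, degree, interval, expected):
        assert classify_pattern(degree, interval) == expected

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            classify_pattern(0.5, (0.7, 0.2))

    @given(degree=st.floats(0, 1), lo=st.floats(0, 1), hi=st.floats(0, 1))
    def test_classification_partitions_unit_interval(self, degree, lo, hi):
        if lo > hi:
            lo, hi = hi, lo
        label = classify_pattern(degree, (lo, hi))
        assert label in ("below", "inside", "above")
        assert (label == "below") == (degree < lo)
        assert (label == "above") == (degree > hi)


class TestEvaluateDifferentiation:
    def test_extreme_fixture(self, mini_bank):
        answers = best_answers(mini_bank)
        for q in mini_bank.subscale("differentiation", "adaptation"):
            answers[q.id] = max(q.effective_score_map(), key=q.effective_score_map().get)
        for q in mini_bank.subscale("differentiation", "reaction"):
            answers[q.id] = max(q.effective_score_map(), key=q.effective_score_map().get)
        sheet = AnswerSheet("r", 40, likert_answers=answers)
        membership = evaluate_differentiation(mini_bank, sheet)
        assert membership.degrees["adaptation"] == 1.0
        assert membership.classifications["adaptation"] == "above"
        assert membership.classifications["reaction"] == "above"
        assert membership.degrees["creativity"] == 0.0
        assert membership.classifications["creativity"] == "below"

    def test_degrees_are_age_free_but_classification_is_not(self, mini_bank):
        answers = answer_all(mini_bank, 2)  # all degrees 0.5
        young = evaluate_differentiation(mini_bank, AnswerSheet("r", 27, likert_answers=answers))
        old = evaluate_differentiation(mini_bank, AnswerSheet("r", 37, likert_answers=answers))
        assert young.degrees == old.degrees
        assert young.age_band is AgeBand.B25_32
        assert old.age_band is AgeBand.B33_PLUS
        # Default table: creativity 0.5 is inside for 25-32, inside/below shifts with band.
        table = default_interval_table()
        for pattern in PATTERNS:
            lo, hi = table.interval(pattern, AgeBand.B33_PLUS)
            assert old.healthy_interval[pattern] == (lo, hi)

    def test_radar_export_carries_limits(self, mini_bank):
        sheet = AnswerSheet("r", 30, likert_answers=answer_all(mini_bank, 2))
        frame = pattern_radar(evaluate_differentiation(mini_bank, sheet))
        assert list(frame.columns) == ["pattern", "degree", "inferior", "superior"]
        assert len(frame) == 3


class TestIntervalTable:
    def test_default_table_is_complete_and_well_formed(self):
        table = default_interval_table()
        for pattern in PATTERNS:
            for band in AgeBand:
                lo, hi = table.interval(pattern, band)
                assert 0.0 <= lo <= hi <= 1.0

    def test_table_round_trip(self, tmp_path):
        from slm import load_interval_table, save_interval_table

        table = default_interval_table()
        path = tmp_path / "intervals.yaml"
        save_interval_table(table, path)
        assert load_interval_table(path).cells == table.cells

    def test_missing_cell_rejected(self):
        from slm import HealthyIntervalTable

        cells = dict(default_interval_table().cells)
        del cells[("reaction", AgeBand.B8_12)]
        with pytest.raises(ValueError):
            HealthyIntervalTable(cells)


class TestLegacyBowenScore:
    def make(self, adaptation, reaction, creativity):
        return PatternMembership(
            degrees={"adaptation": adaptation, "reaction": reaction, "creativity": creativity},
            age_band=AgeBand.B33_PLUS,
            classifications={p: "inside" for p in PATTERNS},
        )

    @pytest.mark.parametrize(
        "degrees,expected",
        [((0.0, 0.0, 1.0), 100.0), ((1.0, 1.0, 0.0), 0.0), ((0.5, 0.5, 0.5), 50.0)],
    )
    def test_documented_formula(self, degrees, expected):
        assert legacy_bowen_score(self.make(*degrees)) == pytest.approx(expected)

    @given(
        adaptation=st.floats(0, 1),
        reaction=st.floats(0, 1),
        creativity=st.floats(0, 1),
    )
    def test_range_is_exactly_0_100(self, adaptation, reaction, creativity):
        score = legacy_bowen_score(self.make(adaptation, reaction, creativity))
        assert 0.0 <= score <= 100.0
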