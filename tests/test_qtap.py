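"""SRM/MRM absolute quantification, positivity rule, ULQ censoring, folds."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainpk.exceptions import SchemaError
from brainpk.qtap import (
    ExpressionStatus,
    FoldKind,
    ProbeSet,
    ProteinExpression,
    TransitionMeasurement,
    assess_positivity,
    compare_expression_groups,
    compute_loq,
    fold_change,
    quantify_transition,
    summarize_expression,
)
from brainpk.report import format_expression_cell, format_fold


def _tm(area_analyte=1e5, area_is=1e5, is_amount=500.0, protein=33.3, rt=True):
    return TransitionMeasurement(
        "Mdr1a", ProbeSet.MOUSE_SPECIFIC, "Q1Q3-1", "run1",
        area_analyte, area_is, is_amount, protein, rt,
    )


def _expr(level, sem=0.1, group="WT", molecule="Mdr1a"):
    return ProteinExpression(
        molecule, group, ExpressionStatus.EXPRESSED, level=level, sem=sem, n_values=12
    )


def _ulq(loq, group="WT", molecule="Mdr1b"):
    return ProteinExpression(molecule, group, ExpressionStatus.ULQ, loq=loq)


class TestQuantifyTransition:
    def test_hplc_setup_hand_arithmetic(self):
        # ratio 1 with 500 fmol IS over 33.3 ug protein
        assert quantify_transition(_tm()) == pytest.approx(500 / 33.3, rel=1e-12)

    def test_microlc_setup_hand_arithmetic(self):
        m = _tm(area_analyte=1e4, area_is=1e5, is_amount=50.0, protein=6.73)
        assert quantify_transition(m) == pytest.approx(0.1 * 50 / 6.73, rel=1e-12)

    def test_zero_analyte_area(self):
        assert quantify_transition(_tm(area_analyte=0.0)) == 0.0

    def test_zero_is_area_excluded(self):
        assert quantify_transition(_tm(area_is=0.0)) is None

    @given(st.floats(1e2, 1e7), st.floats(0.5, 10.0), st.floats(1.0, 50.0))
    @settings(max_examples=100, derandomize=True)
    def test_linear_in_area_inverse_in_protein(self, area, k, protein):
        base = quantify_transition(_tm(area_analyte=area, protein=protein))
        assert quantify_transition(
            _tm(area_analyte=k * area, protein=protein)
        ) == pytest.approx(k * base, rel=1e-9)
        assert quantify_transition(
            _tm(area_analyte=area, protein=k * protein)
        ) == pytest.approx(base / k, rel=1e-9)


class TestPositivity:
    @pytest.mark.parametrize("n_positive,expressed", [(4, True), (3, True), (2, False), (1, False), (0, False)])
    def test_three_or_four_rule(self, n_positive, expressed):
        sets = [(1.0, True, 0.1)] * n_positive + [(0.01, False, 0.1)] * (4 - n_positive)
        got_expressed, got_count = assess_positivity(sets)
        assert got_expressed is expressed
        assert got_count == n_positive

    def test_rt_mismatch_blocks_positivity(self):
        sets = [(1.0, False, 0.1)] * 4
        assert assess_positivity(sets) == (False, 0)

    def test_wrong_transition_count_is_schema_error(self):
        with pytest.raises(SchemaError, match="4"):
            assess_positivity([(1.0, True, 0.1)] * 5)

    @given(st.lists(st.floats(0, 10), min_size=4, max_size=4), st.floats(0.1, 5))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_amounts(self, amounts, bump):
        """Raising any transition's amount never flips expressed -> ULQ."""
        sets = [(a, True, 1.0) for a in amounts]
        before, _ = assess_positivity(sets)
        for i in range(4):
            raised = list(sets)
            raised[i] = (amounts[i] + bump, True, 1.0)
            after, _ = assess_positivity(raised)
            assert after or not before


class TestSummarize:
    def test_identical_values(self):
        e = summarize_expression("Mdr1a", "WT", [5.0] * 12, 4)
        assert e.level == pytest.approx(5.0)
        assert e.sem == 0.0
        assert e.n_values == 12

    def test_hand_sem(self):
        e = summarize_expression("Mdr1a", "WT", [1.0, 2.0, 3.0, 4.0], 4)
        assert e.level == pytest.approx(2.5)
        sd = math.sqrt(sum((v - 2.5) ** 2 for v in [1, 2, 3, 4]) / 3)
        assert e.sem == pytest.approx(sd / 2)
        assert e.sem == pytest.approx(0.6455, abs=1e-4)

    def test_ulq_report_cell_format(self):
        assert format_expression_cell(_ulq(0.112)) == "U.L.Q.(< 0.112)"


class TestLoq:
    def test_zero_noise_blanks(self):
        per, mol = compute_loq({"t1": [0.0, 0.0, 0.0]})
        assert per["t1"] == 0.0
        assert mol == 0.0

    def test_k_times_sd(self):
        values = [0.0, 1.0, 2.0]  # sd = 1
        per, mol = compute_loq({"t1": values, "t2": [0.0, 2.0, 4.0]}, k_noise=3.0)
        assert per["t1"] == pytest.approx(3.0)
        assert per["t2"] == pytest.approx(6.0)
        assert mol == pytest.approx(3.0)  # min over transitions

    def test_insufficient_blanks_fall_back(self):
        with pytest.warns(UserWarning, match="insufficient blanks"):
            per, _ = compute_loq({"t1": [0.1]}, fallback=0.2)
        assert per["t1"] == 0.2


class TestFoldChange:
    def test_printed_fold_values(self):
        assert fold_change(_expr(22.3), _expr(0.355)).value == pytest.approx(
            62.8, abs=0.05
        )
        assert fold_change(_expr(2.45), _expr(0.355)).value == pytest.approx(
            6.90, abs=0.005
        )
        assert fold_change(_expr(22.3), _expr(2.45)).value == pytest.approx(
            9.10, abs=0.005
        )

    def test_ulq_denominator_is_lower_bound(self):
        fc = fold_change(_expr(0.355), _ulq(0.112))
        assert fc.kind is FoldKind.LOWER_BOUND
        assert fc.value == pytest.approx(0.355 / 0.112)
        assert format_fold(fc).startswith("> ")

    def test_ulq_numerator_is_upper_bound(self):
        fc = fold_change(_ulq(0.112), _expr(0.355))
        assert fc.kind is FoldKind.UPPER_BOUND

    def test_both_ulq_undefined(self):
        fc = fold_change(_ulq(0.136), _ulq(0.134))
        assert fc.kind is FoldKind.UNDEFINED
        assert fc.value is None

    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    @settings(max_examples=100, derandomize=True)
    def test_point_antisymmetry(self, a, b):
        fab = fold_change(_expr(a), _expr(b, group="H"))
        fba = fold_change(_expr(b, group="H"), _expr(a))
        assert fab.value == pytest.approx(1 / fba.value, rel=1e-9)


class TestGroupComparison:
    def test_identical_pools_not_significant(self):
        res = compare_expression_groups("Mdr1a", [1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.testable
        assert not res.significant

    def test_separated_pools_significant(self):
        a = [10.0, 10.5, 9.5, 10.2, 9.8]
        b = [1.0, 1.05, 0.95, 1.02, 0.98]
        res = compare_expression_groups("Mdr1a", a, b)
        assert res.testable and res.significant and res.p < 0.01

    def test_censored_group_not_testable(self):
        res = compare_expression_groups("Mdr1b", None, [1.0, 2.0])
        assert not res.testable
        assert "ULQ" in res.reason
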