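from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from decadd.taxonomy import (
    AdditionType,
    DualAdditionType,
    SingleAddition,
    category_of,
    classify_dual,
    classify_single,
    optimal_sequences,
)

from _oracles import dual_type_by_features, single_type_by_features

POST, SUB, COMP, SUPER = (
    AdditionType.POST,
    AdditionType.SUB,
    AdditionType.COMP,
    AdditionType.SUPER,
)


class TestClassifySingle:
    @pytest.mark.parametrize(
        "augend, addend, expected",
        [(10, 5, POST), (15, 4, SUB), (15, 5, COMP), (15, 6, SUPER)],
    )
    def test_defining_examples(self, augend, addend, expected):
        assert classify_single(augend, addend) is expected

    @pytest.mark.parametrize("addend", range(1, 10))
    def test_zero_augend_is_post_complement(self, addend):
        assert classify_single(0, addend) is POST

    def test_exhaustive_agreement_with_feature_table(self):
        """All 900 (augend 0..99, addend 1..9) cases match the independent
        feature-column oracle; classification is total and unique."""
        for augend in range(100):
            for addend in range(1, 10):
                assert classify_single(augend, addend) is single_type_by_features(
                    augend, addend
                )

    @pytest.mark.parametrize("addend", [0, 10, -3])
    def test_rejects_out_of_range_addend(self, addend):
        with pytest.raises(ValueError):
            classify_single(15, addend)
        with pytest.raises(ValueError):
            SingleAddition(15, addend)

    @settings(derandomize=True, max_examples=200)
    @given(augend=st.integers(0, 10**6), addend=st.integers(1, 9))
    def test_depends_only_on_unit_digit(self, augend, addend):
        assert classify_single(augend, addend) is classify_single(
            augend % 10, addend
        )

    def test_single_addition_derived_fields(self):
        a = SingleAddition(15, 6)
        assert (a.unit, a.sum, a.addition_type) == (5, 21, SUPER)


DUAL_EXAMPLES = [
    # printed example column of the nine-type table
    (10, 4, 5, "1"),
    (10, 4, 6, "2"),
    (10, 4, 7, "3"),
    (15, 1, 2, "4"),
    (15, 2, 3, "5"),
    (15, 5, 4, "6a"),
    (15, 4, 5, "6b"),
    (12, 6, 4, "6c"),
    (14, 6, 4, "6d"),
    (14, 4, 6, "6e"),
    (15, 2, 4, "7"),
    (18, 5, 7, "8"),
    (18, 5, 8, "9"),
]


class TestClassifyDual:
    @pytest.mark.parametrize("augend, a1, a2, label", DUAL_EXAMPLES)
    def test_printed_examples(self, augend, a1, a2, label):
        assert classify_dual(augend, a1, a2).label == label

    def test_exhaustive_agreement_with_feature_table(self):
        """All 720 (u, a1, a2) triples with a1 != a2 match the independent
        feature-row oracle; every triple gets exactly one type."""
        for u in range(10):
            for a1, a2 in itertools.permutations(range(1, 10), 2):
                got = classify_dual(u, a1, a2)
                assert got.label == dual_type_by_features(u, a1, a2)

    def test_symmetry_swaps_only_direct_indirect_subtypes(self):
        swap = {"a": "b", "b": "a", "c": "c", "d": "e", "e": "d", "": ""}
        for u in range(10):
            for a1, a2 in itertools.permutations(range(1, 10), 2):
                t12 = classify_dual(u, a1, a2)
                t21 = classify_dual(u, a2, a1)
                assert t21.type_index == t12.type_index
                assert t21.subtype == swap[t12.subtype]

    def test_equal_addends_are_classifiable_without_pair_subtypes(self):
        # adjacent repetition is never generated, but classification is total;
        # the degenerate a1 == a2 == 5 complement collapses onto the direct
        # subtype, so 6d/6e require distinct addends
        for u in range(10):
            for a in range(1, 10):
                t = classify_dual(u, a, a)
                assert t.subtype not in ("d", "e")
        assert classify_dual(15, 5, 5).label == "6a"

    def test_notation_strings(self):
        assert classify_dual(10, 4, 6).notation == "[-=]"
        assert classify_dual(18, 5, 8).notation == "[>>]"
        assert classify_dual(15, 4, 5).name == "indirect complement"

    def test_subtype_required_exactly_for_type_6(self):
        with pytest.raises(ValueError):
            DualAdditionType(5, "a")
        with pytest.raises(ValueError):
            DualAdditionType(6)


class TestCategoryMapping:
    @pytest.mark.parametrize(
        "type_index, subtype, expected",
        [(2, "", POST), (6, "e", COMP), (8, "", SUPER), (4, "", SUB)],
    )
    def test_category_examples(self, type_index, subtype, expected):
        assert category_of(DualAdditionType(type_index, subtype)) is expected

    def test_category_is_total_and_fixed(self):
        expected = {1: POST, 2: POST, 3: POST, 4: SUB, 5: SUB, 7: SUPER,
                    8: SUPER, 9: SUPER}
        for idx, cat in expected.items():
            assert category_of(DualAdditionType(idx)) is cat
        assert category_of(DualAdditionType(6, "c")) is COMP


class TestOptimalSequences:
    def test_indirect_complement_favours_commuted_order(self):
        plans = optimal_sequences(15, 4, 5)
        assert plans[0].name == "commuted"
        assert [s.step_type for s in plans[0].steps] == [COMP, POST]

    def test_direct_complement_keeps_linear_order(self):
        plans = optimal_sequences(15, 5, 4)
        assert plans[0].name == "linear"
        assert [s.step_type for s in plans[0].steps] == [COMP, POST]

    def test_pair_favours_associative_order(self):
        plans = optimal_sequences(12, 6, 4)
        assert plans[0].name == "associative"
        assert [s.step_type for s in plans[0].steps] == [COMP, POST]

    def test_indifferent_case_returns_linear_first(self):
        plans = optimal_sequences(15, 1, 2)
        assert [p.name for p in plans] == ["linear", "commuted", "associative"]
        assert len({(p.facilitative_steps, p.cost) for p in plans}) == 1

    def test_always_returns_three_legal_plans(self):
        for u in range(10):
            for a1, a2 in itertools.permutations(range(1, 10), 2):
                plans = optimal_sequences(u, a1, a2)
                assert sorted(p.name for p in plans) == [
                    "associative", "commuted", "linear",
                ]
                assert all(len(p.steps) == 2 for p in plans)

    def test_comp_category_iff_some_plan_has_complement_then_post(self):
        """A dual addition is in the complement category exactly when some
        evaluation order contains a complement step on a non-round running
        total immediately followed by a post-complement step."""
        for u in range(10):
            for a1, a2 in itertools.permutations(range(1, 10), 2):
                is_comp = category_of(classify_dual(u, a1, a2)) is COMP
                has_pattern = any(
                    p.steps[0].step_type is COMP
                    and p.steps[0].running_unit > 0
                    and p.steps[1].step_type is POST
                    for p in optimal_sequences(u, a1, a2)
                )
                assert is_comp == has_pattern, (u, a1, a2)
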