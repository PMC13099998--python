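import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raterbench import (
    AnnotationRecord,
    AnnotationTable,
    ConsensusRule,
    SchemaError,
    build_consensus,
    default_panel_config,
    multi_option_consensus,
    simulate_panel,
    single_option_consensus,
)

F = frozenset


@pytest.mark.parametrize(
    "responses, expected",
    [
        (("A", "A", "B"), "A"),  # strict majority
        (("A", "B", "C"), "A"),  # three-way tie -> first occurring
        (("B", "A", "A"), "A"),  # majority beats position
        (("B", "A", "B", "A"), "B"),  # two-way tie -> first occurring
        (("A",), "A"),
    ],
)
def test_single_option_majority_with_first_occurrence_tie_break(responses, expected):
    assert single_option_consensus(responses) == expected


def test_single_option_requires_responses():
    with pytest.raises(ValueError):
        single_option_consensus([])


RULE = ConsensusRule


@pytest.mark.parametrize(
    "sets, rule, expected",
    [
        # support counting at threshold 2
        ((F("ab"), F("ac"), F("a")), RULE("threshold_plus_union"), F("a")),
        # no label reaches support 2 -> union fallback fires
        ((F("ab"), F("c"), F("d")), RULE("threshold_plus_union"), F("abcd")),
        # same case, threshold_only: no fallback, empty result
        ((F("ab"), F("c"), F("d")), RULE("threshold_only"), F()),
        ((F("ab"), F("ac"), F("a")), RULE("union_only"), F("abc")),
        ((F("ab"), F("ac"), F("a")), RULE("intersection_only"), F("a")),
        ((F("ab"), F("ab"), F("b")), RULE("threshold_only"), F("ab")),
    ],
)
def test_multi_option_rules(sets, rule, expected):
    assert multi_option_consensus(sets, rule) == expected


def test_fallback_fires_exactly_when_max_support_is_one():
    rule = RULE("threshold_plus_union")
    no_overlap = (F("a"), F("b"), F("c"))
    assert multi_option_consensus(no_overlap, rule) == F("abc")
    with_overlap = (F("a"), F("ab"), F("c"))
    assert multi_option_consensus(with_overlap, rule) == F("a")


label_sets = st.frozensets(st.sampled_from("abcdef"), min_size=1, max_size=4)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(label_sets, min_size=2, max_size=5))
def test_containment_chain(sets):
    """intersection_only <= threshold_only <= union_only (threshold <= #coders)."""
    inter = multi_option_consensus(sets, RULE("intersection_only"))
    thresh = multi_option_consensus(sets, RULE("threshold_only"))
    union = multi_option_consensus(sets, RULE("union_only"))
    assert inter <= thresh <= union


@settings(max_examples=100, deadline=None, derandomize=True)
@given(label_sets, st.integers(min_value=1, max_value=4))
def test_unanimity_for_every_rule(s, n_coders):
    sets = [s] * n_coders
    for name in ("threshold_plus_union", "union_only", "intersection_only", "threshold_only"):
        rule = RULE(name, threshold=min(2, n_coders))
        assert multi_option_consensus(sets, rule) == s
    assert single_option_consensus(["X"] * n_coders) == "X"


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(label_sets, min_size=1, max_size=4), label_sets)
def test_support_monotonicity(sets, extra):
    """A coder repeating already-present labels never shrinks the threshold consensus."""
    rule = RULE("threshold_plus_union")
    before = multi_option_consensus(sets, rule)
    union = frozenset().union(*sets)
    repeat = extra & union
    if not repeat:
        return
    after_support = multi_option_consensus(list(sets) + [repeat], RULE("threshold_only"))
    before_support = multi_option_consensus(sets, RULE("threshold_only"))
    assert before_support <= after_support


class TestBuildConsensus:
    def test_crowd_consensus_covers_all_items(self):
        table = simulate_panel(default_panel_config(n_items=80, seed=5))
        cons = build_consensus(table, roles=("crowd",))
        for qid in table.schemas:
            n = sum(1 for r in cons.records if r.question_id == qid)
            assert n == 80

    def test_expert_consensus_covers_the_subsample(self):
        table = simulate_panel(default_panel_config(n_items=100, seed=5))
        cons = build_consensus(table, roles=("expert",))
        for qid in table.schemas:
            n = sum(1 for r in cons.records if r.question_id == qid)
            assert n == 40  # coverage 0.4

    def test_unanimous_coders_reproduced_exactly(self, single_schema, multi_schema):
        records = []
        for item, (color, tops) in {
            "i1": ("Red", {"Cheese"}),
            "i2": ("Blue", {"Ham", "Olives"}),
        }.items():
            for rater in ("r1", "r2", "r3"):
                records.append(AnnotationRecord(item, rater, "crowd", "color", color))
                records.append(
                    AnnotationRecord(item, rater, "crowd", "toppings", frozenset(tops))
                )
        table = AnnotationTable(records, [single_schema, multi_schema])
        cons = build_consensus(table, roles=("crowd",))
        assert cons.extract_series("consensus:crowd", "color").responses == (
            table.extract_series("r1", "color").responses
        )
        assert cons.extract_series("consensus:crowd", "toppings").responses == (
            table.extract_series("r1", "toppings").responses
        )

    def test_requested_items_without_responses_error(self, tiny_table):
        with pytest.raises(SchemaError, match="i9"):
            build_consensus(tiny_table, roles=("crowd",), items=["i1", "i9"])

    def test_missing_role_is_an_error(self, tiny_table):
        with pytest.raises(SchemaError, match="no raters"):
            build_consensus(tiny_table, roles=("expert",))
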