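import pytest

from raterbench import (
    AnnotationRecord,
    AnnotationTable,
    QuestionSchema,
    ResponseSeries,
)


@pytest.fixture
def single_schema():
    return QuestionSchema("color", "single", ("Red", "Green", "Blue"))


@pytest.fixture
def multi_schema():
    return QuestionSchema(
        "toppings",
        "multi",
        ("None", "Cheese", "Ham", "Olives", "Basil"),
        none_label="None",
    )


@pytest.fixture
def tiny_table(single_schema, multi_schema):
    """Three items, two raters, both question kinds."""
    records = []
    answers = {
        ("i1", "r1"): ("Red", {"Cheese"}),
        ("i1", "r2"): ("Red", {"Cheese", "Ham"}),
        ("i2", "r1"): ("Green", {"None"}),
        ("i2", "r2"): ("Blue", {"Olives"}),
        ("i3", "r1"): ("Blue", {"Ham", "Olives"}),
        ("i3", "r2"): ("Blue", {"Ham", "Olives"}),
    }
    for (item, rater), (color, tops) in answers.items():
        records.append(AnnotationRecord(item, rater, "crowd", "color", color, "Dutch"))
        records.append(
            AnnotationRecord(item, rater, "crowd", "toppings", frozenset(tops), "Dutch")
        )
    return AnnotationTable(records, [single_schema, multi_schema])


def make_series(question_id, rater_id, responses, items=None):
    items = tuple(items) if items else tuple(f"i{j}" for j in range(len(responses)))
    return ResponseSeries(question_id, rater_id, items, tuple(responses))


@pytest.fixture
def series_factory():
    return make_series
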