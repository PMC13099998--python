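import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raterbench import (
    AnnotationRecord,
    AnnotationTable,
    QuestionSchema,
    default_panel_config,
    gwet_ac1,
    jaccard,
    krippendorff_alpha,
    masi_distance,
    mean_jaccard,
    pairwise_matrix,
    passonneau_distance,
    proportion_agreement,
    simulate_panel,
)
from conftest import make_series

F = frozenset


# ------------------------------------------------------------------ oracles


def alpha_bruteforce(resp_a, resp_b, distance):
    """Two-rater Krippendorff alpha by explicit enumeration of every pooled pair."""
    n = len(resp_a)
    pooled = list(resp_a) + list(resp_b)
    d_o = sum(distance(x, y) for x, y in zip(resp_a, resp_b)) / n
    pair_values = [distance(x, y) for x, y in itertools.combinations(pooled, 2)]
    d_e = sum(pair_values) / len(pair_values)
    if d_e == 0:
        return 1.0
    return 1.0 - d_o / d_e


def nominal_alpha_reference(resp_a, resp_b):
    """Standard two-rater nominal alpha from pooled category frequencies."""
    n = len(resp_a)
    m = 2 * n
    labels = sorted(set(resp_a) | set(resp_b))
    freq = {lab: (list(resp_a) + list(resp_b)).count(lab) for lab in labels}
    d_o = sum(x != y for x, y in zip(resp_a, resp_b)) / n
    # expected disagreement: chance a random pooled pair differs
    d_e = sum(
        freq[a] * freq[b] for a in labels for b in labels if a != b
    ) / (m * (m - 1))
    if d_e == 0:
        return 1.0
    return 1.0 - d_o / d_e


# ------------------------------------------------------------ set distances


@pytest.mark.parametrize(
    "A, B, d_p, d_masi",
    [
        (F("ab"), F("ab"), 0.0, 0.0),  # equal
        (F("a"), F("ab"), 1 / 3, 1 / 6),  # proper subset
        (F("ab"), F("bc"), 2 / 3, 4 / 9),  # overlap, neither subset
        (F("a"), F("b"), 1.0, 1.0),  # disjoint
    ],
)
def test_passonneau_and_masi_canonical_values(A, B, d_p, d_masi):
    assert passonneau_distance(A, B) == pytest.approx(d_p)
    assert masi_distance(A, B) == pytest.approx(d_masi)
    assert passonneau_distance(B, A) == pytest.approx(d_p)
    assert masi_distance(B, A) == pytest.approx(d_masi)


@pytest.mark.parametrize(
    "A, B, expected",
    [(F("ab"), F("ab"), 1.0), (F("a"), F("b"), 0.0), (F("ab"), F("ac"), 1 / 3)],
)
def test_jaccard(A, B, expected):
    assert jaccard(A, B) == pytest.approx(expected)


sets = st.frozensets(st.sampled_from("abcdef"), min_size=1, max_size=4)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(sets, sets)
def test_masi_dominated_by_passonneau_and_symmetric(A, B):
    assert masi_distance(A, B) <= passonneau_distance(A, B) + 1e-12
    assert masi_distance(A, B) == pytest.approx(masi_distance(B, A))
    assert 0.0 <= masi_distance(A, B) <= 1.0
    if A == B:
        assert masi_distance(A, B) == 0.0
    if not (A & B):
        assert masi_distance(A, B) == 1.0


# ----------------------------------------------------------- simple metrics


def test_proportion_agreement_counts_matches():
    a = make_series("q", "a", ["X"] * 8 + ["Y"] * 2)
    b = make_series("q", "b", ["X"] * 8 + ["Z", "Z"])
    res = proportion_agreement(a, b)
    assert res.value == pytest.approx(0.8)
    assert res.details["matches"] == 8
    same = proportion_agreement(a, a)
    assert same.value == 1.0
    disjoint = proportion_agreement(
        make_series("q", "a", ["X"] * 5), make_series("q", "b", ["Y"] * 5)
    )
    assert disjoint.value == 0.0


def test_misaligned_series_rejected():
    a = make_series("q", "a", ["X", "Y"], items=["i1", "i2"])
    b = make_series("q", "b", ["X", "Y"], items=["i2", "i1"])
    with pytest.raises(ValueError, match="aligned"):
        proportion_agreement(a, b)


def test_mean_jaccard_is_arithmetic_mean():
    a = make_series("q", "a", [F("ab"), F("a"), F("ab")])
    b = make_series("q", "b", [F("ab"), F("b"), F("ac")])
    # per-item Jaccard: 1, 0, 1/3
    assert mean_jaccard(a, b).value == pytest.approx(4 / 9)
    assert mean_jaccard(a, a).value == 1.0


# -------------------------------------------------------------- Gwet's AC1


def test_gwet_ac1_worked_example():
    """k=2, n=10: P_o = 0.8, pi_X = 0.8 -> p_e = 0.32, AC1 = 0.48/0.68."""
    schema = QuestionSchema("q", "single", ("X", "Y"))
    a = make_series("q", "a", ["X"] * 8 + ["Y"] * 2)
    # rater 2: X on items 1-7 and 9, Y on 8 and 10
    b_resp = ["X"] * 7 + ["Y", "X", "Y"]
    b = make_series("q", "b", b_resp)
    res = gwet_ac1(a, b, schema)
    assert res.details["P_o"] == pytest.approx(0.8)
    assert res.details["pi"]["X"] == pytest.approx(0.8)
    assert res.details["p_e"] == pytest.approx(0.32)
    assert res.value == pytest.approx(0.48 / 0.68, abs=1e-9)


def test_gwet_ac1_perfect_agreement_is_one():
    schema = QuestionSchema("q", "single", ("X", "Y", "Z"))
    a = make_series("q", "a", ["X", "Y", "Z", "X", "X"])
    assert gwet_ac1(a, a, schema).value == pytest.approx(1.0)


def test_gwet_ac1_uses_full_codebook_for_k():
    """Unused categories still enter k (and hence p_e)."""
    schema3 = QuestionSchema("q", "single", ("X", "Y", "Z"))
    schema2 = QuestionSchema("q", "single", ("X", "Y"))
    a = make_series("q", "a", ["X"] * 6 + ["Y"] * 4)
    b = make_series("q", "b", ["X"] * 5 + ["Y"] * 5)
    v3 = gwet_ac1(a, b, schema3)
    v2 = gwet_ac1(a, b, schema2)
    assert v3.details["k"] == 3
    assert v3.value != pytest.approx(v2.value)


# ------------------------------------------------------ Krippendorff alpha


def test_alpha_identity_and_degenerate_convention():
    a = make_series("q", "a", [F("ab"), F("c"), F("a")])
    assert krippendorff_alpha(a, a, "masi").value == pytest.approx(1.0)
    const = make_series("q", "a", [F("ab")] * 5)
    res = krippendorff_alpha(const, const, "masi")
    assert res.value == 1.0
    assert res.details["degenerate"]


@pytest.mark.parametrize("distance_name, distance_fn", [
    ("masi", masi_distance),
    ("jaccard_distance", lambda A, B: 1 - jaccard(A, B)),
    ("passonneau", passonneau_distance),
])
def test_alpha_matches_bruteforce_enumeration(distance_name, distance_fn):
    """Vectorized alpha equals the explicit all-pairs oracle on random instances."""
    rng = np.random.default_rng(2024)
    labels = list("abcde")
    for _ in range(40):
        n = int(rng.integers(2, 21))
        resp_a = [
            frozenset(rng.choice(labels, size=rng.integers(1, 4), replace=False))
            for _ in range(n)
        ]
        resp_b = [
            frozenset(rng.choice(labels, size=rng.integers(1, 4), replace=False))
            for _ in range(n)
        ]
        a = make_series("q", "a", resp_a)
        b = make_series("q", "b", resp_b)
        got = krippendorff_alpha(a, b, distance_name).value
        want = alpha_bruteforce(resp_a, resp_b, distance_fn)
        assert got == pytest.approx(want, abs=1e-12)


def test_alpha_nominal_reduces_to_standard_nominal_alpha():
    rng = np.random.default_rng(7)
    labels = list("xyz")
    for _ in range(30):
        n = int(rng.integers(2, 25))
        resp_a = [labels[i] for i in rng.integers(0, 3, size=n)]
        resp_b = [labels[i] for i in rng.integers(0, 3, size=n)]
        got = krippendorff_alpha(
            make_series("q", "a", resp_a), make_series("q", "b", resp_b), "nominal"
        ).value
        want = nominal_alpha_reference(resp_a, resp_b)
        assert got == pytest.approx(want, abs=1e-12)


def test_alpha_accepts_custom_callable():
    a = make_series("q", "a", [F("ab"), F("c"), F("a"), F("bc")])
    b = make_series("q", "b", [F("a"), F("c"), F("ab"), F("b")])
    via_name = krippendorff_alpha(a, b, "masi").value
    via_callable = krippendorff_alpha(a, b, masi_distance).value
    assert via_name == pytest.approx(via_callable, abs=1e-12)


def test_alpha_value_reproducible_from_details():
    a = make_series("q", "a", [F("ab"), F("c"), F("a"), F("bc")])
    b = make_series("q", "b", [F("a"), F("c"), F("ab"), F("b")])
    res = krippendorff_alpha(a, b, "masi")
    assert res.value == pytest.approx(
        1 - res.details["D_o"] / res.details["D_e"], abs=1e-12
    )


# ---------------------------------------------------------- pairwise matrix


@pytest.fixture(scope="module")
def panel():
    return simulate_panel(default_panel_config(n_items=100, seed=8))


class TestPairwiseMatrix:
    def test_symmetric_access(self, panel):
        m = pairwise_matrix(panel, "alcohol", raters=["crowd1", "crowd2"])
        assert m.cell("crowd1", "crowd2") == m.cell("crowd2", "crowd1")
        assert m.cell("crowd1", "crowd1")["proportion"].value == 1.0

    def test_expert_model_overlap_is_the_subsample(self, panel):
        m = pairwise_matrix(panel, "alcohol", raters=["expert1", "model_gpt", "crowd1"])
        assert m.overlap[("expert1", "model_gpt")] == 40  # 0.4 x 100
        assert m.overlap[("model_gpt", "crowd1")] == 100

    def test_metrics_follow_question_kind(self, panel):
        single = pairwise_matrix(panel, "alcohol", raters=["crowd1", "crowd2"])
        multi = pairwise_matrix(panel, "premium_offers", raters=["crowd1", "crowd2"])
        assert set(single.cell("crowd1", "crowd2")) == {"proportion", "gwet_ac1"}
        assert set(multi.cell("crowd1", "crowd2")) == {"jaccard_mean", "alpha_masi"}

    def test_empty_overlap_marked_missing(self, single_schema):
        recs = [
            AnnotationRecord("i1", "r1", "crowd", "color", "Red"),
            AnnotationRecord("i2", "r2", "crowd", "color", "Blue"),
        ]
        table = AnnotationTable(recs, [single_schema])
        m = pairwise_matrix(table, "color")
        assert m.cells[("r1", "r2")] is None
        assert m.overlap[("r1", "r2")] == 0

    def test_dataframe_round(self, panel):
        m = pairwise_matrix(panel, "alcohol", raters=["crowd1", "crowd2", "crowd3"])
        df = m.to_dataframe()
        assert set(df.columns) == {"question_id", "rater_a", "rater_b", "metric", "value", "n"}
        assert len(df) == 6 * 2  # 3 diagonal + 3 off-diagonal pairs, 2 metrics
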