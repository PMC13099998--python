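"""Pairwise inter-rater agreement statistics.

Four metrics, matched to the question kind:

* single-option — proportion agreement ``P_o`` and Gwet's AC1, the
  chance-corrected coefficient ``(P_o - p_e) / (1 - p_e)`` with
  ``p_e = (1/(k-1)) * sum_q pi_q (1 - pi_q)``, where ``pi_q`` is the two
  raters' mean usage proportion of category ``q`` over all ``k`` codebook
  categories.  Unlike Cohen's kappa, AC1 stays stable under skewed category
  prevalence (it avoids the kappa paradox).
* multi-option — mean per-item Jaccard similarity, and Krippendorff's alpha
  ``1 - D_o / D_e`` with the MASI set distance
  ``d_MASI(A, B) = d_P(A, B) * (1 - J(A, B))`` where ``d_P`` is Passonneau's
  four-level distance (0 equal, 1/3 subset, 2/3 partial overlap, 1 disjoint).

The two-rater alpha uses the canonical pooled estimator: ``D_o`` is the mean
within-item distance and ``D_e`` the mean distance over all unordered pairs of
the ``2n`` pooled responses.  When every pooled value is identical ``D_e`` is
zero; by convention alpha is then 1, flagged as degenerate.

MASI is not a metric (the triangle inequality can fail); it is a bounded,
symmetric dissimilarity with ``d(A, A) = 0``, which is all alpha requires.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import AnnotationTable, QuestionSchema, ResponseSeries


class DegenerateMetricError(ValueError):
    """The coefficient is undefined on this input (e.g. expected agreement 1)."""


@dataclass(frozen=True)
class AgreementResult:
    """An agreement coefficient plus the intermediates it was computed from."""

    metric: str
    value: float
    n_items: int
    details: dict = field(default_factory=dict)


# ------------------------------------------------------------ set distances


def jaccard(A: frozenset, B: frozenset) -> float:
    """Intersection over union of two label sets."""
    if not A and not B:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(A & B) / len(A | B)


def passonneau_distance(A: frozenset, B: frozenset) -> float:
    """Four-level set distance: 0 equal, 1/3 subset, 2/3 overlap, 1 disjoint."""
    if A == B:
        return 0.0
    if A < B or B < A:
        return 1.0 / 3.0
    if A & B:
        return 2.0 / 3.0
    return 1.0


def masi_distance(A: frozenset, B: frozenset) -> float:
    """Passonneau distance scaled by the Jaccard distance."""
    return passonneau_distance(A, B) * (1.0 - jaccard(A, B))


def nominal_distance(a, b) -> float:
    """0/1 disagreement for single labels (or any hashable values)."""
    return 0.0 if a == b else 1.0


_NAMED_DISTANCES: dict[str, Callable] = {
    "nominal": nominal_distance,
    "masi": masi_distance,
    "jaccard_distance": lambda A, B: 1.0 - jaccard(A, B),
    "passonneau": passonneau_distance,
}


# ------------------------------------------------- vectorized set encoding


def _encode_sets(values: Sequence[frozenset]) -> tuple[np.ndarray, list]:
    """Map label sets to bitmask integers (codebooks up to 64 labels)."""
    vocab: dict[str, int] = {}
    for v in values:
        for lab in v:
            vocab.setdefault(lab, len(vocab))
    if len(vocab) > 64:
        raise ValueError("bitmask encoding supports at most 64 distinct labels")
    masks = np.empty(len(values), dtype=np.uint64)
    for i, v in enumerate(values):
        m = 0
        for lab in v:
            m |= 1 << vocab[lab]
        masks[i] = m
    return masks, list(vocab)


def _set_distance_matrix(masks: np.ndarray, kind: str) -> np.ndarray:
    """Pairwise set distances between bitmask-encoded unique label sets."""
    a = masks[:, None]
    b = masks[None, :]
    inter = np.bitwise_count(a & b).astype(float)
    union = np.bitwise_count(a | b).astype(float)
    size_a = np.bitwise_count(masks).astype(float)
    jac = np.divide(inter, union, out=np.ones_like(inter), where=union > 0)
    if kind == "jaccard_distance":
        return 1.0 - jac
    equal = a == b
    subset = (inter == size_a[:, None]) | (inter == size_a[None, :])
    overlap = inter > 0
    d_p = np.where(equal, 0.0, np.where(subset, 1 / 3, np.where(overlap, 2 / 3, 1.0)))
    if kind == "passonneau":
        return d_p
    return d_p * (1.0 - jac)  # masi


def _distance_matrix(uniques: list, distance) -> np.ndarray:
    """Distance matrix over unique responses; vectorized for named set distances."""
    if isinstance(distance, str):
        kind = distance
        if kind == "nominal" or not isinstance(uniques[0], frozenset):
            D = np.ones((len(uniques), len(uniques)))
            for i, u in enumerate(uniques):
                for j in range(i, len(uniques)):
                    D[i, j] = D[j, i] = 0.0 if u == uniques[j] else 1.0
            return D
        try:
            masks, _ = _encode_sets(uniques)
            return _set_distance_matrix(masks, kind)
        except ValueError:
            distance = _NAMED_DISTANCES[kind]
    m = len(uniques)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = distance(uniques[i], uniques[j])
    return D


def _check_aligned(a: ResponseSeries, b: ResponseSeries) -> int:
    if a.items != b.items:
        raise ValueError(
            f"series are not item-aligned ({a.rater_id!r} vs {b.rater_id!r})"
        )
    if len(a) == 0:
        raise ValueError("empty series")
    return len(a)


# ---------------------------------------------------------- simple metrics


def proportion_agreement(a: ResponseSeries, b: ResponseSeries) -> AgreementResult:
    """Fraction of items on which two raters give the identical response."""
    n = _check_aligned(a, b)
    matches = sum(x == y for x, y in zip(a.responses, b.responses))
    return AgreementResult(
        "proportion", matches / n, n, details={"matches": matches, "P_o": matches / n}
    )


def mean_jaccard(a: ResponseSeries, b: ResponseSeries) -> AgreementResult:
    """Arithmetic mean of per-item Jaccard similarity between label sets."""
    n = _check_aligned(a, b)
    values = [jaccard(x, y) for x, y in zip(a.responses, b.responses)]
    return AgreementResult("jaccard_mean", float(np.mean(values)), n, details={})


def gwet_ac1(
    a: ResponseSeries, b: ResponseSeries, schema: QuestionSchema
) -> AgreementResult:
    """Gwet's AC1 chance-corrected agreement for single-option data."""
    n = _check_aligned(a, b)
    k = schema.k
    p_o = sum(x == y for x, y in zip(a.responses, b.responses)) / n
    pi = {}
    for q in schema.codebook:
        pa = sum(x == q for x in a.responses) / n
        pb = sum(x == q for x in b.responses) / n
        pi[q] = (pa + pb) / 2.0
    p_e = sum(p * (1 - p) for p in pi.values()) / (k - 1)
    if p_e >= 1.0 - 1e-15:
        raise DegenerateMetricError(
            f"AC1 undefined: chance agreement p_e = {p_e} (category proportions {pi})"
        )
    value = (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(
        "gwet_ac1", value, n, details={"P_o": p_o, "p_e": p_e, "pi": pi, "k": k}
    )


# ------------------------------------------------------- Krippendorff alpha


def _alpha_core(
    resp_a: Sequence, resp_b: Sequence, distance
) -> tuple[float, float, float, bool]:
    """(alpha, D_o, D_e, degenerate) for two aligned response vectors.

    Pools the 2n responses, reduces to unique values with counts, and uses
    the distance matrix among uniques: with counts ``c`` and matrix ``D``
    (zero diagonal), the sum over unordered pooled pairs is ``c' D c / 2``.
    """
    n = len(resp_a)
    pooled = list(resp_a) + list(resp_b)
    uniq: dict = {}
    codes = np.empty(2 * n, dtype=np.intp)
    for i, v in enumerate(pooled):
        codes[i] = uniq.setdefault(v, len(uniq))
    uniques = list(uniq)
    if len(uniques) == 1:
        return 1.0, 0.0, 0.0, True
    D = _distance_matrix(uniques, distance)
    counts = np.bincount(codes, minlength=len(uniques)).astype(float)
    m = 2 * n
    pair_sum = counts @ D @ counts / 2.0  # diagonal of D is 0
    D_e = pair_sum / (m * (m - 1) / 2.0)
    D_o = float(np.mean(D[codes[:n], codes[n:]]))
    if D_e <= 0.0:
        return 1.0, D_o, D_e, True
    return 1.0 - D_o / D_e, D_o, D_e, False


def krippendorff_alpha(
    a: ResponseSeries,
    b: ResponseSeries,
    distance: str | Callable = "masi",
) -> AgreementResult:
    """Two-rater Krippendorff alpha under an arbitrary response distance.

    ``distance`` may be ``"nominal"``, ``"masi"``, ``"jaccard_distance"``,
    ``"passonneau"`` or any symmetric callable with ``d(x, x) = 0``.  With the
    nominal distance on single-option data this is standard nominal alpha.
    """
    n = _check_aligned(a, b)
    name = distance if isinstance(distance, str) else getattr(distance, "__name__", "custom")
    alpha, d_o, d_e, degenerate = _alpha_core(a.responses, b.responses, distance)
    metric = "alpha_masi" if name == "masi" else f"alpha_{name}"
    return AgreementResult(
        metric,
        alpha,
        n,
        details={"D_o": d_o, "D_e": d_e, "distance": name, "degenerate": degenerate},
    )


# -------------------------------------------------------- all-pairs matrix


@dataclass
class PairwiseMatrix:
    """Agreement results for every rater pair on one question."""

    question_id: str
    raters: tuple
    cells: dict  # (rater_a, rater_b) -> {metric: AgreementResult}
    overlap: dict  # (rater_a, rater_b) -> shared item count

    def cell(self, a: str, b: str) -> dict:
        key = (a, b) if (a, b) in self.cells else (b, a)
        return self.cells[key]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (ra, rb), metrics in sorted(self.cells.items()):
            for metric, res in metrics.items():
                rows.append(
                    {
                        "question_id": self.question_id,
                        "rater_a": ra,
                        "rater_b": rb,
                        "metric": metric,
                        "value": res.value,
                        "n": res.n_items,
                    }
                )
        return pd.DataFrame(rows, columns=["question_id", "rater_a", "rater_b", "metric", "value", "n"])


def metrics_for_kind(kind: str) -> tuple[str, ...]:
    """The headline metric pair per question kind."""
    return ("proportion", "gwet_ac1") if kind == "single" else ("jaccard_mean", "alpha_masi")


def compute_metric(
    metric: str, a: ResponseSeries, b: ResponseSeries, schema: QuestionSchema
) -> AgreementResult:
    if metric == "proportion":
        return proportion_agreement(a, b)
    if metric == "gwet_ac1":
        return gwet_ac1(a, b, schema)
    if metric == "jaccard_mean":
        return mean_jaccard(a, b)
    if metric == "alpha_masi":
        return krippendorff_alpha(a, b, "masi")
    if metric == "alpha_nominal":
        return krippendorff_alpha(a, b, "nominal")
    raise ValueError(f"unknown metric {metric!r}")


def pairwise_matrix(
    table: AnnotationTable,
    question_id: str,
    raters: Sequence[str] | None = None,
    metrics: Sequence[str] | None = None,
) -> PairwiseMatrix:
    """All-pairs agreement on one question.

    Each pair's metrics are computed on the intersection of the two raters'
    item sets (so an expert x model pair is scored on the expert subsample);
    pairs with empty overlap get a missing cell, never a zero.
    """
    schema = table.schemas[question_id]
    if raters is None:
        raters = [r for r in table.raters() if table.rater_items(r, question_id)]
    if metrics is None:
        metrics = metrics_for_kind(schema.kind)
    item_sets = {r: table.rater_items(r, question_id) for r in raters}
    cells: dict = {}
    overlap: dict = {}
    for i, ra in enumerate(raters):
        for rb in raters[i:]:
            shared = [it for it in item_sets[ra] if it in set(item_sets[rb])]
            overlap[(ra, rb)] = len(shared)
            if not shared:
                cells[(ra, rb)] = None
                continue
            sa = table.extract_series(ra, question_id, shared)
            sb = table.extract_series(rb, question_id, shared)
            cells[(ra, rb)] = {m: compute_metric(m, sa, sb, schema) for m in metrics}
    return PairwiseMatrix(question_id, tuple(raters), cells, overlap)
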