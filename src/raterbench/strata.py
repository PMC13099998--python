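"""Stratum-wise agreement comparison (e.g. Dutch vs. French ads).

For a rater pair, the agreement metric is computed within each of two item
strata; the delta (stratum A minus stratum B) is tested against a
stratum-permutation null: stratum labels are shuffled across the pair's
overlap items, preserving the two group sizes, and the delta recomputed.
The two-sided p-value uses add-one smoothing, p = (1 + #{|null| >= |obs|}) /
(P + 1), so it never reaches exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import DegenerateMetricError, compute_metric
from .schema import AnnotationTable, ResponseSeries


@dataclass(frozen=True)
class StratifiedDelta:
    question_id: str
    rater_a: str
    rater_b: str
    metric: str
    stratum_a: str
    stratum_b: str
    value_a: float
    value_b: float
    delta: float
    p_delta: float
    n_a: int
    n_b: int
    permutations: int


def _metric_on(metric, sa: ResponseSeries, sb: ResponseSeries, schema, idx) -> float:
    items = tuple(sa.items[i] for i in idx)
    a = ResponseSeries(sa.question_id, sa.rater_id, items, tuple(sa.responses[i] for i in idx))
    b = ResponseSeries(sb.question_id, sb.rater_id, items, tuple(sb.responses[i] for i in idx))
    return compute_metric(metric, a, b, schema).value


def stratified_delta(
    table: AnnotationTable,
    question_id: str,
    rater_a: str,
    rater_b: str,
    stratum_a: str,
    stratum_b: str,
    metric: str,
    permutations: int = 500,
    seed: int = 0,
) -> StratifiedDelta:
    """Between-stratum agreement delta with a permutation p-value."""
    schema = table.schemas[question_id]
    items_a = table.rater_items(rater_a, question_id)
    items_b = set(table.rater_items(rater_b, question_id))
    shared = [it for it in items_a if it in items_b]
    strata = table.strata()
    idx_a = [i for i, it in enumerate(shared) if strata.get(it) == stratum_a]
    idx_b = [i for i, it in enumerate(shared) if strata.get(it) == stratum_b]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError(
            f"need >= 2 items per stratum, got {len(idx_a)} ({stratum_a!r}) "
            f"and {len(idx_b)} ({stratum_b!r})"
        )
    sa = table.extract_series(rater_a, question_id, shared)
    sb = table.extract_series(rater_b, question_id, shared)

    value_a = _metric_on(metric, sa, sb, schema, idx_a)
    value_b = _metric_on(metric, sa, sb, schema, idx_b)
    observed = value_a - value_b

    # the null is built in a canonical stratum order so that swapping the two
    # strata negates the delta but leaves the p-value unchanged
    first, second = sorted([(stratum_a, idx_a), (stratum_b, idx_b)])
    rng = np.random.default_rng(seed)
    pool = np.asarray(sorted(first[1] + second[1]))
    n_first = len(first[1])
    exceed = 0
    valid = 0
    for _ in range(permutations):
        perm = rng.permutation(pool)
        try:
            d = _metric_on(metric, sa, sb, schema, perm[:n_first]) - _metric_on(
                metric, sa, sb, schema, perm[n_first:]
            )
        except DegenerateMetricError:
            continue
        valid += 1
        if abs(d) >= abs(observed) - 1e-15:
            exceed += 1
    p = (1 + exceed) / (valid + 1)
    return StratifiedDelta(
        question_id=question_id,
        rater_a=rater_a,
        rater_b=rater_b,
        metric=metric,
        stratum_a=stratum_a,
        stratum_b=stratum_b,
        value_a=value_a,
        value_b=value_b,
        delta=observed,
        p_delta=p,
        n_a=len(idx_a),
        n_b=len(idx_b),
        permutations=permutations,
    )
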