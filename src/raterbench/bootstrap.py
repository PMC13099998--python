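"""Bootstrap exchangeability: is a model's agreement within expert range?

Each iteration resamples the common item set with replacement — the *same*
resample for every rater, so the within-iteration comparison is meaningful —
and computes each rater's agreement with the (fixed) consensus: Gwet's AC1
for single-option questions, Krippendorff's alpha with MASI distance for
multi-option questions.  The *in-range proportion* is the fraction of
iterations in which the model's coefficient lies inside the min-max envelope
of the individual experts' coefficients; values near 1 are evidence that the
model is statistically exchangeable with an expert coder.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .metrics import DegenerateMetricError, metrics_for_kind
from .schema import AnnotationTable


@dataclass
class BootstrapResult:
    question_id: str
    metric: str
    B: int
    seed: int
    model_id: str
    expert_ids: tuple
    model_coefficients: np.ndarray  # NaN where the iteration was degenerate
    expert_coefficients: dict  # expert_id -> np.ndarray
    in_range: np.ndarray  # boolean, NaN-iterations excluded
    n_missing: int

    @property
    def in_range_proportion(self) -> float:
        return float(np.mean(self.in_range)) if len(self.in_range) else float("nan")

    @property
    def model_median(self) -> float:
        return float(np.nanmedian(self.model_coefficients))

    def model_ci(self, level: float = 95.0) -> tuple[float, float]:
        lo = (100.0 - level) / 2.0
        vals = self.model_coefficients[~np.isnan(self.model_coefficients)]
        return float(np.percentile(vals, lo)), float(np.percentile(vals, 100.0 - lo))


def _ac1_arrays(xa: np.ndarray, xb: np.ndarray, k: int) -> float:
    """AC1 from integer-coded single-option responses (codes 0..k-1)."""
    n = len(xa)
    p_o = float(np.mean(xa == xb))
    ca = np.bincount(xa, minlength=k) / n
    cb = np.bincount(xb, minlength=k) / n
    pi = (ca + cb) / 2.0
    p_e = float(np.sum(pi * (1.0 - pi))) / (k - 1)
    if p_e >= 1.0 - 1e-15:
        raise DegenerateMetricError("AC1 undefined: p_e == 1")
    return (p_o - p_e) / (1.0 - p_e)


def _alpha_codes(code_a: np.ndarray, code_b: np.ndarray, D: np.ndarray) -> float:
    """Alpha from unique-value codes and a precomputed distance matrix."""
    n = len(code_a)
    m = 2 * n
    counts = np.bincount(code_a, minlength=D.shape[0]).astype(float)
    counts += np.bincount(code_b, minlength=D.shape[0])
    pair_sum = counts @ D @ counts / 2.0
    D_e = pair_sum / (m * (m - 1) / 2.0)
    D_o = float(np.mean(D[code_a, code_b]))
    if D_e <= 0.0:
        raise DegenerateMetricError("alpha undefined: all pooled values identical")
    return 1.0 - D_o / D_e


def bootstrap_exchangeability(
    table: AnnotationTable,
    question_id: str,
    model_id: str,
    expert_ids: Sequence[str],
    consensus_id: str,
    metric: str | None = None,
    B: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Run the Monte-Carlo in-range analysis for one model on one question.

    All raters must cover a common item set (typically the expert subsample).
    ``metric`` defaults to the question kind's chance-corrected coefficient.
    Degenerate iterations (undefined coefficient for any rater) are recorded
    as missing and excluded from the summaries.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    schema = table.schemas[question_id]
    if metric is None:
        metric = metrics_for_kind(schema.kind)[1]
    raters = [model_id, *expert_ids]
    item_sets = [set(table.rater_items(r, question_id)) for r in raters + [consensus_id]]
    common = set.intersection(*item_sets)
    if not common:
        raise ValueError("raters share no common items")
    items = [it for it in table.rater_items(consensus_id, question_id) if it in common]
    n = len(items)

    series = {r: table.extract_series(r, question_id, items) for r in raters}
    consensus = table.extract_series(consensus_id, question_id, items)

    if metric == "gwet_ac1":
        code = {lab: i for i, lab in enumerate(schema.codebook)}
        enc = {r: np.array([code[v] for v in series[r].responses]) for r in raters}
        enc_c = np.array([code[v] for v in consensus.responses])

        def coefficient(r: str, idx: np.ndarray) -> float:
            return _ac1_arrays(enc[r][idx], enc_c[idx], schema.k)

    elif metric in ("alpha_masi", "alpha_nominal"):
        from .metrics import _distance_matrix

        uniq: dict = {}
        all_vals = [v for r in raters for v in series[r].responses] + list(consensus.responses)
        for v in all_vals:
            uniq.setdefault(v, len(uniq))
        dist_name = "masi" if metric == "alpha_masi" else "nominal"
        D = _distance_matrix(list(uniq), dist_name)
        enc = {r: np.array([uniq[v] for v in series[r].responses]) for r in raters}
        enc_c = np.array([uniq[v] for v in consensus.responses])

        def coefficient(r: str, idx: np.ndarray) -> float:
            return _alpha_codes(enc[r][idx], enc_c[idx], D)

    else:
        raise ValueError(f"unsupported bootstrap metric {metric!r}")

    rng = np.random.default_rng(seed)
    model_coef = np.full(B, np.nan)
    expert_coef = {e: np.full(B, np.nan) for e in expert_ids}
    in_range = []
    n_missing = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            mc = coefficient(model_id, idx)
            ecs = [coefficient(e, idx) for e in expert_ids]
        except DegenerateMetricError:
            n_missing += 1
            continue
        model_coef[b] = mc
        for e, v in zip(expert_ids, ecs):
            expert_coef[e][b] = v
        in_range.append(min(ecs) <= mc <= max(ecs))
    return BootstrapResult(
        question_id=question_id,
        metric=metric,
        B=B,
        seed=seed,
        model_id=model_id,
        expert_ids=tuple(expert_ids),
        model_coefficients=model_coef,
        expert_coefficients=expert_coef,
        in_range=np.asarray(in_range, dtype=bool),
        n_missing=n_missing,
    )
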