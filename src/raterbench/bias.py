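"""Label-level option-bias diagnostics: model vs. human reference consensus.

For each label the *option bias* is the difference in selection rates
``rate_model - rate_reference`` over the items both cover.  Positive values
mean the model over-detects the label relative to the human benchmark,
negative values under-detection.  Significance comes from a two-tailed
two-proportion pooled z-test by default (a paired McNemar-style variant on
the discordant items is available), starred at p < .05 / .01 / .001.

Labels that were only offered to human coders (an ``"Other"`` option, say)
are excluded from the model bias table via the schema's ``ai_excluded`` set.
Raw p-values drive the stars; Benjamini-Hochberg adjusted p-values are
reported alongside for users who want familywise control.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .schema import AnnotationTable, ResponseSeries, SchemaError


@dataclass(frozen=True)
class BiasEstimate:
    question_id: str
    label: str
    model_id: str
    n: int
    rate_model: float
    rate_reference: float
    delta: float
    z: float
    p: float
    stars: str
    reference_support: int
    degenerate: bool = False


def stars_for(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _contains(response, label: str) -> bool:
    if isinstance(response, frozenset):
        return label in response
    return response == label


def selection_rate(series: ResponseSeries, label: str) -> float:
    """Fraction of items whose response contains (or equals) the label."""
    if len(series) == 0:
        raise ValueError("empty series")
    return sum(_contains(r, label) for r in series.responses) / len(series)


def option_bias(
    model: ResponseSeries,
    reference: ResponseSeries,
    label: str,
    paired: bool = False,
    model_id: str | None = None,
) -> BiasEstimate:
    """Selection-rate delta for one label with a two-tailed z-test.

    Unpaired (default): pooled two-proportion z treating the two rates as
    independent binomials over n items each.  Paired: McNemar-style z on the
    discordant item counts, sharper when the same items underlie both series.
    """
    if model.items != reference.items:
        raise ValueError("model and reference series are not item-aligned")
    n = len(model.items)
    sel_m = np.array([_contains(r, label) for r in model.responses], dtype=bool)
    sel_r = np.array([_contains(r, label) for r in reference.responses], dtype=bool)
    rate_m = sel_m.mean()
    rate_r = sel_r.mean()
    delta = float(rate_m - rate_r)
    degenerate = False
    if paired:
        b = int((sel_m & ~sel_r).sum())
        c = int((~sel_m & sel_r).sum())
        if b + c == 0:
            z, p, degenerate = 0.0, 1.0, True
        else:
            z = (b - c) / np.sqrt(b + c)
            p = 2.0 * stats.norm.sf(abs(z))
    else:
        pooled = (sel_m.sum() + sel_r.sum()) / (2.0 * n)
        var = pooled * (1.0 - pooled) * (2.0 / n)
        if var <= 0.0:
            z, p, degenerate = float("nan"), 1.0, True
        else:
            z = delta / np.sqrt(var)
            p = 2.0 * stats.norm.sf(abs(z))
    return BiasEstimate(
        question_id=model.question_id,
        label=label,
        model_id=model_id or model.rater_id,
        n=n,
        rate_model=float(rate_m),
        rate_reference=float(rate_r),
        delta=delta,
        z=float(z),
        p=float(p),
        stars=stars_for(p),
        reference_support=int(sel_r.sum()),
        degenerate=degenerate,
    )


def bias_table(
    table: AnnotationTable,
    model_ids: Sequence[str],
    reference_id: str,
    question_id: str,
    paired: bool = False,
) -> list[BiasEstimate]:
    """One bias estimate per (model, label), excluding AI-excluded labels.

    Each estimate is computed on the intersection of the model's and the
    reference rater's item sets.  ``reference_support`` counts the items on
    which the reference selected the label.
    """
    schema = table.schemas[question_id]
    ref_items = table.rater_items(reference_id, question_id)
    if not ref_items:
        raise SchemaError(f"reference rater {reference_id!r} has no records on {question_id!r}")
    labels = [c for c in schema.codebook if c not in schema.ai_excluded]
    out: list[BiasEstimate] = []
    for mid in model_ids:
        m_items = set(table.rater_items(mid, question_id))
        shared = [it for it in ref_items if it in m_items]
        if not shared:
            raise SchemaError(f"model {mid!r} shares no items with reference on {question_id!r}")
        model_series = table.extract_series(mid, question_id, shared)
        ref_series = table.extract_series(reference_id, question_id, shared)
        for label in labels:
            out.append(
                option_bias(model_series, ref_series, label, paired=paired, model_id=mid)
            )
    return out


def bias_frame(estimates: Sequence[BiasEstimate]) -> pd.DataFrame:
    """Tabular view with a BH-adjusted p column (``p_bh``) per model family."""
    df = pd.DataFrame([e.__dict__ for e in estimates])
    if df.empty:
        return df
    df["p_bh"] = np.nan
    for mid, idx in df.groupby("model_id").groups.items():
        df.loc[idx, "p_bh"] = multipletests(df.loc[idx, "p"], method="fdr_bh")[1]
    return df
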