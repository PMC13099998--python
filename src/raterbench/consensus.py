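"""Consensus (reference) labels from multiple human coders.

Single-option questions use majority vote with a first-occurrence tie-break:
among labels tied for the top count, the one appearing earliest in the coder
order wins.  Multi-option questions use a support threshold (default: chosen
by at least 2 coders) with a union fallback when no label reaches it; the
sensitivity variants union-only, intersection-only and threshold-only apply
the plain set operation, threshold-only deliberately returning the empty set
when no label has enough support.

The coder order that drives the tie-break is ascending rater_id, fixed before
any analysis.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Sequence
from dataclasses import dataclass

from .schema import (
    AnnotationRecord,
    AnnotationTable,
    Label,
    SchemaError,
)

SET_RULES = ("threshold_plus_union", "union_only", "intersection_only", "threshold_only")
SINGLE_RULES = ("majority_first_tie",)


@dataclass(frozen=True)
class ConsensusRule:
    name: str
    threshold: int = 2

    def __post_init__(self) -> None:
        if self.name not in SET_RULES + SINGLE_RULES:
            raise ValueError(f"unknown consensus rule {self.name!r}")
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")


def single_option_consensus(responses: Sequence[Label]) -> Label:
    """Majority vote; ties go to the label occurring first in coder order."""
    if not responses:
        raise ValueError("no responses to aggregate")
    counts = Counter(responses)
    top = max(counts.values())
    for label in responses:  # coder order
        if counts[label] == top:
            return label
    raise AssertionError("unreachable")


def multi_option_consensus(
    responses: Sequence[frozenset], rule: ConsensusRule
) -> frozenset:
    """Aggregate label sets under the given rule.

    ``threshold_plus_union`` falls back to the union of all coders' labels
    when no label reaches the support threshold; ``threshold_only`` does not
    and may return the empty set.
    """
    if not responses:
        raise ValueError("no responses to aggregate")
    if rule.name not in SET_RULES:
        raise ValueError(f"rule {rule.name!r} does not apply to multi-option questions")
    union = frozenset().union(*responses)
    if rule.name == "union_only":
        return union
    if rule.name == "intersection_only":
        out = responses[0]
        for r in responses[1:]:
            out = out & r
        return frozenset(out)
    support = Counter()
    for r in responses:
        support.update(set(r))
    meets = frozenset(lab for lab, c in support.items() if c >= rule.threshold)
    if rule.name == "threshold_only":
        return meets
    return meets if meets else union  # threshold_plus_union


DEFAULT_RULES = {
    "single": ConsensusRule("majority_first_tie"),
    "multi": ConsensusRule("threshold_plus_union", threshold=2),
}


def build_consensus(
    table: AnnotationTable,
    roles: Sequence[str] = ("crowd",),
    rules: dict | None = None,
    rater_id: str | None = None,
    items: Sequence[str] | None = None,
) -> AnnotationTable:
    """Derive one consensus record per (item, question) from the given roles.

    Returns a new table containing only the consensus records (role
    ``"consensus"``, rater id ``"consensus:<roles>"`` unless overridden).
    Coders are ordered by ascending rater_id for the tie-break.  By default
    consensus covers every item at least one eligible coder annotated; an
    explicit ``items`` list makes gaps an error instead.
    """
    rules = {**DEFAULT_RULES, **(rules or {})}
    roles = tuple(roles)
    cid = rater_id or ("consensus:" + "+".join(roles))
    eligible = sorted(
        {rec.rater_id for rec in table.records if rec.role in roles}
    )
    if not eligible:
        raise SchemaError(f"no raters with role(s) {roles}")

    out: list[AnnotationRecord] = []
    strata = table.strata()
    for schema in table.schemas.values():
        qid = schema.question_id
        per_item: dict[str, list] = {}
        for rid in eligible:  # ascending rater order
            for item in table.rater_items(rid, qid):
                per_item.setdefault(item, []).append(
                    table.get(item, rid, qid).response
                )
        if not per_item and items is None:
            continue
        rule = rules[schema.kind]
        wanted = [str(i) for i in items] if items is not None else table.items()
        if items is not None:
            gaps = [i for i in wanted if i not in per_item]
            if gaps:
                raise SchemaError(
                    f"{qid}: no response from role(s) {roles} for item(s) "
                    f"{gaps[:10]}{'...' if len(gaps) > 10 else ''}"
                )
        for item in wanted:
            if item not in per_item:
                continue
            responses = per_item[item]
            if schema.kind == "single":
                value = single_option_consensus(responses)
            else:
                value = multi_option_consensus(responses, rule)
                if not value:
                    # threshold_only with no supported label: skip the record,
                    # empty sets are not representable as responses
                    continue
            out.append(
                AnnotationRecord(
                    item_id=item,
                    rater_id=cid,
                    role="consensus",
                    question_id=qid,
                    response=value,
                    stratum=strata.get(item),
                )
            )
    return AnnotationTable(out, table.schemas.values())
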