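"""Synthetic annotation panels with latent truth and noisy raters.

The generator emulates the structure of a dual-benchmark ad-annotation study:
~1000 items coded by 3 crowd workers each, a fixed 400-item subsample coded by
3 experts, and 4 model raters covering everything; six questions (three
single-option, three multi-option) with skewed label prevalence and sparse
label sets; a per-item language stratum.

Every rater is an independent-noise channel over a latent truth: single-option
raters confuse the true label with probability ``epsilon_single`` (uniform over
the wrong labels); multi-option raters drop each true label with probability
``epsilon_miss`` and add each absent label with probability ``epsilon_add``
plus a per-label bias offset — the mechanism that produces over-/under-detected
labels downstream.  Empty multi-label results fall back to the question's
explicit none label, so responses are never empty sets.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .schema import (
    AnnotationRecord,
    AnnotationTable,
    QuestionSchema,
    ResponseSeries,
)


class ConfigError(ValueError):
    """A simulation configuration is internally inconsistent."""


# --------------------------------------------------------------- truth model


@dataclass
class TruthTable:
    """Latent true response per (item, question), plus per-item stratum."""

    schemas: dict[str, QuestionSchema]
    items: tuple
    truths: dict[str, list]  # question_id -> per-item responses
    strata: tuple

    def series(self, question_id: str) -> ResponseSeries:
        return ResponseSeries(
            question_id, "truth", self.items, tuple(self.truths[question_id])
        )


@dataclass
class RaterErrorModel:
    """Independent-noise channel applied to the latent truth.

    Parameters
    ----------
    epsilon_single : float
        Probability a single-option response is a uniformly random wrong label.
    epsilon_miss : float
        Per-label probability a true label is dropped (multi questions).
    epsilon_add : float
        Per-label probability an absent label is added (multi questions).
    bias_offsets : mapping label -> float
        Additive offset on the add probability; positive values model a
        rater's systematic over-detection of that label.
    """

    epsilon_single: float = 0.0
    epsilon_miss: float = 0.0
    epsilon_add: float = 0.0
    bias_offsets: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("epsilon_single", "epsilon_miss", "epsilon_add"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")


@dataclass
class RaterSpec:
    rater_id: str
    role: str  # crowd | expert | model
    error_model: RaterErrorModel
    coverage: float = 1.0  # fraction of items the rater codes

    def __post_init__(self) -> None:
        if not 0.0 < self.coverage <= 1.0:
            raise ConfigError(f"coverage must be in (0, 1], got {self.coverage}")


@dataclass
class PanelConfig:
    """Full description of a synthetic annotation panel."""

    n_items: int
    schemas: Sequence[QuestionSchema]
    prevalence: Mapping[str, Mapping[str, float]]  # question -> label -> weight
    size_distribution: Mapping[str, Mapping[int, float]]  # multi question -> size -> prob
    raters: Sequence[RaterSpec]
    strata_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"Dutch": 0.5, "French": 0.4, "English": 0.1}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for qid, prev in self.prevalence.items():
            for label, p in prev.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"prevalence[{qid}][{label}] = {p} outside [0, 1]")
        for qid, dist in self.size_distribution.items():
            schema = next(s for s in self.schemas if s.question_id == qid)
            if any(size > schema.k for size in dist):
                raise ConfigError(f"size_distribution[{qid}] allows sizes > codebook size {schema.k}")
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"size_distribution[{qid}] sums to {total}, not 1")


# ----------------------------------------------------------------- sampling


def sample_truth(config: PanelConfig) -> TruthTable:
    """Draw the latent truth table for a panel.

    Single questions: the true label is drawn from the normalized prevalence.
    Multi questions: the set size is drawn from ``size_distribution`` and
    members are drawn without replacement with probability proportional to
    prevalence; an empty draw becomes ``{none_label}``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    items = tuple(f"item{idx:05d}" for idx in range(config.n_items))
    strata_names = list(config.strata_proportions)
    strata_p = np.asarray([config.strata_proportions[s] for s in strata_names], dtype=float)
    strata_p = strata_p / strata_p.sum()
    strata = tuple(rng.choice(strata_names, size=config.n_items, p=strata_p))

    truths: dict[str, list] = {}
    for schema in config.schemas:
        prev = config.prevalence.get(schema.question_id)
        if prev is None:
            raise ConfigError(f"no prevalence for question {schema.question_id!r}")
        if schema.kind == "single":
            weights = np.asarray([prev.get(c, 0.0) for c in schema.codebook], dtype=float)
            if weights.sum() <= 0:
                raise ConfigError(f"all-zero prevalence for {schema.question_id!r}")
            weights = weights / weights.sum()
            idx = rng.choice(schema.k, size=config.n_items, p=weights)
            truths[schema.question_id] = [schema.codebook[i] for i in idx]
        else:
            dist = config.size_distribution.get(schema.question_id)
            if dist is None:
                raise ConfigError(f"no size_distribution for multi question {schema.question_id!r}")
            sizes = np.asarray(sorted(dist), dtype=int)
            size_p = np.asarray([dist[int(s)] for s in sizes], dtype=float)
            size_p = size_p / size_p.sum()
            weights = np.asarray([prev.get(c, 0.0) for c in schema.codebook], dtype=float)
            if weights.sum() <= 0:
                raise ConfigError(f"all-zero prevalence for {schema.question_id!r}")
            weights = weights / weights.sum()
            drawn_sizes = rng.choice(sizes, size=config.n_items, p=size_p)
            col = []
            for size in drawn_sizes:
                if size <= 0:
                    col.append(frozenset({schema.none_label}) if schema.none_label else frozenset())
                    continue
                members = rng.choice(schema.k, size=int(size), replace=False, p=weights)
                col.append(frozenset(schema.codebook[i] for i in members))
            truths[schema.question_id] = col
    return TruthTable(
        schemas={s.question_id: s for s in config.schemas},
        items=items,
        truths=truths,
        strata=strata,
    )


def simulate_rater(
    truth: TruthTable,
    model: RaterErrorModel,
    question_id: str,
    rater_id: str = "rater",
    seed: int | None = 0,
    items: Sequence[str] | None = None,
) -> ResponseSeries:
    """Pass the latent truth through one rater's noise channel."""
    if question_id not in truth.truths:
        raise ConfigError(f"question {question_id!r} not in truth table")
    schema = truth.schemas[question_id]
    rng = np.random.default_rng(seed)
    if items is None:
        items = truth.items
        values = truth.truths[question_id]
    else:
        pos = {it: i for i, it in enumerate(truth.items)}
        values = [truth.truths[question_id][pos[it]] for it in items]

    out = []
    if schema.kind == "single":
        flips = rng.random(len(values)) < model.epsilon_single
        for v, flip in zip(values, flips):
            if not flip:
                out.append(v)
            else:
                others = [c for c in schema.codebook if c != v]
                out.append(others[rng.integers(len(others))])
    else:
        add_p = np.asarray(
            [
                min(1.0, max(0.0, model.epsilon_add + model.bias_offsets.get(c, 0.0)))
                for c in schema.codebook
            ]
        )
        for v in values:
            # iterate in codebook order: set iteration order is hash-dependent
            # and would desynchronize the rng stream across processes
            u_keep = rng.random(schema.k)
            u_add = rng.random(schema.k)
            kept = set()
            for c, keep_roll, add_roll, p in zip(schema.codebook, u_keep, u_add, add_p):
                if c in v:
                    if keep_roll >= model.epsilon_miss:
                        kept.add(c)
                elif add_roll < p:
                    kept.add(c)
            if not kept:
                if schema.none_label is None:
                    raise ConfigError(
                        f"{question_id!r}: empty response and no none_label to fall back on"
                    )
                kept = {schema.none_label}
            out.append(frozenset(kept))
    return ResponseSeries(question_id, rater_id, tuple(items), tuple(out))


def simulate_panel(config: PanelConfig) -> AnnotationTable:
    """Simulate a full annotation panel.

    Crowd and model raters cover a contiguous random block of items sized by
    their coverage fraction; expert raters share one common block (emulating a
    fixed expert subsample).  Deterministic given ``config.seed``.
    """
    truth = sample_truth(config)
    ss = np.random.SeedSequence([int(config.seed), 1])
    rng = np.random.default_rng(ss)
    n = config.n_items

    def block(coverage: float, start: int | None = None) -> tuple[Sequence[str], int]:
        size = int(round(coverage * n))
        size = max(1, min(n, size))
        if start is None:
            start = int(rng.integers(0, n - size + 1))
        return truth.items[start : start + size], start

    expert_start: int | None = None
    records: list[AnnotationRecord] = []
    stratum_of = dict(zip(truth.items, truth.strata))
    # independent sub-seed per (rater, question), derived from the master seed
    child_seeds = iter(ss.spawn(len(config.raters) * len(list(config.schemas))))
    for spec in config.raters:
        if spec.role == "expert":
            rater_items, expert_start = block(spec.coverage, expert_start)
        else:
            rater_items, _ = block(spec.coverage)
        for schema in config.schemas:
            series = simulate_rater(
                truth,
                spec.error_model,
                schema.question_id,
                rater_id=spec.rater_id,
                seed=next(child_seeds),
                items=rater_items,
            )
            for item, resp in zip(series.items, series.responses):
                records.append(
                    AnnotationRecord(
                        item_id=item,
                        rater_id=spec.rater_id,
                        role=spec.role,
                        question_id=schema.question_id,
                        response=resp,
                        stratum=stratum_of[item],
                    )
                )
    return AnnotationTable(records, config.schemas)


# ----------------------------------------------------------------- defaults


def default_schemas() -> list[QuestionSchema]:
    """The six-question study codebook: three single-option questions
    (k = 2, 3, 9) and three sparse multi-option questions (k = 10, 11, 26),
    each multi question carrying an explicit absence label and — for the two
    marketing questions — an ``"Other"`` option offered only to human coders.
    """
    return [
        QuestionSchema("alcohol", "single", ("Yes", "No")),
        QuestionSchema("target_group", "single", ("Child", "Adolescent", "Adult")),
        QuestionSchema(
            "ad_type",
            "single",
            (
                "Manufacturer", "Restaurant", "Retailer", "Supermarket", "Delivery",
                "Event", "Campaign", "Media", "Other",
            ),
        ),
        QuestionSchema(
            "premium_offers",
            "multi",
            (
                "None", "Price discount", "Limited edition", "Loyalty program",
                "Games", "Charity", "Apps", "Gift", "Contest", "Other",
            ),
            ai_excluded=frozenset({"Other"}),
            none_label="None",
        ),
        QuestionSchema(
            "marketing_strategies",
            "multi",
            (
                "None", "Events", "Celebrities", "Cartoons", "Owned characters",
                "Other characters", "Sport", "Health claims", "Nature claims",
                "Convenience", "Other",
            ),
            ai_excluded=frozenset({"Other"}),
            none_label="None",
        ),
        QuestionSchema(
            "who_categories",
            "multi",
            (
                "Non-applicable", "Dairy", "Cheese", "Fresh fruit", "Processed fruit",
                "Vegetables", "Processed vegetables", "Snacks", "Chocolate/Sugar",
                "Pastries", "Cakes", "Soft drinks", "Juices", "Energy drinks",
                "Alcoholic drinks", "Ready-made", "Fast food", "Bread", "Cereals",
                "Processed meat", "Fresh meat", "Fish", "Sauces", "Oils",
                "Composite dishes", "Edible ices",
            ),
            none_label="Non-applicable",
        ),
    ]


def _decaying_weights(labels: Sequence[str], none_weight: float = 0.25, decay: float = 0.75):
    """Skewed prevalence: the absence label gets a lump, the rest decay geometrically."""
    out = {}
    w = 1.0
    for label in labels[1:]:
        out[label] = w
        w *= decay
    total = sum(out.values())
    out = {lab: (1 - none_weight) * v / total for lab, v in out.items()}
    out[labels[0]] = none_weight
    return out


def default_panel_config(
    n_items: int = 1000,
    seed: int = 0,
    crowd_noise: float = 0.12,
    expert_noise: float = 0.06,
    model_noise: float = 0.10,
    model_bias: Mapping[str, Mapping[str, float]] | None = None,
) -> PanelConfig:
    """Study-shaped default panel: 3 crowd raters on all items, 3 experts on a
    shared 40% subsample, 4 model raters on all items.

    The three noise arguments set ``epsilon_single`` per role; multi-question
    miss/add rates are scaled from them (miss = 2x, add = x/4) so multi tasks
    are noisier than single tasks, as sparse set-valued coding is in practice.
    ``model_bias`` maps question -> label -> add-rate offset; the default
    injects the over-detection of a salient promotional label and the
    under-detection pressure on the absence label that motivates the bias
    diagnostics.
    """
    schemas = default_schemas()
    prevalence = {
        "alcohol": {"Yes": 0.2, "No": 0.8},
        "target_group": {"Child": 0.1, "Adolescent": 0.2, "Adult": 0.7},
        "ad_type": _decaying_weights([s for s in schemas if s.question_id == "ad_type"][0].codebook, none_weight=0.05),
        "premium_offers": _decaying_weights(schemas[3].codebook),
        "marketing_strategies": _decaying_weights(schemas[4].codebook),
        "who_categories": _decaying_weights(schemas[5].codebook, none_weight=0.15, decay=0.85),
    }
    size_distribution = {
        "premium_offers": {1: 0.5, 2: 0.3, 3: 0.2},
        "marketing_strategies": {1: 0.5, 2: 0.3, 3: 0.2},
        "who_categories": {1: 0.5, 2: 0.3, 3: 0.2},
    }
    if model_bias is None:
        model_bias = {
            "premium_offers": {"Limited edition": 0.10},
            "marketing_strategies": {"Events": 0.12},
            "who_categories": {"Ready-made": 0.10},
        }

    def em(eps: float, offsets: Mapping[str, float] | None = None) -> RaterErrorModel:
        return RaterErrorModel(
            epsilon_single=eps,
            epsilon_miss=min(1.0, 2 * eps),
            epsilon_add=eps / 4,
            bias_offsets=dict(offsets or {}),
        )

    # per-question offsets are flattened: label names are unique enough across
    # the default codebooks that a single map suffices
    flat_bias: dict[str, float] = {}
    for qmap in model_bias.values():
        flat_bias.update(qmap)

    # experts are deliberately heterogeneous: real expert panels show wide
    # inter-expert variability, and the exchangeability envelope is only
    # meaningful when the expert range has width
    raters = [
        RaterSpec("crowd1", "crowd", em(crowd_noise)),
        RaterSpec("crowd2", "crowd", em(crowd_noise)),
        RaterSpec("crowd3", "crowd", em(crowd_noise)),
        RaterSpec("expert1", "expert", em(expert_noise * 0.7), coverage=0.4),
        RaterSpec("expert2", "expert", em(expert_noise), coverage=0.4),
        RaterSpec("expert3", "expert", em(expert_noise * 1.8), coverage=0.4),
        RaterSpec("model_gpt", "model", em(model_noise * 0.8, flat_bias)),
        RaterSpec("model_qwen", "model", em(model_noise, {k: 1.4 * v for k, v in flat_bias.items()})),
        RaterSpec("model_pixtral", "model", em(model_noise * 1.2, flat_bias)),
        RaterSpec("model_gemma", "model", em(model_noise * 1.5, {k: 1.4 * v for k, v in flat_bias.items()})),
    ]
    return PanelConfig(
        n_items=n_items,
        schemas=schemas,
        prevalence=prevalence,
        size_distribution=size_distribution,
        raters=raters,
        seed=seed,
    )
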