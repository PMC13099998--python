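"""Simulation-based calibration of attainable agreement.

Chance-corrected coefficients on sparse multi-label tasks depend strongly on
the number of categories and the label-set-size distribution, so universal
benchmarks ("alpha above 0.8 is good") mislead.  This module simulates three
reference scenarios matched to a task's empirical set-size distribution —

* ``random_like`` — two independent raters drawing sets of the observed sizes
  uniformly from the codebook (agreement is pure chance; alpha centres on 0),
* ``near_perfect`` — rater 2 copies rater 1 except that with probability
  ``epsilon_cal`` per item one label is swapped for a random outsider,
* ``near_disagreement`` — rater 2 draws a same-size set from the complement
  of rater 1's labels (fully disjoint whenever the codebook allows),

and summarizes each coefficient over replications, yielding task-specific
upper and lower bounds against which observed values can be interpreted.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import compute_metric, metrics_for_kind
from .schema import QuestionSchema, ResponseSeries

SCENARIOS = ("random_like", "near_perfect", "near_disagreement")


@dataclass
class ScenarioSpec:
    name: str
    codebook: tuple
    size_distribution: Mapping[int, float]
    n_items: int = 1000
    replications: int = 100
    epsilon_cal: float = 0.05  # per-item perturbation probability (near_* scenarios)
    seed: int = 0
    kind: str = "multi"

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}")
        total = sum(self.size_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"size_distribution sums to {total}, not 1")
        if any(s > len(self.codebook) for s in self.size_distribution):
            raise ValueError("size_distribution allows sizes larger than the codebook")
        if not 0.0 <= self.epsilon_cal <= 1.0:
            raise ValueError("epsilon_cal must be in [0, 1]")


def empirical_size_distribution(series: ResponseSeries) -> dict[int, float]:
    """Normalized histogram of observed label-set sizes."""
    if len(series) == 0:
        raise ValueError("empty series")
    sizes = [len(r) if isinstance(r, frozenset) else 1 for r in series.responses]
    counts = pd.Series(sizes).value_counts().sort_index()
    return {int(s): float(c) / len(sizes) for s, c in counts.items()}


def _draw_sets(rng, codebook: Sequence, sizes: np.ndarray) -> list[frozenset]:
    k = len(codebook)
    return [
        frozenset(codebook[i] for i in rng.choice(k, size=int(s), replace=False))
        for s in sizes
    ]


def simulate_scenario(spec: ScenarioSpec) -> tuple[ResponseSeries, ResponseSeries]:
    """Draw one pair of rater series under the scenario. Deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    sizes_avail = np.asarray(sorted(spec.size_distribution), dtype=int)
    size_p = np.asarray([spec.size_distribution[int(s)] for s in sizes_avail], dtype=float)
    size_p /= size_p.sum()
    items = tuple(f"i{j}" for j in range(spec.n_items))
    codebook = tuple(spec.codebook)
    k = len(codebook)

    if spec.kind == "single":
        x1 = rng.integers(0, k, size=spec.n_items)
        if spec.name == "random_like":
            x2 = rng.integers(0, k, size=spec.n_items)
        elif spec.name == "near_perfect":
            x2 = x1.copy()
            flip = rng.random(spec.n_items) < spec.epsilon_cal
            x2[flip] = (x1[flip] + 1 + rng.integers(0, k - 1, size=int(flip.sum()))) % k
        else:  # near_disagreement
            x2 = (x1 + 1 + rng.integers(0, k - 1, size=spec.n_items)) % k
        r1 = tuple(codebook[i] for i in x1)
        r2 = tuple(codebook[i] for i in x2)
        return (
            ResponseSeries("scenario", "rater1", items, r1),
            ResponseSeries("scenario", "rater2", items, r2),
        )

    sizes = rng.choice(sizes_avail, size=spec.n_items, p=size_p)
    sets1 = _draw_sets(rng, codebook, sizes)
    if spec.name == "random_like":
        sets2 = _draw_sets(rng, codebook, rng.choice(sizes_avail, size=spec.n_items, p=size_p))
    elif spec.name == "near_perfect":
        sets2 = []
        perturb = rng.random(spec.n_items) < spec.epsilon_cal
        for s, do in zip(sets1, perturb):
            if not do:
                sets2.append(s)
                continue
            outside = [c for c in codebook if c not in s]
            if not outside:
                sets2.append(s)
                continue
            members = sorted(s)  # deterministic order regardless of set hashing
            drop = members[rng.integers(len(members))]
            add = outside[rng.integers(len(outside))]
            sets2.append((s - {drop}) | {add})
    else:  # near_disagreement: same-size draw from the complement where possible
        sets2 = []
        for s in sets1:
            outside = [c for c in codebook if c not in s]
            want = len(s)
            if len(outside) >= want:
                members = rng.choice(len(outside), size=want, replace=False)
                sets2.append(frozenset(outside[i] for i in members))
            else:
                # codebook too small for full disjointness; minimize overlap
                inside = sorted(s)
                fill = rng.choice(len(inside), size=want - len(outside), replace=False)
                sets2.append(frozenset(outside) | frozenset(inside[i] for i in fill))
    return (
        ResponseSeries("scenario", "rater1", items, tuple(frozenset(s) for s in sets1)),
        ResponseSeries("scenario", "rater2", items, tuple(frozenset(s) for s in sets2)),
    )


@dataclass
class CalibrationBounds:
    """Per (scenario, metric) summaries over replications."""

    table: pd.DataFrame  # columns: scenario, metric, mean, sd, q2.5, q97.5, R

    def mean(self, scenario: str, metric: str) -> float:
        sel = self.table[(self.table.scenario == scenario) & (self.table.metric == metric)]
        return float(sel["mean"].iloc[0])


def calibrate_bounds(
    specs: Sequence[ScenarioSpec],
    metrics: Sequence[str] | None = None,
    schema: QuestionSchema | None = None,
) -> CalibrationBounds:
    """Replicate each scenario and summarize each metric's distribution.

    ``sd`` is reported as missing for a single replication.
    """
    rows = []
    for spec in specs:
        spec_metrics = tuple(metrics) if metrics is not None else metrics_for_kind(spec.kind)
        q_schema = schema or QuestionSchema(
            "scenario", spec.kind, tuple(spec.codebook),
        )
        values: dict[str, list[float]] = {m: [] for m in spec_metrics}
        child_seeds = np.random.SeedSequence(spec.seed).spawn(spec.replications)
        for r in range(spec.replications):
            rep = ScenarioSpec(
                name=spec.name,
                codebook=spec.codebook,
                size_distribution=spec.size_distribution,
                n_items=spec.n_items,
                replications=1,
                epsilon_cal=spec.epsilon_cal,
                seed=child_seeds[r],
                kind=spec.kind,
            )
            s1, s2 = simulate_scenario(rep)
            for m in spec_metrics:
                values[m].append(compute_metric(m, s1, s2, q_schema).value)
        for m in spec_metrics:
            arr = np.asarray(values[m], dtype=float)
            rows.append(
                {
                    "scenario": spec.name,
                    "metric": m,
                    "mean": float(arr.mean()),
                    "sd": float(arr.std(ddof=1)) if len(arr) > 1 else float("nan"),
                    "q2.5": float(np.percentile(arr, 2.5)),
                    "q97.5": float(np.percentile(arr, 97.5)),
                    "R": len(arr),
                }
            )
    return CalibrationBounds(pd.DataFrame(rows))
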