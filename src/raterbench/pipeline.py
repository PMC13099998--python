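"""End-to-end pipeline: simulate -> consensus -> agree -> bias -> bootstrap
-> calibrate -> strata, with a reproducible run manifest.

Stages run in dependency order; a stage failure aborts the run, removes any
partial outputs, and names the failing stage.  All randomness derives from
the seeds recorded in the manifest, so a manifest plus config reproduces
every output file byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .bias import bias_frame, bias_table
from .bootstrap import bootstrap_exchangeability
from .calibration import ScenarioSpec, calibrate_bounds, empirical_size_distribution
from .consensus import build_consensus
from .metrics import metrics_for_kind, pairwise_matrix
from .schema import AnnotationTable, load_annotations, load_schema, write_annotations
from .strata import stratified_delta
from .synth import default_panel_config, simulate_panel

log = logging.getLogger("raterbench")

STAGES = ("simulate", "consensus", "agree", "bias", "exchangeability", "calibrate", "strata")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    out_dir: str
    seed: int = 0
    n_items: int = 1000
    annotations: str | None = None  # use an existing panel instead of simulating
    codebook: str | None = None
    questions: list = field(default_factory=list)  # empty = all
    stages: tuple = STAGES
    bootstrap_iterations: int = 1000
    calibration_replications: int = 100
    calibration_items: int = 500
    permutations: int = 200
    strata_pair: tuple = ("Dutch", "French")

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_or_simulate(config: RunConfig) -> AnnotationTable:
    if config.annotations:
        if not config.codebook:
            raise ValueError("annotations input requires a codebook path")
        schemas = load_schema(config.codebook)
        return load_annotations(config.annotations, schemas)
    panel_cfg = default_panel_config(n_items=config.n_items, seed=config.seed)
    return simulate_panel(panel_cfg)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest = {
        "package": "raterbench",
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in config.__dict__.items()},
        "config_hash": config.config_hash(),
        "stages": {},
        "outputs": [],
    }

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)
        manifest["outputs"].append(name)

    current = None
    try:
        for stage in config.stages:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
        questions = None
        t_all = time.time()

        current = "simulate"
        t0 = time.time()
        table = _load_or_simulate(config)
        questions = config.questions or list(table.schemas)
        unknown = [q for q in questions if q not in table.schemas]
        if unknown:
            raise ValueError(f"unknown question(s) in config: {unknown}")
        if "simulate" in config.stages and not config.annotations:
            write_annotations(table, out / "panel.csv")
            written.append(out / "panel.csv")
            manifest["outputs"].append("panel.csv")
        manifest["stages"]["simulate"] = round(time.time() - t0, 3)
        log.info("simulate: %d records", len(table))

        current = "consensus"
        t0 = time.time()
        crowd_cons = build_consensus(table, roles=("crowd",))
        combined = AnnotationTable(table.records + crowd_cons.records, table.schemas.values())
        expert_ids = table.raters("expert")
        if expert_ids:
            expert_cons = build_consensus(table, roles=("expert",))
            combined = AnnotationTable(
                combined.records + expert_cons.records, table.schemas.values()
            )
        if "consensus" in config.stages:
            cons_only = AnnotationTable(
                [r for r in combined.records if r.role == "consensus"], table.schemas.values()
            )
            write_annotations(cons_only, out / "consensus.csv")
            written.append(out / "consensus.csv")
            manifest["outputs"].append("consensus.csv")
        manifest["stages"]["consensus"] = round(time.time() - t0, 3)

        if "agree" in config.stages:
            current = "agree"
            t0 = time.time()
            frames = [
                pairwise_matrix(combined, qid).to_dataframe() for qid in questions
            ]
            emit(pd.concat(frames, ignore_index=True), "agreement.csv")
            manifest["stages"]["agree"] = round(time.time() - t0, 3)

        model_ids = table.raters("model")
        if "bias" in config.stages and model_ids:
            current = "bias"
            t0 = time.time()
            frames = []
            for qid in questions:
                # nutrition-flavoured questions benchmark against experts when
                # available, marketing-flavoured ones against the crowd
                ref = (
                    "consensus:expert"
                    if expert_ids and qid not in ("premium_offers", "marketing_strategies")
                    else "consensus:crowd"
                )
                if ref not in combined.raters():
                    ref = "consensus:crowd"
                ests = bias_table(combined, model_ids, ref, qid)
                frames.append(bias_frame(ests))
            emit(pd.concat(frames, ignore_index=True), "bias.csv")
            manifest["stages"]["bias"] = round(time.time() - t0, 3)

        if "exchangeability" in config.stages and model_ids and expert_ids:
            current = "exchangeability"
            t0 = time.time()
            rows = []
            for qid in questions:
                res = bootstrap_exchangeability(
                    combined,
                    qid,
                    model_id=model_ids[0],
                    expert_ids=expert_ids,
                    consensus_id="consensus:expert",
                    B=config.bootstrap_iterations,
                    seed=config.seed,
                )
                lo, hi = res.model_ci()
                rows.append(
                    {
                        "question_id": qid,
                        "metric": res.metric,
                        "model": res.model_id,
                        "B": res.B,
                        "in_range_proportion": res.in_range_proportion,
                        "model_median": res.model_median,
                        "ci_low": lo,
                        "ci_high": hi,
                        "n_missing": res.n_missing,
                    }
                )
            emit(pd.DataFrame(rows), "exchangeability.csv")
            manifest["stages"]["exchangeability"] = round(time.time() - t0, 3)

        if "calibrate" in config.stages:
            current = "calibrate"
            t0 = time.time()
            frames = []
            for qid in questions:
                schema = table.schemas[qid]
                if schema.kind != "multi":
                    continue
                sizes = empirical_size_distribution(
                    combined.extract_series("consensus:crowd", qid)
                )
                specs = [
                    ScenarioSpec(
                        name,
                        codebook=schema.codebook,
                        size_distribution=sizes,
                        n_items=config.calibration_items,
                        replications=config.calibration_replications,
                        seed=config.seed,
                        kind="multi",
                    )
                    for name in ("random_like", "near_perfect", "near_disagreement")
                ]
                bounds = calibrate_bounds(specs).table
                bounds.insert(0, "question_id", qid)
                frames.append(bounds)
            emit(pd.concat(frames, ignore_index=True), "calibration.csv")
            manifest["stages"]["calibrate"] = round(time.time() - t0, 3)

        if "strata" in config.stages:
            current = "strata"
            t0 = time.time()
            sa, sb = config.strata_pair
            rows = []
            for qid in questions:
                metric = metrics_for_kind(table.schemas[qid].kind)[1]
                for mid in model_ids[:1] or table.raters()[:1]:
                    d = stratified_delta(
                        combined,
                        qid,
                        rater_a=mid,
                        rater_b="consensus:crowd",
                        stratum_a=sa,
                        stratum_b=sb,
                        metric=metric,
                        permutations=config.permutations,
                        seed=config.seed,
                    )
                    rows.append(d.__dict__)
            emit(pd.DataFrame(rows), "strata.csv")
            manifest["stages"]["strata"] = round(time.time() - t0, 3)

        manifest["elapsed"] = round(time.time() - t_all, 3)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
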